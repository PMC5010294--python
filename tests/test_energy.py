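import math

import numpy as np
import pytest

from oracles import brute_force_psee
from psee.energy import (
    DISORDERED,
    ORDERED,
    PSEEConfig,
    classify_by_threshold,
    hydrophobicity_correlation,
    idr_length_stratum,
    mean_psee_by_label,
    mean_psee_by_amino_acid,
    midpoint_threshold,
    proportional_burial,
    proportional_exposure,
    profile_sequence,
    psee_profile,
    region_mean_psee,
    sweep_contact_radius,
)
from psee.tables import AMINO_ACIDS, UnknownResidueError


# ---------------------------------------------------------------------------
# exposure / burial


def test_proportional_exposure_examples(asa_table):
    assert proportional_exposure("G", 104.0, asa_table) == pytest.approx(1.0)
    assert proportional_exposure("A", 0.0, asa_table) == 0.0
    # 258/129 = 2.0 clips to 1
    assert proportional_exposure("A", 258.0, asa_table, clip=True) == 1.0
    assert proportional_exposure("A", 258.0, asa_table, clip=False) == pytest.approx(2.0)


def test_proportional_exposure_rejects_bad_input(asa_table):
    with pytest.raises(ValueError, match="non-negative"):
        proportional_exposure("A", -1.0, asa_table)
    with pytest.raises(UnknownResidueError):
        proportional_exposure("X", 10.0, asa_table)


@pytest.mark.parametrize("p_exp, expected", [(0.0, 1.0), (1.0, 0.0), (0.25, 0.75)])
def test_proportional_burial_complement(p_exp, expected):
    assert proportional_burial(p_exp) == expected


def test_proportional_burial_rejects_out_of_range():
    with pytest.raises(ValueError):
        proportional_burial(1.5)


# ---------------------------------------------------------------------------
# PSEE closed forms and oracle


def test_poly_alanine_interior_psee_is_diagonal_entry(matrix):
    profiles = psee_profile("A" * 30, [1.0] * 30, PSEEConfig(contact_radius=9), matrix)
    for p in profiles[9:21]:  # fully interior positions
        assert p.psee == pytest.approx(-1.65, abs=1e-12)


def test_zero_target_burial_gives_zero_psee(matrix):
    p_bur = [0.8] * 10
    p_bur[4] = 0.0
    profiles = psee_profile("ACDEFGHIKL", p_bur, PSEEConfig(contact_radius=3), matrix)
    assert profiles[4].psee == 0.0


def test_arn_hand_computed_value(matrix):
    profiles = psee_profile("ARN", [0.5, 0.5, 0.5], PSEEConfig(contact_radius=1), matrix)
    # 0.5 * (P(R,A)*0.5 + P(R,N)*0.5) / 2 = 0.5*(0.49 + 0.54)/2
    assert profiles[1].psee == pytest.approx(0.2575, abs=1e-12)


def test_nonstandard_residue_marked_unavailable_not_zero(matrix):
    profiles = psee_profile("AXA", [1.0, 1.0, 1.0], PSEEConfig(contact_radius=1), matrix)
    assert profiles[1].psee is None
    assert not profiles[1].available
    # and it does not contribute as a partner either
    assert profiles[0].psee == 0.0  # only partner is X -> empty sum


def test_strict_mode_rejects_nonstandard(matrix):
    with pytest.raises(UnknownResidueError, match="strict"):
        psee_profile("AXA", [1.0] * 3, PSEEConfig(contact_radius=1, strict_alphabet=True), matrix)


def test_length_mismatch_rejected(matrix):
    with pytest.raises(ValueError, match="length"):
        psee_profile("ARN", [0.5, 0.5], PSEEConfig(), matrix)


@pytest.mark.parametrize("cr", [1, 3, 9])
@pytest.mark.parametrize("symmetrize", [False, True])
def test_psee_matches_brute_force_oracle(matrix, cr, symmetrize):
    """Vectorized profile equals an explicit double-loop enumeration on
    random sequences (including non-standard residues) to 1e-12."""
    rng = np.random.default_rng(1234 + cr)
    alphabet = AMINO_ACIDS + "X"
    for _ in range(70):
        L = int(rng.integers(1, 61))
        seq = "".join(rng.choice(list(alphabet), size=L, p=[0.0485] * 20 + [0.03]))
        p_bur = rng.uniform(0, 1, size=L)
        config = PSEEConfig(contact_radius=cr, symmetrize=symmetrize)
        got = [p.psee for p in psee_profile(seq, p_bur, config, matrix)]
        expected = brute_force_psee(seq, p_bur, cr, matrix, symmetrize=symmetrize)
        for g, e in zip(got, expected):
            if e is None:
                assert g is None
            else:
                assert g == pytest.approx(e, abs=1e-12)


def test_normalize_by_count_matches_oracle(matrix):
    rng = np.random.default_rng(77)
    for _ in range(20):
        L = int(rng.integers(2, 40))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=L))
        p_bur = rng.uniform(0, 1, size=L)
        config = PSEEConfig(contact_radius=5, normalize_by_count=True)
        got = [p.psee for p in psee_profile(seq, p_bur, config, matrix)]
        expected = brute_force_psee(seq, p_bur, 5, matrix, normalize_by_count=True)
        assert got == pytest.approx(expected, abs=1e-12)


def test_psee_linear_in_target_burial(matrix):
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=30))
    p_bur = rng.uniform(0, 1, size=30)
    base = [p.psee for p in psee_profile(seq, p_bur, PSEEConfig(contact_radius=4), matrix)]
    for i, lam in [(0, 0.5), (15, 0.25), (29, 2 / 3)]:
        scaled = p_bur.copy()
        scaled[i] = lam * p_bur[i]
        got = psee_profile(seq, scaled, PSEEConfig(contact_radius=4), matrix)[i].psee
        assert got == pytest.approx(lam * base[i], rel=1e-12)


def test_constant_divisor_never_exceeds_per_count_magnitude(matrix):
    """|PSEE| with the fixed 2*CR divisor is bounded by the per-count
    normalization at every position (the divisor is never smaller)."""
    rng = np.random.default_rng(11)
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=25))
    p_bur = rng.uniform(0, 1, size=25)
    fixed = psee_profile(seq, p_bur, PSEEConfig(contact_radius=9), matrix)
    counted = psee_profile(
        seq, p_bur, PSEEConfig(contact_radius=9, normalize_by_count=True), matrix
    )
    for a, b in zip(fixed, counted):
        assert abs(a.psee) <= abs(b.psee) + 1e-12


# ---------------------------------------------------------------------------
# class means, thresholds, regions


def _profiles_with_psee(values):
    from psee.energy import ResidueProfile

    return [
        ResidueProfile(i + 1, "A", None, 0.0, 1.0, v) for i, v in enumerate(values)
    ]


def test_mean_psee_by_label_two_classes():
    profiles = _profiles_with_psee([-1.0, -2.0, 0.0, 1.0])
    summary = mean_psee_by_label(profiles, ["O", "O", "D", "D"])
    assert summary.class_means["O"] == pytest.approx(-1.5)
    assert summary.class_means["D"] == pytest.approx(0.5)
    assert summary.class_counts == {"O": 2, "D": 2}
    assert summary.threshold == pytest.approx(-0.5)


def test_mean_psee_excludes_unknown_and_unavailable():
    profiles = _profiles_with_psee([-1.0, None, -3.0, 5.0])
    summary = mean_psee_by_label(profiles, ["O", "O", "O", "X"])
    assert summary.class_means["O"] == pytest.approx(-2.0)
    assert summary.class_counts == {"O": 2}
    assert summary.threshold is None


def test_mean_psee_all_unknown_is_error():
    with pytest.raises(ValueError, match="no usable residues"):
        mean_psee_by_label(_profiles_with_psee([1.0, 2.0]), ["X", "X"])


def test_three_class_means_have_no_threshold():
    profiles = _profiles_with_psee([-2.0, -1.0, 0.5])
    summary = mean_psee_by_label(profiles, ["E", "H", "C"])
    assert summary.class_means == {"E": -2.0, "H": -1.0, "C": 0.5}
    assert summary.threshold is None


def test_midpoint_threshold():
    assert midpoint_threshold(-1.00, -0.391) == pytest.approx(-0.6955)
    assert midpoint_threshold(-0.5, -0.5) == -0.5
    assert midpoint_threshold(0, 0) == 0
    with pytest.raises(ValueError):
        midpoint_threshold(float("nan"), 0.0)


def test_midpoint_is_equidistant():
    rng = np.random.default_rng(3)
    for _ in range(50):
        a, b = rng.normal(size=2)
        t = midpoint_threshold(a, b)
        assert abs(t - a) == pytest.approx(abs(t - b), abs=1e-12)


def test_classify_by_threshold_boundary_and_unavailable():
    t = -0.6955
    assert classify_by_threshold([-1.0], t) == [ORDERED]
    assert classify_by_threshold([0.0], t) == [DISORDERED]
    assert classify_by_threshold([t], t) == [ORDERED]  # tie goes to favorable side
    assert classify_by_threshold([None, -1.0], t) == [None, ORDERED]


def test_region_mean_and_strata():
    profiles = _profiles_with_psee([-0.4] + [0.1] * 59)
    records = region_mean_psee(profiles, [(1, 1, DISORDERED)])
    assert records[0].mean_psee == pytest.approx(-0.4)
    assert records[0].length_stratum == "<=5"
    lengths = {3: "<=5", 10: "6-20", 30: "21-40", 50: ">=41"}
    for length, stratum in lengths.items():
        assert idr_length_stratum(length) == stratum
        rec = region_mean_psee(profiles, [(1, length, DISORDERED)])[0]
        assert rec.length_stratum == stratum
    ordered = region_mean_psee(profiles, [(2, 4, ORDERED)])[0]
    assert ordered.length_stratum is None
    assert ordered.mean_psee == pytest.approx(0.1)


def test_region_bounds_validated():
    profiles = _profiles_with_psee([0.0] * 10)
    with pytest.raises(ValueError, match="invalid"):
        region_mean_psee(profiles, [(5, 2, ORDERED)])
    with pytest.raises(ValueError, match="invalid"):
        region_mean_psee(profiles, [(0, 3, ORDERED)])
    with pytest.raises(ValueError, match="invalid"):
        region_mean_psee(profiles, [(8, 11, ORDERED)])


# ---------------------------------------------------------------------------
# CR sweep


def _sweep_dataset(synth_dataset, asa_table, n=8):
    dataset = []
    for record, asa, track in synth_dataset[:n]:
        p_bur = [
            1.0 - min(a / asa_table[aa], 1.0)
            for aa, a in zip(record.sequence, asa)
        ]
        dataset.append((record.sequence, p_bur, list(track.symbols)))
    return dataset


def test_sweep_best_cr_attains_max_mcc(synth_dataset, asa_table, matrix):
    dataset = _sweep_dataset(synth_dataset, asa_table)
    result = sweep_contact_radius(dataset, range(4, 13), matrix)
    assert [r.cr for r in result.records] == list(range(4, 13))
    best = result.record_for(result.best_cr)
    assert all(best.mcc >= r.mcc for r in result.records)
    # smallest CR wins ties by construction of the argmax
    tied = [r.cr for r in result.records if r.mcc == best.mcc]
    assert result.best_cr == min(tied)
    for r in result.records:
        assert r.mean_ordered < r.mean_disordered
        assert r.threshold == pytest.approx(0.5 * (r.mean_ordered + r.mean_disordered))


def test_sweep_singleton_range(synth_dataset, asa_table, matrix):
    dataset = _sweep_dataset(synth_dataset, asa_table, n=4)
    result = sweep_contact_radius(dataset, [9], matrix)
    assert len(result.records) == 1
    assert result.records[0].cr == 9
    assert result.best_cr == 9


def test_sweep_rejects_single_class(matrix):
    dataset = [("ARNDA", [0.5] * 5, ["O"] * 5)]
    with pytest.raises(ValueError, match="both ordered and disordered"):
        sweep_contact_radius(dataset, [4], matrix)


# ---------------------------------------------------------------------------
# hydrophobicity correlation


def test_hydrophobicity_correlation_perfect_cases(hydro_table):
    exact = {aa: -hydro_table.index(aa) for aa in AMINO_ACIDS}
    assert hydrophobicity_correlation(exact, hydro_table) == pytest.approx(-1.0)
    flipped = {aa: hydro_table.index(aa) for aa in AMINO_ACIDS}
    assert hydrophobicity_correlation(flipped, hydro_table) == pytest.approx(1.0)


def test_hydrophobicity_correlation_three_points(hydro_table):
    """Closed-form Pearson on three residues whose packaged indices are
    replaced by a constructed table (A:1, C:2, D:3 vs means 1, 2, 4)."""
    from psee.tables import HydrophobicityTable

    values = {aa: 0.0 for aa in AMINO_ACIDS}
    values.update({"A": 1.0, "C": 2.0, "D": 3.0})
    table = HydrophobicityTable(values, dict(hydro_table.partition))
    got = hydrophobicity_correlation({"A": 1.0, "C": 2.0, "D": 4.0}, table)
    assert got == pytest.approx(0.9820, abs=5e-5)


def test_hydrophobicity_correlation_degenerate(hydro_table):
    with pytest.raises(ValueError, match="at least 3"):
        hydrophobicity_correlation({"A": 1.0, "C": 2.0}, hydro_table)
    with pytest.raises(ValueError, match="constant"):
        hydrophobicity_correlation({"A": 1.0, "C": 1.0, "D": 1.0}, hydro_table)


def test_synthetic_mean_psee_anticorrelates_with_hydrophobicity(
    synth_summary, hydro_table
):
    """Hydrophobic residues, being enriched in buried ordered segments,
    should carry more favorable mean PSEE: a clearly negative correlation."""
    profiles, _, _ = synth_summary
    per_aa = mean_psee_by_amino_acid(profiles)
    assert len(per_aa) == 20
    assert hydrophobicity_correlation(per_aa, hydro_table) < -0.5


def test_profile_sequence_roundtrips_exposure(asa_table, matrix):
    seq = "GWA"
    asa = [52.0, 142.5, 129.0]  # exposures 0.5, 0.5, 1.0
    profiles = profile_sequence(seq, asa, asa_table, PSEEConfig(contact_radius=1), matrix)
    assert [p.p_exp for p in profiles] == pytest.approx([0.5, 0.5, 1.0])
    assert [p.p_bur for p in profiles] == pytest.approx([0.5, 0.5, 0.0])
    assert profiles[2].psee == 0.0
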