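"""Position Specific Estimated Energy (PSEE) and its threshold analysis.

PSEE assigns each residue of a protein sequence an estimated energy based on
two ingredients that are both available from sequence alone: a pairwise
contact potential P(target, partner) between amino-acid types, and the
proportional burial pBur of every residue derived from predicted accessible
surface area.  For residue i with sequence neighborhood N_i (the CR residues
on either side of i, CR being the contact radius):

    PSEE(i) = pBur(i) * sum_{j in N_i} P(aa_i, aa_j) * pBur(j) / (2 * CR)

Negative (favorable) PSEE marks residues that sit in a stabilizing, buried,
hydrophobic-contact-rich context — the signature of structured (ordered)
regions — while disordered residues accumulate less favorable energy.  The
midpoint between the per-class mean PSEE of ordered and disordered residues
serves as a simple energy threshold classifier, and sweeping CR against
labeled data selects the neighborhood size (CR = 9 by default) that best
separates the two classes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .tables import (
    AMINO_ACIDS,
    ASANormalizationTable,
    ContactEnergyMatrix,
    HydrophobicityTable,
    UnknownResidueError,
    _AA_INDEX,
    normalize_code,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ORDERED",
    "DISORDERED",
    "PSEEConfig",
    "ResidueProfile",
    "ClassMeanSummary",
    "RegionRecord",
    "CRSweepResult",
    "proportional_exposure",
    "proportional_burial",
    "psee_profile",
    "profile_sequence",
    "mean_psee_by_label",
    "midpoint_threshold",
    "classify_by_threshold",
    "region_mean_psee",
    "sweep_contact_radius",
    "hydrophobicity_correlation",
]

ORDERED = "O"
DISORDERED = "D"
UNKNOWN = "X"

#: |PSEE| above this triggers a diagnostic log line (reactive-cysteine
#: contexts can produce outlying magnitudes); nothing is excluded here.
ABNORMAL_PSEE_MAGNITUDE = 10.0


@dataclass(frozen=True)
class PSEEConfig:
    """Tunable knobs of the PSEE computation.

    contact_radius
        Number of neighbors on each side of the target residue (2*CR
        partners total).  Default 9, the value that maximizes order/disorder
        separation in the reference analysis.
    symmetrize
        Average P(a,b) and P(b,a) instead of the as-printed row-major entry.
    clip_exposure
        Truncate proportional exposure into [0, 1] (predicted ASA can exceed
        the Gly-X-Gly reference area).
    normalize_by_count
        Divide by the actual partner count near sequence ends instead of the
        constant 2*CR.
    strict_alphabet
        Reject sequences containing non-standard residues outright instead
        of marking those positions unavailable.
    """

    contact_radius: int = 9
    symmetrize: bool = False
    clip_exposure: bool = True
    normalize_by_count: bool = False
    strict_alphabet: bool = False

    def __post_init__(self) -> None:
        if self.contact_radius < 1:
            raise ValueError("contact_radius must be >= 1")


@dataclass(frozen=True)
class ResidueProfile:
    """Per-residue record: position (1-based), residue, burial and PSEE.

    ``psee`` is ``None`` for positions whose residue is outside the standard
    alphabet; such positions are excluded from all downstream means.
    """

    position: int
    aa: str
    predicted_asa: float | None
    p_exp: float
    p_bur: float
    psee: float | None

    @property
    def available(self) -> bool:
        return self.psee is not None


@dataclass(frozen=True)
class ClassMeanSummary:
    """Mean PSEE per label class; midpoint threshold when exactly two classes."""

    class_means: dict[str, float]
    class_counts: dict[str, int]
    threshold: float | None = None


@dataclass(frozen=True)
class RegionRecord:
    """A contiguous labeled region with its mean PSEE and, for disordered
    regions, the IDR length stratum (<=5, 6-20, 21-40, >=41 residues)."""

    start: int
    end: int
    label: str
    mean_psee: float
    length_stratum: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CRSweepRecord:
    cr: int
    mean_ordered: float
    mean_disordered: float
    threshold: float
    acc: float
    ppv: float
    mcc: float


@dataclass(frozen=True)
class CRSweepResult:
    records: tuple[CRSweepRecord, ...]
    best_cr: int

    def record_for(self, cr: int) -> CRSweepRecord:
        for rec in self.records:
            if rec.cr == cr:
                return rec
        raise KeyError(cr)


# ---------------------------------------------------------------------------
# Exposure and burial


def proportional_exposure(
    aa: str, predicted_asa: float, table: ASANormalizationTable, clip: bool = True
) -> float:
    """Predicted ASA over the residue's Gly-X-Gly reference area.

    ASA predictors are unconstrained regressors, so the raw ratio can exceed
    1; with ``clip`` it is truncated into [0, 1] so that the complementary
    burial stays a proportion.
    """
    code = normalize_code(aa)
    if not math.isfinite(predicted_asa) or predicted_asa < 0:
        raise ValueError(f"predicted ASA must be a finite non-negative area, got {predicted_asa}")
    ratio = predicted_asa / table[code]
    if clip:
        ratio = min(max(ratio, 0.0), 1.0)
    return ratio


def proportional_burial(p_exp: float) -> float:
    """Complement of proportional exposure."""
    if not 0.0 <= p_exp <= 1.0:
        raise ValueError(f"proportional exposure must lie in [0, 1], got {p_exp}")
    return 1.0 - p_exp


# ---------------------------------------------------------------------------
# PSEE


def _encode_sequence(sequence: str, strict: bool) -> np.ndarray:
    """Map a sequence to alphabet indices, -1 for non-standard residues."""
    idx = np.empty(len(sequence), dtype=np.int64)
    for i, aa in enumerate(sequence):
        code = aa.upper()
        if code in _AA_INDEX:
            idx[i] = _AA_INDEX[code]
        elif strict:
            raise UnknownResidueError(
                f"non-standard residue {aa!r} at position {i + 1} (strict mode)"
            )
        else:
            idx[i] = -1
    if np.any(idx < 0):
        bad = int(np.sum(idx < 0))
        logger.warning(
            "%d non-standard residue position(s) marked unavailable", bad
        )
    return idx


def psee_profile(
    sequence: str,
    p_bur: Sequence[float],
    config: PSEEConfig | None = None,
    matrix: ContactEnergyMatrix | None = None,
    predicted_asa: Sequence[float] | None = None,
) -> list[ResidueProfile]:
    """Per-residue PSEE of a sequence given proportional burial values.

    The divisor is the constant 2*CR regardless of how many partners
    actually exist near the termini (set ``config.normalize_by_count`` for
    the per-count alternative).  Non-standard residues yield ``psee=None``
    and do not contribute as partners either.
    """
    if config is None:
        config = PSEEConfig()
    if matrix is None:
        from .tables import load_contact_energy_matrix

        matrix = load_contact_energy_matrix()
    L = len(sequence)
    if L < 1:
        raise ValueError("sequence must be non-empty")
    pbur = np.asarray(p_bur, dtype=float)
    if pbur.shape != (L,):
        raise ValueError(
            f"burial vector length {pbur.shape} does not match sequence length {L}"
        )
    if np.any(~np.isfinite(pbur)) or np.any(pbur < 0) or np.any(pbur > 1):
        raise ValueError("all burial values must lie in [0, 1]")
    if predicted_asa is not None and len(predicted_asa) != L:
        raise ValueError("predicted_asa length does not match sequence length")

    idx = _encode_sequence(sequence, config.strict_alphabet)
    P = matrix.values
    if config.symmetrize:
        P = 0.5 * (P + P.T)
    cr = config.contact_radius

    # partner term for position j, seen from a target of type a:
    # P[a, idx[j]] * pbur[j]; unavailable partners contribute 0.
    available = idx >= 0
    partner_idx = np.where(available, idx, 0)
    # E[a, j] = P[a, partner_j] * pbur_j, masked
    E = P[:, partner_idx] * np.where(available, pbur, 0.0)[None, :]

    # windowed sums over j in [i-cr, i+cr] \ {i}
    csum = np.concatenate([np.zeros((20, 1)), np.cumsum(E, axis=1)], axis=1)
    profiles: list[ResidueProfile] = []
    for i in range(L):
        aa = sequence[i].upper()
        asa_i = float(predicted_asa[i]) if predicted_asa is not None else None
        pe = 1.0 - float(pbur[i])
        if not available[i]:
            profiles.append(
                ResidueProfile(i + 1, sequence[i], asa_i, pe, float(pbur[i]), None)
            )
            continue
        a = idx[i]
        lo, hi = max(0, i - cr), min(L - 1, i + cr)
        window = csum[a, hi + 1] - csum[a, lo]
        window -= E[a, i]
        if config.normalize_by_count:
            count = (hi - lo + 1) - 1
            divisor = max(count, 1)
        else:
            divisor = 2 * cr
        value = float(pbur[i] * window / divisor)
        if abs(value) > ABNORMAL_PSEE_MAGNITUDE:
            logger.warning(
                "abnormal PSEE magnitude %.3f at position %d (%s)", value, i + 1, aa
            )
        profiles.append(
            ResidueProfile(i + 1, aa, asa_i, pe, float(pbur[i]), value)
        )
    return profiles


def profile_sequence(
    sequence: str,
    predicted_asa: Sequence[float],
    asa_table: ASANormalizationTable,
    config: PSEEConfig | None = None,
    matrix: ContactEnergyMatrix | None = None,
) -> list[ResidueProfile]:
    """Convenience path from predicted ASA (A^2) straight to PSEE profiles."""
    if config is None:
        config = PSEEConfig()
    if len(predicted_asa) != len(sequence):
        raise ValueError("ASA vector length does not match sequence length")
    p_bur = []
    for aa, asa in zip(sequence, predicted_asa):
        code = aa.upper()
        if code in _AA_INDEX:
            p_exp = proportional_exposure(code, float(asa), asa_table, clip=config.clip_exposure)
            if not 0.0 <= p_exp <= 1.0:
                raise ValueError(
                    f"proportional exposure {p_exp:.3f} outside [0, 1]; enable clip_exposure"
                )
            p_bur.append(proportional_burial(p_exp))
        else:
            p_bur.append(0.0)  # placeholder; position is marked unavailable anyway
    return psee_profile(sequence, p_bur, config, matrix, predicted_asa=predicted_asa)


# ---------------------------------------------------------------------------
# Class means, thresholds, regions


def mean_psee_by_label(
    profiles: Iterable[ResidueProfile], labels: Sequence[str]
) -> ClassMeanSummary:
    """Arithmetic mean PSEE per label class.

    Positions with unavailable PSEE or label ``X`` are excluded.  When the
    usable labels form exactly two classes the midpoint threshold between
    the two class means is reported as well.
    """
    profiles = list(profiles)
    if len(profiles) != len(labels):
        raise ValueError("labels must align with profiles")
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    requested = {lab for lab in labels if lab != UNKNOWN}
    for prof, lab in zip(profiles, labels):
        if lab == UNKNOWN or not prof.available:
            continue
        sums[lab] = sums.get(lab, 0.0) + prof.psee
        counts[lab] = counts.get(lab, 0) + 1
    empty = requested - set(counts)
    if empty or not counts:
        missing = ", ".join(sorted(empty)) or "(all labels unknown)"
        raise ValueError(f"no usable residues for class(es): {missing}")
    means = {lab: sums[lab] / counts[lab] for lab in counts}
    threshold = None
    if len(means) == 2:
        a, b = means.values()
        threshold = midpoint_threshold(a, b)
    return ClassMeanSummary(means, counts, threshold)


def midpoint_threshold(mean_a: float, mean_b: float) -> float:
    """Value equidistant from the two class means."""
    if not (math.isfinite(mean_a) and math.isfinite(mean_b)):
        raise ValueError("class means must be finite")
    return 0.5 * (mean_a + mean_b)


def classify_by_threshold(
    psee: Sequence[float | None], t: float
) -> list[str | None]:
    """Threshold classification: PSEE <= t (favorable side) is ordered.

    The boundary value is deterministically assigned to the ordered class;
    unavailable PSEE yields ``None``.
    """
    if not math.isfinite(t):
        raise ValueError("threshold must be finite")
    out: list[str | None] = []
    for v in psee:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            out.append(None)
        else:
            out.append(ORDERED if v <= t else DISORDERED)
    return out


_STRATA = ((5, "<=5"), (20, "6-20"), (40, "21-40"), (math.inf, ">=41"))


def idr_length_stratum(length: int) -> str:
    """Stratum name for a disordered region of the given length."""
    for bound, name in _STRATA:
        if length <= bound:
            return name
    raise AssertionError("unreachable")


def region_mean_psee(
    profiles: Sequence[ResidueProfile],
    regions: Iterable[tuple[int, int, str]],
) -> list[RegionRecord]:
    """Mean PSEE of contiguous labeled regions (1-based inclusive bounds)."""
    L = len(profiles)
    records = []
    for start, end, label in regions:
        if not (1 <= start <= end <= L):
            raise ValueError(f"region ({start}, {end}) invalid for sequence of length {L}")
        values = [p.psee for p in profiles[start - 1 : end] if p.available]
        if not values:
            raise ValueError(f"region ({start}, {end}) has no residues with available PSEE")
        stratum = (
            idr_length_stratum(end - start + 1) if label == DISORDERED else None
        )
        records.append(
            RegionRecord(start, end, label, float(np.mean(values)), stratum)
        )
    return records


# ---------------------------------------------------------------------------
# Contact-radius sweep


def sweep_contact_radius(
    dataset: Iterable[tuple[str, Sequence[float], Sequence[str]]],
    cr_range: Iterable[int],
    matrix: ContactEnergyMatrix | None = None,
    config: PSEEConfig | None = None,
) -> CRSweepResult:
    """Sweep CR over a labeled dataset and pick the MCC-maximizing radius.

    ``dataset`` yields ``(sequence, p_bur, labels)`` triples with labels in
    {O, D, X}.  For each CR, all PSEE profiles are recomputed, the midpoint
    threshold between the ordered and disordered class means is derived, and
    the threshold classification is scored (balanced accuracy, precision,
    MCC) against the labels.  Ties on MCC go to the smallest CR.
    """
    from .evaluate import balanced_accuracy, confusion_counts, mcc, precision

    dataset = list(dataset)
    crs = list(cr_range)
    if not crs:
        raise ValueError("cr_range must be non-empty")
    if len(set(crs)) != len(crs):
        raise ValueError("cr_range must not repeat CR values")
    all_labels = [lab for _, _, labels in dataset for lab in labels]
    present = set(all_labels) - {UNKNOWN}
    if present != {ORDERED, DISORDERED}:
        raise ValueError(
            f"dataset must contain both ordered and disordered residues, found {sorted(present)}"
        )
    base = config or PSEEConfig()
    records = []
    for cr in sorted(crs):
        cfg = replace(base, contact_radius=cr)
        flat_profiles: list[ResidueProfile] = []
        flat_labels: list[str] = []
        for sequence, p_bur, labels in dataset:
            if len(labels) != len(sequence):
                raise ValueError("labels must align with sequence")
            flat_profiles.extend(psee_profile(sequence, p_bur, cfg, matrix))
            flat_labels.extend(labels)
        summary = mean_psee_by_label(flat_profiles, flat_labels)
        threshold = summary.threshold
        predicted = classify_by_threshold([p.psee for p in flat_profiles], threshold)
        pred_kept, truth_kept = [], []
        for pred, truth in zip(predicted, flat_labels):
            if pred is None or truth == UNKNOWN:
                continue
            pred_kept.append(pred)
            truth_kept.append(truth)
        counts = confusion_counts(pred_kept, truth_kept)
        records.append(
            CRSweepRecord(
                cr=cr,
                mean_ordered=summary.class_means[ORDERED],
                mean_disordered=summary.class_means[DISORDERED],
                threshold=threshold,
                acc=balanced_accuracy(counts),
                ppv=precision(counts),
                mcc=mcc(counts),
            )
        )
    best = max(records, key=lambda r: (r.mcc, -r.cr))
    return CRSweepResult(tuple(records), best.cr)


# ---------------------------------------------------------------------------
# Hydrophobicity correlation


def hydrophobicity_correlation(
    per_aa_mean_psee: Mapping[str, float], hydro: HydrophobicityTable
) -> float:
    """Pearson correlation between per-residue-type mean PSEE and the
    hydrophobicity index (negative when favorable energy tracks
    hydrophobicity, as expected)."""
    aas = sorted(per_aa_mean_psee)
    if len(aas) < 3:
        raise ValueError("need mean PSEE for at least 3 amino-acid types")
    x = np.array([per_aa_mean_psee[aa] for aa in aas], dtype=float)
    y = np.array([hydro.index(aa) for aa in aas], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def mean_psee_by_amino_acid(
    profiles: Iterable[ResidueProfile],
) -> dict[str, float]:
    """Mean PSEE per residue type over all available positions."""
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for p in profiles:
        if not p.available:
            continue
        sums[p.aa] = sums.get(p.aa, 0.0) + p.psee
        counts[p.aa] = counts.get(p.aa, 0) + 1
    return {aa: sums[aa] / counts[aa] for aa in sums}
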