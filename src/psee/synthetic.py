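"""Labeled synthetic protein datasets for end-to-end testing.

Real ordered regions are enriched in hydrophobic residues and buried; real
disordered regions are enriched in hydrophilic residues and exposed.  The
generator emulates exactly that contrast: each sequence is a concatenation
of alternating ordered/disordered segments, residues are drawn from a
state-specific composition (hydrophobic-biased for ordered, hydrophilic-
biased for disordered), and each residue's relative exposure is drawn from
a state-specific Beta distribution (low mean for ordered, high for
disordered).  ASA is then exposure times the residue's Gly-X-Gly reference
area, so the exposure normalization recovers the sampled value exactly.

Everything is driven by a single integer seed and is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import FeatureSchema, terminal_indicator
from .energy import DISORDERED, ORDERED, PSEEConfig, psee_profile
from .io import AnnotationTrack, SequenceRecord
from .tables import AMINO_ACIDS, load_asa_normalization, load_hydrophobicity

__all__ = ["SyntheticSpec", "generate_dataset", "generate_feature_table"]


def _composition(bias_hydrophobic: bool, bias: float = 3.0) -> dict[str, float]:
    """Residue sampling weights with a ``bias``-fold preference for one class."""
    hydro = load_hydrophobicity()
    weights = {
        aa: (bias if (hydro.klass(aa) == hydro.HYDROPHOBIC) == bias_hydrophobic else 1.0)
        for aa in AMINO_ACIDS
    }
    total = sum(weights.values())
    return {aa: w / total for aa, w in weights.items()}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic dataset.

    Defaults give 24 sequences of 60-160 residues built from 5-40 residue
    segments; ordered segments sample hydrophobic residues three times as
    often as hydrophilic ones (reversed for disordered) and draw relative
    exposure from Beta distributions with means 0.25 (ordered) and 0.67
    (disordered), straddling the conventional 25% burial cut.
    """

    n_sequences: int = 24
    length_range: tuple[int, int] = (60, 160)
    segment_length_range: tuple[int, int] = (5, 40)
    ordered_composition: Mapping[str, float] = field(
        default_factory=lambda: _composition(bias_hydrophobic=True)
    )
    disordered_composition: Mapping[str, float] = field(
        default_factory=lambda: _composition(bias_hydrophobic=False)
    )
    ordered_exposure_mean: float = 0.25
    disordered_exposure_mean: float = 0.67
    exposure_concentration: float = 8.0
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be positive")
        lo, hi = self.length_range
        slo, shi = self.segment_length_range
        if not (1 <= lo <= hi) or not (1 <= slo <= shi):
            raise ValueError("length ranges must be non-empty and positive")
        for comp in (self.ordered_composition, self.disordered_composition):
            if abs(sum(comp.values()) - 1.0) > 1e-9:
                raise ValueError("composition weights must sum to 1")
        for mean in (self.ordered_exposure_mean, self.disordered_exposure_mean):
            if not 0.0 < mean < 1.0:
                raise ValueError("exposure means must lie strictly inside (0, 1)")
        if self.exposure_concentration <= 0:
            raise ValueError("exposure concentration must be positive")


def _beta_params(mean: float, concentration: float) -> tuple[float, float]:
    return mean * concentration, (1.0 - mean) * concentration


def generate_dataset(
    spec: SyntheticSpec | None = None,
) -> list[tuple[SequenceRecord, list[float], AnnotationTrack]]:
    """Generate ``(sequence, per-residue ASA, O/D annotation)`` triples."""
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    asa_table = load_asa_normalization()
    comps = {
        ORDERED: spec.ordered_composition,
        DISORDERED: spec.disordered_composition,
    }
    beta = {
        ORDERED: _beta_params(spec.ordered_exposure_mean, spec.exposure_concentration),
        DISORDERED: _beta_params(spec.disordered_exposure_mean, spec.exposure_concentration),
    }
    dataset = []
    for k in range(spec.n_sequences):
        target_len = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        state = ORDERED if rng.random() < 0.5 else DISORDERED
        residues: list[str] = []
        labels: list[str] = []
        asa: list[float] = []
        while len(residues) < target_len:
            seg_len = int(
                rng.integers(
                    spec.segment_length_range[0], spec.segment_length_range[1] + 1
                )
            )
            seg_len = min(seg_len, target_len - len(residues))
            comp = comps[state]
            aas = rng.choice(list(comp), size=seg_len, p=list(comp.values()))
            a, b = beta[state]
            exposure = rng.beta(a, b, size=seg_len)
            for aa, exp in zip(aas, exposure):
                residues.append(str(aa))
                labels.append(state)
                asa.append(float(exp) * asa_table[str(aa)])
            state = DISORDERED if state == ORDERED else ORDERED
        seq_id = f"synth{k + 1:03d}"
        dataset.append(
            (
                SequenceRecord(seq_id, "".join(residues)),
                asa,
                AnnotationTrack(seq_id, "".join(labels)),
            )
        )
    return dataset


def generate_feature_table(
    dataset: Sequence[tuple[SequenceRecord, Sequence[float], AnnotationTrack]],
    schema: FeatureSchema,
    seed: int,
    label_correlation: float = 0.25,
    config: PSEEConfig | None = None,
) -> list[pd.DataFrame]:
    """Per-sequence feature tables matching ``schema``.

    The ``psee`` and ``terminal`` columns are genuinely computed; every
    other column is standard-normal noise shifted by ``+label_correlation``
    for disordered and ``-label_correlation`` for ordered residues — a
    stand-in for the externally predicted features of a real pipeline that
    preserves the geometry the classifier sees.
    """
    rng = np.random.default_rng(seed)
    config = config or PSEEConfig()
    asa_table = load_asa_normalization()
    tables = []
    for record, asa, track in dataset:
        if len(asa) != len(record) or len(track.symbols) != len(record):
            raise ValueError(
                f"ASA/annotation length mismatch for sequence {record.id!r}"
            )
        L = len(record)
        p_bur = [
            1.0 - min(a / asa_table[aa], 1.0)
            for aa, a in zip(record.sequence, asa)
        ]
        profiles = psee_profile(record.sequence, p_bur, config)
        shift = np.where(
            np.array(list(track.symbols)) == DISORDERED,
            label_correlation,
            -label_correlation,
        )
        data = {}
        for name in schema.feature_names:
            if name == "psee":
                data[name] = [p.psee if p.available else 0.0 for p in profiles]
            elif name == "terminal":
                data[name] = [terminal_indicator(i, L) for i in range(1, L + 1)]
            else:
                data[name] = rng.normal(0.0, 1.0, size=L) + shift
        tables.append(pd.DataFrame(data, columns=list(schema.feature_names)))
    return tables
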