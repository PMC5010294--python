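"""Packaged residue-level data tables.

Three small tables ship with the package as human-diffable TSV resources:

* a 20 x 20 pairwise contact-energy matrix (dimensionless statistical
  potential; row = target residue, column = contact partner),
* per-residue reference accessible surface areas in the Gly-X-Gly extended
  tripeptide state (A^2), used to normalize predicted ASA into a relative
  exposure, and
* a hydrophobicity index with the conventional 10/10 split of the alphabet
  into hydrophobic and hydrophilic residues.

The contact matrix is kept exactly as printed in its source, including a
handful of asymmetric cells; :func:`lookup_energy` offers symmetrization as
an explicit opt-in, and :func:`matrix_asymmetry_report` enumerates the
asymmetric pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "ContactEnergyMatrix",
    "ASANormalizationTable",
    "HydrophobicityTable",
    "load_contact_energy_matrix",
    "lookup_energy",
    "matrix_asymmetry_report",
    "load_asa_normalization",
    "load_hydrophobicity",
]

#: The 20 standard one-letter amino-acid codes, in the row/column order of
#: the packaged contact-energy matrix.
AMINO_ACIDS: str = "ARNDCQEGHILKMFPSTWYV"

_AA_SET = frozenset(AMINO_ACIDS)
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


class UnknownResidueError(ValueError):
    """An amino-acid code outside the 20-letter standard alphabet."""


def normalize_code(aa: str) -> str:
    """Uppercase a one-letter code and reject anything non-standard."""
    code = aa.upper() if isinstance(aa, str) else aa
    if not isinstance(code, str) or len(code) != 1 or code not in _AA_SET:
        raise UnknownResidueError(
            f"unknown amino-acid code {aa!r}; expected one of {AMINO_ACIDS}"
        )
    return code


@dataclass(frozen=True)
class ContactEnergyMatrix:
    """Pairwise contact potential P(target, partner) over the 20 residues.

    ``values[i, j]`` is the energy of the ordered pair
    ``(AMINO_ACIDS[i], AMINO_ACIDS[j])`` with the target residue indexing
    the row.
    """

    values: np.ndarray
    alphabet: str = AMINO_ACIDS

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (20, 20):
            raise ValueError(f"contact matrix must be 20x20, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("contact matrix contains non-finite entries")
        object.__setattr__(self, "values", arr)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        target, partner = pair
        return float(
            self.values[_AA_INDEX[normalize_code(target)],
                        _AA_INDEX[normalize_code(partner)]]
        )

    @property
    def entries(self) -> dict[tuple[str, str], float]:
        """All 400 ordered-pair entries as a mapping."""
        return {
            (a, b): float(self.values[i, j])
            for i, a in enumerate(self.alphabet)
            for j, b in enumerate(self.alphabet)
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.alphabet), columns=list(self.alphabet)
        )


@dataclass(frozen=True)
class ASANormalizationTable:
    """Reference ASA per residue (A^2) in the Gly-X-Gly extended state."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != _AA_SET:
            raise ValueError("ASA table must cover exactly the 20 standard residues")
        if any(v <= 0 or not np.isfinite(v) for v in self.values.values()):
            raise ValueError("ASA reference areas must be strictly positive")

    def __getitem__(self, aa: str) -> float:
        return self.values[normalize_code(aa)]


@dataclass(frozen=True)
class HydrophobicityTable:
    """Hydrophobicity index plus the binary hydrophobic/hydrophilic split."""

    values: dict[str, float]
    partition: dict[str, str] = field(default_factory=dict)

    HYDROPHOBIC = "hydrophobic"
    HYDROPHILIC = "hydrophilic"

    def __post_init__(self) -> None:
        if set(self.values) != _AA_SET or set(self.partition) != _AA_SET:
            raise ValueError("hydrophobicity table must cover the 20 standard residues")
        classes = set(self.partition.values())
        if classes != {self.HYDROPHOBIC, self.HYDROPHILIC}:
            raise ValueError(f"bad partition classes: {classes}")

    def index(self, aa: str) -> float:
        return self.values[normalize_code(aa)]

    def klass(self, aa: str) -> str:
        return self.partition[normalize_code(aa)]


def _read_resource(name: str) -> str:
    ref = resources.files("psee.data").joinpath(name)
    try:
        return ref.read_text(encoding="utf-8")
    except (FileNotFoundError, OSError) as exc:  # pragma: no cover - packaging fault
        raise RuntimeError(f"packaged table resource {name!r} is missing or unreadable") from exc


def load_contact_energy_matrix() -> ContactEnergyMatrix:
    """Load the packaged 20 x 20 contact-energy matrix (as printed)."""
    text = _read_resource("contact_energies.tsv")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")[1:]
    if "".join(header) != AMINO_ACIDS:
        raise RuntimeError("contact-energy resource is corrupted: bad column header")
    rows: dict[str, list[float]] = {}
    for ln in lines[1:]:
        fields = ln.split("\t")
        rows[fields[0]] = [float(x) for x in fields[1:]]
    if "".join(rows) != AMINO_ACIDS or any(len(v) != 20 for v in rows.values()):
        raise RuntimeError("contact-energy resource is corrupted: bad row layout")
    return ContactEnergyMatrix(np.array([rows[aa] for aa in AMINO_ACIDS]))


def lookup_energy(
    matrix: ContactEnergyMatrix, target: str, partner: str, symmetrize: bool = False
) -> float:
    """Contact energy of an ordered residue pair.

    With ``symmetrize=False`` this is the as-printed entry at
    (target row, partner column); with ``symmetrize=True`` it is the mean of
    the (target, partner) and (partner, target) entries, which papers over
    the asymmetric cells of the printed matrix.
    """
    value = matrix[target, partner]
    if symmetrize:
        value = 0.5 * (value + matrix[partner, target])
    return value


def matrix_asymmetry_report(
    matrix: ContactEnergyMatrix, tol: float = 1e-9
) -> list[tuple[frozenset[str], float]]:
    """Unordered pairs whose two entries differ by more than ``tol``.

    Returns ``(pair, |delta|)`` sorted by descending delta (alphabetical pair
    order breaks exact ties) so the largest transcription-suspect cells come
    first.
    """
    report = []
    for i, a in enumerate(matrix.alphabet):
        for j in range(i + 1, 20):
            b = matrix.alphabet[j]
            delta = abs(matrix.values[i, j] - matrix.values[j, i])
            if delta > tol:
                report.append((frozenset((a, b)), float(delta)))
    report.sort(key=lambda item: (-item[1], sorted(item[0])))
    return report


def load_asa_normalization() -> ASANormalizationTable:
    """Load the packaged Gly-X-Gly reference ASA values (A^2)."""
    text = _read_resource("asa_reference.tsv")
    values: dict[str, float] = {}
    for ln in text.splitlines()[1:]:
        if not ln.strip():
            continue
        aa, val = ln.split("\t")
        values[aa] = float(val)
    return ASANormalizationTable(values)


def load_hydrophobicity() -> HydrophobicityTable:
    """Load the packaged hydrophobicity scale and residue partition."""
    text = _read_resource("hydrophobicity.tsv")
    values: dict[str, float] = {}
    partition: dict[str, str] = {}
    mapping = {"H": HydrophobicityTable.HYDROPHOBIC, "P": HydrophobicityTable.HYDROPHILIC}
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    for ln in lines[1:]:
        aa, idx, klass = ln.split("\t")
        values[aa] = float(idx)
        partition[aa] = mapping[klass]
    return HydrophobicityTable(values, partition)


def write_contact_energy_matrix(matrix: ContactEnergyMatrix, sink) -> None:
    """Write a matrix in the packaged TSV layout (used for round-trip checks)."""
    lines = ["\t" + "\t".join(matrix.alphabet)]
    for i, aa in enumerate(matrix.alphabet):
        lines.append(aa + "\t" + "\t".join(repr(float(v)) for v in matrix.values[i]))
    text = "\n".join(lines) + "\n"
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with open(sink, "w", encoding="utf-8") as fh:
            fh.write(text)


def read_contact_energy_matrix(source) -> ContactEnergyMatrix:
    """Read a matrix written by :func:`write_contact_energy_matrix`."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    alphabet = "".join(lines[0].split("\t")[1:])
    rows = {}
    for ln in lines[1:]:
        fields = ln.split("\t")
        rows[fields[0]] = [float(x) for x in fields[1:]]
    return ContactEnergyMatrix(
        np.array([rows[aa] for aa in alphabet]), alphabet=alphabet
    )
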