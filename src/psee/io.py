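"""File formats: FASTA sequences, annotation tracks, ASA tables, result tables.

Sequences and track-style annotations travel as FASTA (parsed with
Biopython); per-residue ASA values and all result tables are plain
delimited text.  Parsers validate eagerly and report the offending line or
position — nothing is silently coerced.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .energy import ResidueProfile
from .classify import DisorderPrediction

__all__ = [
    "SequenceRecord",
    "AnnotationTrack",
    "DISORDER_ALPHABET",
    "SECONDARY_STRUCTURE_ALPHABET",
    "read_fasta",
    "write_fasta",
    "read_annotation",
    "read_asa",
    "write_residue_table",
    "read_metric_table",
    "write_ranking_table",
]

DISORDER_ALPHABET = frozenset("ODX")
SECONDARY_STRUCTURE_ALPHABET = frozenset("HEC")

STANDARD_AA = frozenset("ARNDCQEGHILKMFPSTWYV")


class ParseError(ValueError):
    """Malformed input file; the message carries the line or position."""


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or not self.sequence:
            raise ValueError("sequence records need a non-empty id and sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AnnotationTrack:
    seq_id: str
    symbols: str


def _as_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    with open(source, encoding="utf-8") as fh:
        return fh.read()


def _header_lines(text: str) -> dict[str, int]:
    """1-based line number of each FASTA header, for error messages."""
    return {
        line[1:].split()[0] if len(line) > 1 else "": i
        for i, line in enumerate(text.splitlines(), start=1)
        if line.startswith(">")
    }


def read_fasta(source, strict_alphabet: bool = False) -> list[SequenceRecord]:
    """Parse FASTA into uppercased records, in file order.

    Multi-line sequences are joined and CR/LF endings tolerated.  With
    ``strict_alphabet`` any residue outside the 20 standard codes is a
    parse error; otherwise non-standard residues pass through for the
    energy layer to mark unavailable.
    """
    text = _as_text(source).replace("\r\n", "\n").replace("\r", "\n")
    if not text.strip():
        raise ParseError("empty FASTA input")
    if not text.lstrip().startswith(">"):
        raise ParseError("line 1: FASTA input must start with a '>' header")
    headers = _header_lines(text)
    records = []
    for rec in SeqIO.parse(_stdio.StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        line = headers.get(rec.id, "?")
        if not seq:
            raise ParseError(f"line {line}: record {rec.id!r} has no sequence")
        if strict_alphabet:
            for pos, aa in enumerate(seq, start=1):
                if aa not in STANDARD_AA:
                    raise ParseError(
                        f"record {rec.id!r} position {pos}: illegal residue {aa!r}"
                    )
        records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise ParseError("no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], sink, width: int = 60) -> None:
    lines = []
    for rec in records:
        lines.append(f">{rec.id}")
        lines.extend(rec.sequence[i : i + width] for i in range(0, len(rec.sequence), width))
    text = "\n".join(lines) + "\n"
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with open(sink, "w", encoding="utf-8") as fh:
            fh.write(text)


def read_annotation(
    source,
    alphabet: frozenset[str] = DISORDER_ALPHABET,
    paired: Mapping[str, int] | None = None,
    symbol_map: Mapping[str, str] | None = None,
    seq_id: str = "track",
) -> list[AnnotationTrack]:
    """Read per-residue annotation tracks.

    Accepts either FASTA-like input (one ``>id`` header per track) or a
    bare two-column ``position symbol`` layout describing a single track
    (named by ``seq_id``).  ``alphabet`` is the allowed symbol set
    ({O, D, X} for disorder, {H, E, C} for secondary structure).
    ``symbol_map`` translates variant encodings (e.g. DisProt-style '-'
    for ordered) before validation.  ``paired`` maps seq_id to the
    expected sequence length; a mismatching track is a domain error
    naming the id.
    """
    text = _as_text(source).replace("\r\n", "\n").replace("\r", "\n")
    if text.strip() and not text.lstrip().startswith(">"):
        text = _positional_track_as_fasta(text, seq_id)
    tracks = []
    for rec in SeqIO.parse(_stdio.StringIO(text), "fasta"):
        symbols = str(rec.seq).upper()
        if symbol_map:
            symbols = "".join(symbol_map.get(s, s) for s in symbols)
        for pos, s in enumerate(symbols, start=1):
            if s not in alphabet:
                raise ParseError(
                    f"track {rec.id!r} position {pos}: symbol {s!r} not in "
                    f"alphabet {{{','.join(sorted(alphabet))}}}"
                )
        if paired is not None:
            expected = paired.get(rec.id)
            if expected is not None and expected != len(symbols):
                raise ValueError(
                    f"track {rec.id!r} has {len(symbols)} symbols but the paired "
                    f"sequence has {expected} residues"
                )
        tracks.append(AnnotationTrack(rec.id, symbols))
    if not tracks:
        raise ParseError("no annotation tracks found")
    return tracks


def _positional_track_as_fasta(text: str, seq_id: str) -> str:
    """Normalize a two-column (position, symbol) track to FASTA-like form."""
    symbols: dict[int, str] = {}
    for lineno, ln in enumerate(text.splitlines(), start=1):
        if not ln.strip() or ln.lstrip().startswith("#"):
            continue
        fields = ln.split()
        if len(fields) != 2:
            raise ParseError(f"line {lineno}: expected 'position symbol', got {ln!r}")
        try:
            pos = int(fields[0])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: bad position {fields[0]!r}") from exc
        if pos in symbols:
            raise ParseError(f"line {lineno}: duplicate position {pos}")
        symbols[pos] = fields[1]
    if sorted(symbols) != list(range(1, len(symbols) + 1)):
        raise ParseError("positional track must cover positions 1..N contiguously")
    return f">{seq_id}\n" + "".join(symbols[i] for i in sorted(symbols)) + "\n"


def read_asa(source, length: int) -> list[float]:
    """Per-residue ASA values in A^2, either bare one-per-line or
    (position, value) pairs; exactly ``length`` finite non-negative values."""
    text = _as_text(source)
    lines = [ln.strip() for ln in text.splitlines()]
    lines = [(i, ln) for i, ln in enumerate(lines, start=1) if ln and not ln.startswith("#")]
    values: dict[int, float] = {}
    positional = None
    for lineno, ln in lines:
        fields = ln.split()
        if positional is None:
            positional = len(fields) == 1
        if len(fields) != (1 if positional else 2):
            raise ParseError(f"line {lineno}: mixed ASA dialects")
        try:
            if positional:
                pos, value = len(values) + 1, float(fields[0])
            else:
                pos, value = int(fields[0]), float(fields[1])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-numeric ASA entry {ln!r}") from exc
        if not value >= 0:
            raise ParseError(f"line {lineno}: negative ASA value {value}")
        if pos in values:
            raise ParseError(f"line {lineno}: duplicate position {pos}")
        values[pos] = value
    missing = sorted(set(range(1, length + 1)) - set(values))
    extra = sorted(set(values) - set(range(1, length + 1)))
    if missing or extra:
        raise ParseError(
            f"ASA table does not cover positions 1..{length}: "
            f"missing {missing[:5]}, unexpected {extra[:5]}"
        )
    return [values[i] for i in range(1, length + 1)]


def _fmt(value: float | None) -> str:
    return "NA" if value is None else f"{value:.4f}"


def write_residue_table(
    profiles: Mapping[str, Sequence[ResidueProfile]],
    sink,
    predictions: Mapping[str, Sequence[DisorderPrediction]] | None = None,
    labels: Mapping[str, Sequence[str | None]] | None = None,
) -> None:
    """Tab-delimited per-residue table; floats at 4 decimals, gaps as NA."""
    header = [
        "seq_id", "position", "aa", "asa", "p_exp", "p_bur", "psee",
        "raw_prob", "rescaled_prob", "label",
    ]
    rows = ["\t".join(header)]
    for seq_id, profs in profiles.items():
        preds = predictions.get(seq_id) if predictions else None
        labs = labels.get(seq_id) if labels else None
        for i, p in enumerate(profs):
            pred = preds[i] if preds is not None else None
            if labs is not None:
                label = labs[i] or "NA"
            elif pred is not None:
                label = pred.label
            else:
                label = "NA"
            rows.append(
                "\t".join(
                    [
                        seq_id,
                        str(p.position),
                        p.aa,
                        _fmt(p.predicted_asa),
                        _fmt(p.p_exp),
                        _fmt(p.p_bur),
                        _fmt(p.psee),
                        _fmt(pred.raw_probability if pred else None),
                        _fmt(pred.rescaled_probability if pred else None),
                        label,
                    ]
                )
            )
    text = "\n".join(rows) + "\n"
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with open(sink, "w", encoding="utf-8") as fh:
            fh.write(text)


def read_residue_table(source) -> pd.DataFrame:
    return pd.read_csv(source, sep="\t", na_values=["NA"])


def read_metric_table(source) -> pd.DataFrame:
    """Predictor-name + acc/ppv/mcc/auc columns, one row per predictor."""
    df = pd.read_csv(source, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    if "predictor" not in df.columns:
        raise ParseError("metric table must have a 'predictor' column")
    return df.set_index("predictor")


def write_ranking_table(ranking: pd.DataFrame, sink) -> None:
    """Ranking output in the metric-table layout plus rank/S_c columns."""
    out = ranking.reset_index(names="predictor")
    out.to_csv(sink, sep="\t", index=False, float_format="%.4f")
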