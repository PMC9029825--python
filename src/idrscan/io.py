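"""Readers and writers for the plain-text formats the pipeline touches.

Four dialects are supported:

* multi-record FASTA (accession = first header token, NCBI convention);
* per-residue disorder score tables in the IUPred server layout
  (optional ``#`` comments, then ``POS<TAB>RES<TAB>SCORE`` with 1-based,
  consecutive positions);
* identification tables mapping accessions to experimental group and
  heat treatment;
* annotation tables mapping accessions to functional categories.

Delimited tables accept tab or comma on input (sniffed from the header
line); everything written out is tab-separated.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import validate_sequence

DEFAULT_GROUPS = ("NCA", "CA")
DEFAULT_TREATMENTS = ("heated", "non-heated")


@dataclass(frozen=True)
class ProteinRecord:
    """One identified protein: accession, free-text description, sequence."""

    accession: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.accession}: sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ScoreTrack:
    """Per-residue disorder scores in [0, 1] aligned to one sequence.

    ``residues`` keeps the residue column of the score table (when read
    from file) so the track can be cross-checked against its FASTA
    sequence before use.
    """

    accession: str
    scores: np.ndarray
    residues: str | None = field(default=None)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or self.scores.size == 0:
            raise ValueError(f"{self.accession}: scores must be a non-empty vector")
        if np.any((self.scores < 0.0) | (self.scores > 1.0)):
            raise ValueError(f"{self.accession}: scores must lie in [0, 1]")
        if self.residues is not None and len(self.residues) != self.scores.size:
            raise ValueError(f"{self.accession}: residue column length mismatch")

    def __len__(self) -> int:
        return int(self.scores.size)

    def check_sequence(self, sequence: str) -> None:
        """Verify the track aligns with *sequence* (length and, when the
        residue column is present, letter-by-letter identity)."""
        if len(sequence) != len(self):
            raise ValueError(
                f"{self.accession}: track length {len(self)} != sequence "
                f"length {len(sequence)}"
            )
        if self.residues is not None:
            for pos, (a, b) in enumerate(zip(self.residues, sequence), start=1):
                if a != b:
                    raise ValueError(
                        f"{self.accession}: residue mismatch at position {pos}: "
                        f"track has {a!r}, sequence has {b!r}"
                    )


def _as_text_handle(source: str | Path | TextIO) -> tuple[TextIO, bool]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8"), True
    return source, False


def read_fasta(
    source: str | Path | TextIO, strict: bool = False
) -> list[ProteinRecord]:
    """Parse a multi-record FASTA into :class:`ProteinRecord` objects.

    Sequences are whitespace-stripped and uppercased; the accession is the
    first whitespace-delimited header token, the remainder the description.
    Duplicate accessions and headers without sequence lines are errors.
    """
    handle, close = _as_text_handle(source)
    try:
        records: list[ProteinRecord] = []
        seen: dict[str, int] = {}
        for seq_record in SeqIO.parse(handle, "fasta"):
            sequence = str(seq_record.seq).upper().replace(" ", "")
            if not sequence:
                raise ValueError(
                    f"FASTA header {seq_record.id!r} has no sequence lines"
                )
            validate_sequence(sequence, strict=strict)
            description = seq_record.description[len(seq_record.id) :].strip()
            records.append(ProteinRecord(seq_record.id, description, sequence))
            seen[seq_record.id] = seen.get(seq_record.id, 0) + 1
        duplicates = sorted(acc for acc, n in seen.items() if n > 1)
        if duplicates:
            raise ValueError(f"duplicate accessions in FASTA: {duplicates}")
        return records
    finally:
        if close:
            handle.close()


def write_fasta(
    records: Iterable[ProteinRecord], dest: str | Path | TextIO, width: int = 60
) -> None:
    """Write records as wrapped FASTA (``>accession description``)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.description)
        for r in records
    ]
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8") as handle:
            _write_fasta_handle(seq_records, handle, width)
    else:
        _write_fasta_handle(seq_records, dest, width)


def _write_fasta_handle(
    seq_records: list[SeqRecord], handle: TextIO, width: int
) -> None:
    for rec in seq_records:
        header = rec.id if not rec.description.strip() else rec.description
        if not header.startswith(rec.id):
            header = f"{rec.id} {rec.description}".strip()
        handle.write(f">{header}\n")
        seq = str(rec.seq)
        for start in range(0, len(seq), width):
            handle.write(seq[start : start + width] + "\n")


def read_score_table(
    source: str | Path | TextIO, accession: str = ""
) -> ScoreTrack:
    """Parse an IUPred-style ``position residue score`` table.

    Lines starting with ``#`` are comments.  Positions must be 1-based and
    consecutive; scores must lie in [0, 1].  The residue column is kept on
    the returned track for later cross-checking against the sequence.
    """
    handle, close = _as_text_handle(source)
    try:
        scores: list[float] = []
        residues: list[str] = []
        expected_pos = 1
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(
                    f"line {lineno}: expected 'position residue score', got {line!r}"
                )
            pos = int(parts[0])
            if pos != expected_pos:
                raise ValueError(
                    f"line {lineno}: non-consecutive position {pos} "
                    f"(expected {expected_pos})"
                )
            score = float(parts[2])
            if not 0.0 <= score <= 1.0:
                raise ValueError(
                    f"line {lineno}: score {score} outside [0, 1]"
                )
            residues.append(parts[1].upper())
            scores.append(score)
            expected_pos += 1
        if not scores:
            raise ValueError("score table contains no data lines")
        return ScoreTrack(accession, np.array(scores), "".join(residues))
    finally:
        if close:
            handle.close()


def write_score_table(
    track: ScoreTrack, dest: str | Path | TextIO, sequence: str | None = None
) -> None:
    """Serialize a track in the same ``POS RES SCORE`` layout it is read from."""
    residues = track.residues or sequence
    if residues is None:
        residues = "X" * len(track)
    lines = [f"# {track.accession}\n"] + [
        f"{i}\t{aa}\t{s:.4f}\n"
        for i, (aa, s) in enumerate(zip(residues, track.scores), start=1)
    ]
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8") as handle:
            handle.writelines(lines)
    else:
        dest.writelines(lines)


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _read_delimited(source: str | Path | TextIO) -> pd.DataFrame:
    handle, close = _as_text_handle(source)
    try:
        text = handle.read()
    finally:
        if close:
            handle.close()
    if not text.strip():
        raise ValueError("empty table")
    sep = _sniff_delimiter(text.splitlines()[0])
    return pd.read_csv(_io.StringIO(text), sep=sep, dtype=str).rename(
        columns=lambda c: c.strip().lower()
    )


def read_identification_table(
    source: str | Path | TextIO,
    groups: Sequence[str] = DEFAULT_GROUPS,
    treatments: Sequence[str] = DEFAULT_TREATMENTS,
) -> pd.DataFrame:
    """Read an identification list with columns accession/group/treatment.

    Group and treatment labels are validated against the configured
    vocabularies; duplicate rows are errors.
    """
    table = _read_delimited(source)
    required = {"accession", "group", "treatment"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"identification table missing columns: {sorted(missing)}")
    table = table[["accession", "group", "treatment"]].apply(
        lambda col: col.str.strip()
    )
    bad_groups = sorted(set(table["group"]) - set(groups))
    if bad_groups:
        raise ValueError(f"unknown group labels: {bad_groups} (allowed: {list(groups)})")
    bad_treat = sorted(set(table["treatment"]) - set(treatments))
    if bad_treat:
        raise ValueError(
            f"unknown treatment labels: {bad_treat} (allowed: {list(treatments)})"
        )
    dup = table.duplicated()
    if dup.any():
        first = table[dup].iloc[0]
        raise ValueError(
            "duplicate identification row: "
            f"({first['accession']}, {first['group']}, {first['treatment']})"
        )
    return table.reset_index(drop=True)


def read_annotation_table(source: str | Path | TextIO) -> pd.DataFrame:
    """Read an accession -> functional-category table (one row per pair)."""
    table = _read_delimited(source)
    required = {"accession", "category"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    table = table[["accession", "category"]].apply(lambda col: col.str.strip())
    if (table["category"] == "").any():
        raise ValueError("annotation table contains empty category labels")
    dup = table.duplicated()
    if dup.any():
        first = table[dup].iloc[0]
        raise ValueError(
            f"duplicate annotation row: ({first['accession']}, {first['category']})"
        )
    return table.reset_index(drop=True)


def write_table(table: pd.DataFrame, dest: str | Path | TextIO) -> None:
    """Write a result table as TSV with 2-decimal rounding of float columns."""
    out = table.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(2)
    out.to_csv(dest, sep="\t", index=False)
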