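"""Per-protein disorder metrics and classification.

A residue is called disordered when its per-residue score reaches the
cutoff (0.5, inclusive).  From the thresholded track the module derives:

* *percental disorder* (overall disorder rate): the percentage of
  disordered residues in the chain;
* *mean disorder*: the arithmetic mean of the raw scores;
* a four-band label — ordered (OP, < 10%), nearly ordered (NOP, 10–30%),
  partially disordered (PDP, 30–70%), mostly disordered (MDP, >= 70%);
* *long IDRs*: maximal runs of at least 20 consecutive disordered
  residues, reported as 1-based inclusive segments.

The band boundary wording in the literature is ambiguous about which
band owns the 10/30/70 points; the default convention assigns each bound
to the more-disordered band ([0,10), [10,30), [30,70), [70,100]) and an
``upper`` convention flag flips this to ([0,10], (10,30], (30,70],
(70,100]).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ProteinRecord, ScoreTrack

#: Band labels ordered from least to most disordered.
BANDS = ("OP", "NOP", "PDP", "MDP")


@dataclass(frozen=True)
class DisorderThresholds:
    """Thresholds driving residue calls, band labels and IDR detection.

    residue_cutoff
        Score at or above which a residue counts as disordered.
    band_bounds
        The three percental-disorder boundaries between OP/NOP/PDP/MDP.
    min_idr_length
        Minimum run length (residues) for a long IDR.
    boundary_convention
        ``"lower"``: a bound belongs to the more-disordered band;
        ``"upper"``: a bound belongs to the less-disordered band.
    """

    residue_cutoff: float = 0.5
    band_bounds: tuple[float, float, float] = (10.0, 30.0, 70.0)
    min_idr_length: int = 20
    boundary_convention: str = "lower"

    def __post_init__(self) -> None:
        if not 0.0 < self.residue_cutoff < 1.0:
            raise ValueError("residue_cutoff must lie in (0, 1)")
        b = self.band_bounds
        if not (0.0 < b[0] < b[1] < b[2] < 100.0):
            raise ValueError("band_bounds must be strictly increasing within (0, 100)")
        if self.min_idr_length < 1:
            raise ValueError("min_idr_length must be >= 1")
        if self.boundary_convention not in ("lower", "upper"):
            raise ValueError("boundary_convention must be 'lower' or 'upper'")


DEFAULT_THRESHOLDS = DisorderThresholds()


@dataclass(frozen=True)
class IDRSegment:
    """A long disordered region, 1-based inclusive coordinates."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid segment ({self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class DisorderSummary:
    """All per-protein disorder metrics for one accession."""

    accession: str
    length: int
    mean_disorder: float
    disorder_rate: float
    band: str
    long_idrs: list[IDRSegment] = field(default_factory=list)

    @property
    def n_long_idrs(self) -> int:
        return len(self.long_idrs)


def residue_is_disordered(
    score: float, thresholds: DisorderThresholds = DEFAULT_THRESHOLDS
) -> bool:
    """True iff *score* meets the residue cutoff (inclusive)."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [0, 1]")
    return score >= thresholds.residue_cutoff


def _disordered_mask(
    track: ScoreTrack, thresholds: DisorderThresholds
) -> np.ndarray:
    if len(track) == 0:
        raise ValueError(f"{track.accession}: empty score track")
    return track.scores >= thresholds.residue_cutoff


def disorder_rate(
    track: ScoreTrack, thresholds: DisorderThresholds = DEFAULT_THRESHOLDS
) -> float:
    """Percental disorder: 100 x disordered residues / chain length."""
    mask = _disordered_mask(track, thresholds)
    return 100.0 * int(mask.sum()) / len(track)


def mean_disorder(track: ScoreTrack) -> float:
    """Arithmetic mean of the per-residue scores."""
    if len(track) == 0:
        raise ValueError(f"{track.accession}: empty score track")
    return float(np.mean(track.scores))


def classify_band(
    rate: float, thresholds: DisorderThresholds = DEFAULT_THRESHOLDS
) -> str:
    """Map a percental-disorder value to its band label."""
    if not 0.0 <= rate <= 100.0:
        raise ValueError(f"disorder rate {rate} outside [0, 100]")
    b1, b2, b3 = thresholds.band_bounds
    if thresholds.boundary_convention == "lower":
        if rate < b1:
            return "OP"
        if rate < b2:
            return "NOP"
        if rate < b3:
            return "PDP"
        return "MDP"
    if rate <= b1:
        return "OP"
    if rate <= b2:
        return "NOP"
    if rate <= b3:
        return "PDP"
    return "MDP"


def find_long_idrs(
    track: ScoreTrack, thresholds: DisorderThresholds = DEFAULT_THRESHOLDS
) -> list[IDRSegment]:
    """Maximal runs of consecutive disordered residues of qualifying length.

    Returns disjoint segments sorted by start, 1-based inclusive.
    """
    mask = _disordered_mask(track, thresholds)
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]  # 0-based half-open runs
    return [
        IDRSegment(int(s) + 1, int(e))
        for s, e in zip(starts, ends)
        if e - s >= thresholds.min_idr_length
    ]


def summarize_protein(
    record: ProteinRecord,
    track: ScoreTrack,
    thresholds: DisorderThresholds = DEFAULT_THRESHOLDS,
) -> DisorderSummary:
    """Compute all per-protein metrics for one record/track pair."""
    if len(record) != len(track):
        raise ValueError(
            f"{record.accession}: sequence length {len(record)} != "
            f"track length {len(track)}"
        )
    rate = disorder_rate(track, thresholds)
    return DisorderSummary(
        accession=record.accession,
        length=len(record),
        mean_disorder=mean_disorder(track),
        disorder_rate=rate,
        band=classify_band(rate, thresholds),
        long_idrs=find_long_idrs(track, thresholds),
    )


def summarize_proteome(
    records: Sequence[ProteinRecord],
    tracks: Mapping[str, ScoreTrack] | Sequence[ScoreTrack],
    thresholds: DisorderThresholds = DEFAULT_THRESHOLDS,
) -> list[DisorderSummary]:
    """Summarize every record against its track (matched by accession)."""
    if not isinstance(tracks, Mapping):
        tracks = {t.accession: t for t in tracks}
    missing = [r.accession for r in records if r.accession not in tracks]
    if missing:
        raise ValueError(f"no score track for accessions: {missing[:5]}")
    return [summarize_protein(r, tracks[r.accession], thresholds) for r in records]


def summaries_to_frame(summaries: Iterable[DisorderSummary]) -> pd.DataFrame:
    """Tabulate summaries, one row per protein; segments joined as
    semicolon-separated ``start-end`` spans."""
    rows = [
        {
            "accession": s.accession,
            "length": s.length,
            "mean_disorder": s.mean_disorder,
            "disorder_rate": s.disorder_rate,
            "band": s.band,
            "n_long_idrs": s.n_long_idrs,
            "long_idrs": ";".join(f"{seg.start}-{seg.end}" for seg in s.long_idrs),
        }
        for s in summaries
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "accession",
            "length",
            "mean_disorder",
            "disorder_rate",
            "band",
            "n_long_idrs",
            "long_idrs",
        ],
    )
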