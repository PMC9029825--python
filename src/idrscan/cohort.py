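"""Set algebra over identification lists and cohort-level count tables.

Identification experiments yield presence/absence sets of accessions per
experimental group (e.g. cold-acclimated vs not) and heat treatment.
This module partitions pairs of sets into exclusive/common parts,
tabulates disorder-band counts and long-IDR histograms per set, and
computes headline aggregate fractions such as the share of proteins that
are disordered or carry long IDRs.

A "unique protein" is a unique accession string; no sequence-identity
clustering is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .profile import BANDS, DisorderSummary


@dataclass
class SampleSet:
    """Accessions observed in one (group, treatment) cell."""

    group: str
    treatment: str
    accessions: set[str] = field(default_factory=set)

    @property
    def label(self) -> str:
        return f"{self.group}/{self.treatment}"

    def __len__(self) -> int:
        return len(self.accessions)


@dataclass
class PartitionResult:
    """Exclusive and shared accessions of two sets, with cardinalities."""

    only_a: set[str]
    only_b: set[str]
    common: set[str]

    @property
    def n_only_a(self) -> int:
        return len(self.only_a)

    @property
    def n_only_b(self) -> int:
        return len(self.only_b)

    @property
    def n_common(self) -> int:
        return len(self.common)

    @property
    def n_union(self) -> int:
        return self.n_only_a + self.n_only_b + self.n_common


def partition(a: SampleSet | set[str], b: SampleSet | set[str]) -> PartitionResult:
    """Split two accession sets into A-only, B-only and common parts."""
    set_a = a.accessions if isinstance(a, SampleSet) else set(a)
    set_b = b.accessions if isinstance(b, SampleSet) else set(b)
    common = set_a & set_b
    return PartitionResult(only_a=set_a - common, only_b=set_b - common, common=common)


def partition_to_frame(result: PartitionResult, name_a: str, name_b: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "part": [f"only_{name_a}", f"only_{name_b}", "common", "union"],
            "count": [
                result.n_only_a,
                result.n_only_b,
                result.n_common,
                result.n_union,
            ],
        }
    )


def _index_summaries(
    summaries: Sequence[DisorderSummary],
) -> dict[str, DisorderSummary]:
    return {s.accession: s for s in summaries}


def _check_membership(
    summaries: Sequence[DisorderSummary], sets: Sequence[SampleSet]
) -> None:
    members = set().union(*(s.accessions for s in sets)) if sets else set()
    orphans = [s.accession for s in summaries if s.accession not in members]
    if orphans:
        raise ValueError(
            f"summaries for accessions absent from every sample set: {orphans[:5]}"
        )


def band_count_table(
    summaries: Sequence[DisorderSummary], sets: Sequence[SampleSet]
) -> pd.DataFrame:
    """Contingency table of disorder-band counts per sample set.

    Rows are bands (OP..MDP plus a ``total`` margin); columns are sample
    sets.  Column totals equal the cardinality of each set restricted to
    summarized accessions.
    """
    _check_membership(summaries, sets)
    by_acc = _index_summaries(summaries)
    table = pd.DataFrame(0, index=list(BANDS), columns=[s.label for s in sets])
    for sample in sets:
        for acc in sample.accessions:
            if acc in by_acc:
                table.loc[by_acc[acc].band, sample.label] += 1
    table.loc["total"] = table.sum(axis=0)
    return table


def long_idr_distribution(
    summaries: Sequence[DisorderSummary], band_subset: Iterable[str] = BANDS
) -> pd.DataFrame:
    """Histogram of proteins by number of long IDRs within each band.

    Rows are bands, columns the long-IDR count (0, 1, 2, ... up to the
    observed maximum — bins are open-ended because multidomain proteins
    can carry a dozen or more long disordered segments).
    """
    bands = [b for b in BANDS if b in set(band_subset)]
    max_n = max((s.n_long_idrs for s in summaries), default=0)
    table = pd.DataFrame(0, index=bands, columns=list(range(max_n + 1)))
    for s in summaries:
        if s.band in table.index:
            table.loc[s.band, s.n_long_idrs] += 1
    return table


def headline_disorder_fraction(
    band_counts: Mapping[str, int], nop_with_idr: int, total: int
) -> float:
    """Percentage of proteins that are MDP or PDP, or NOP with >= 1 long IDR.

    Returned unrounded; reporting layers round to the nearest integer
    percent.
    """
    mdp = int(band_counts.get("MDP", 0))
    pdp = int(band_counts.get("PDP", 0))
    nop = int(band_counts.get("NOP", 0))
    if not 0 <= nop_with_idr <= nop:
        raise ValueError(
            f"NOP-with-IDR count {nop_with_idr} inconsistent with NOP count {nop}"
        )
    if total <= 0 or mdp + pdp + nop > total:
        raise ValueError("band counts inconsistent with total")
    return 100.0 * (mdp + pdp + nop_with_idr) / total


def band_counts_from_summaries(
    summaries: Sequence[DisorderSummary],
) -> dict[str, int]:
    """Simple band -> protein-count tally over a summary collection."""
    counts = {band: 0 for band in BANDS}
    for s in summaries:
        counts[s.band] += 1
    return counts
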