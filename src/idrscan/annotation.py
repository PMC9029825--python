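"""Functional-category tallies for disorder-containing proteins.

The annotation table is a user-supplied accession -> category mapping
(collapsed from UniProt/Pfam/InterPro/GO by the table's author); a
protein may carry several categories and contributes one *hit* per
category, so total hits can exceed unique proteins.  Categories whose
hits fall below a percentage threshold of total hits (default 4%) are
folded into an ``Other`` bucket.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .profile import DisorderSummary

OTHER_LABEL = "Other"


@dataclass
class FunctionalTally:
    """Per-category hit counts over a protein subset, after folding."""

    counts: dict[str, int]
    folded: set[str] = field(default_factory=set)
    threshold: float = 4.0
    n_unannotated: int = 0

    @property
    def total_hits(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        total = self.total_hits
        rows = [
            {
                "category": cat,
                "hits": n,
                "percent": 100.0 * n / total if total else 0.0,
                "folded": cat == OTHER_LABEL,
            }
            for cat, n in sorted(
                self.counts.items(), key=lambda kv: (kv[0] == OTHER_LABEL, -kv[1], kv[0])
            )
        ]
        return pd.DataFrame(rows, columns=["category", "hits", "percent", "folded"])


def select_disorder_relevant(summaries: Iterable[DisorderSummary]) -> set[str]:
    """Accessions that are mostly/partially disordered or carry >= 1 long IDR."""
    return {
        s.accession
        for s in summaries
        if s.band in ("MDP", "PDP") or s.n_long_idrs >= 1
    }


def tally_functions(
    annotation: pd.DataFrame,
    subset: Sequence[str] | set[str],
    threshold: float = 4.0,
) -> FunctionalTally:
    """Tally category hits over *subset* and fold rare categories.

    Categories contributing fewer than *threshold* percent of total hits
    each are merged into ``Other``.  Subset members with no annotation
    row are counted separately, not treated as errors.
    """
    if not 0.0 < threshold < 100.0:
        raise ValueError(f"threshold {threshold} outside (0, 100)")
    subset = set(subset)
    hits = annotation[annotation["accession"].isin(subset)]
    annotated = set(hits["accession"])
    raw = hits.groupby("category").size().to_dict()
    total = sum(raw.values())
    counts: dict[str, int] = {}
    folded: set[str] = set()
    for cat, n in raw.items():
        if cat == OTHER_LABEL:
            # already-folded mass stays in the bucket; keeps folding idempotent
            counts[OTHER_LABEL] = counts.get(OTHER_LABEL, 0) + int(n)
        elif total and 100.0 * n / total < threshold:
            folded.add(cat)
            counts[OTHER_LABEL] = counts.get(OTHER_LABEL, 0) + n
        else:
            counts[cat] = int(n)
    return FunctionalTally(
        counts=counts,
        folded=folded,
        threshold=threshold,
        n_unannotated=len(subset - annotated),
    )
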