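"""Amino-acid composition per protein and aggregated per disorder band.

Counts run over the 20 canonical residues; nonstandard letters (B, Z, X,
U, O, J) are excluded from both numerator and denominator so fractions
stay comparable across proteins, and are reported in a diagnostics
column instead.  The disorder-/order-promoting split follows the
standard residue classes (see :mod:`idrscan.alphabet`).

Band aggregation averages per-protein fractions (each protein weighs
equally regardless of length); a pooled-counts mode is available behind
a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import CANONICAL, DISORDER_PROMOTING, NONSTANDARD_INDEX, encode
from .io import ProteinRecord
from .profile import BANDS

_DP_MASK = np.array([aa in DISORDER_PROMOTING for aa in CANONICAL])


@dataclass
class CompositionProfile:
    """Residue counts and fractions for one protein."""

    accession: str
    counts: np.ndarray  # 20 ints, CANONICAL order
    fractions: np.ndarray  # 20 floats, sum to 1 over counted residues
    dp_fraction: float  # % disorder-promoting
    op_fraction: float  # % order-promoting
    n_nonstandard: int = 0

    def fraction_of(self, residue: str) -> float:
        return float(self.fractions[CANONICAL.index(residue)])


def composition_profile(record: ProteinRecord) -> CompositionProfile:
    """Count canonical residues and derive fractions and dp/op percentages."""
    encoded = encode(record.sequence)
    counts = np.bincount(encoded, minlength=NONSTANDARD_INDEX + 1)
    n_nonstandard = int(counts[NONSTANDARD_INDEX])
    counts = counts[:NONSTANDARD_INDEX]
    total = int(counts.sum())
    if total == 0:
        raise ValueError(f"{record.accession}: no canonical residues to count")
    fractions = counts / total
    dp = 100.0 * float(fractions[_DP_MASK].sum())
    return CompositionProfile(
        accession=record.accession,
        counts=counts,
        fractions=fractions,
        dp_fraction=dp,
        op_fraction=100.0 - dp,
        n_nonstandard=n_nonstandard,
    )


def profiles_to_frame(profiles: Iterable[CompositionProfile]) -> pd.DataFrame:
    """One row per protein: 20 residue fractions plus dp/op percentages."""
    rows = []
    for p in profiles:
        row = {"accession": p.accession}
        row.update({aa: float(f) for aa, f in zip(CANONICAL, p.fractions)})
        row["dp_fraction"] = p.dp_fraction
        row["op_fraction"] = p.op_fraction
        row["n_nonstandard"] = p.n_nonstandard
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_by_band(
    profiles: Sequence[CompositionProfile],
    band_of: Mapping[str, str],
    pooled: bool = False,
) -> pd.DataFrame:
    """Mean residue fractions and dp/op percentages per disorder band.

    Default mode averages per-protein fractions; *pooled* instead sums
    raw counts within a band before normalizing.  Bands with no member
    proteins are omitted.
    """
    missing = [p.accession for p in profiles if p.accession not in band_of]
    if missing:
        raise ValueError(f"no band assignment for accessions: {missing[:5]}")
    rows = []
    for band in BANDS:
        members = [p for p in profiles if band_of[p.accession] == band]
        if not members:
            continue
        if pooled:
            counts = np.sum([p.counts for p in members], axis=0)
            fractions = counts / counts.sum()
            dp = 100.0 * float(fractions[_DP_MASK].sum())
        else:
            fractions = np.mean([p.fractions for p in members], axis=0)
            dp = float(np.mean([p.dp_fraction for p in members]))
        row = {"band": band, "n_proteins": len(members)}
        row.update({aa: float(f) for aa, f in zip(CANONICAL, fractions)})
        row["dp_fraction"] = dp
        row["op_fraction"] = 100.0 - dp
        rows.append(row)
    return pd.DataFrame(rows)


def residue_order_by_mdp_abundance(band_table: pd.DataFrame) -> list[str]:
    """Residues of each class sorted by their abundance in the MDP band,
    disorder-promoting class first (display order for composition tables)."""
    ref_band = "MDP" if (band_table["band"] == "MDP").any() else band_table["band"].iloc[-1]
    ref = band_table.set_index("band").loc[ref_band]
    dp = sorted(
        (aa for aa in CANONICAL if aa in DISORDER_PROMOTING),
        key=lambda aa: -float(ref[aa]),
    )
    op = sorted(
        (aa for aa in CANONICAL if aa not in DISORDER_PROMOTING),
        key=lambda aa: -float(ref[aa]),
    )
    return dp + op
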