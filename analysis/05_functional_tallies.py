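#!/usr/bin/env python
"""Functional categories of disorder-containing proteins.

Selects the disorder-relevant subset (mostly/partially disordered, or
carrying at least one long IDR), restricts it to the annotated part of
the proteome, and tallies functional-category hits for the whole subset
and for the heated / non-heated sample types separately.  Categories
under 4% of total hits fold into "Other".  Writes one tally table per
subset under results/.
"""

from pathlib import Path

import pandas as pd

from idrscan.annotation import tally_functions
from idrscan.io import read_annotation_table, read_identification_table, write_table

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"


def main() -> None:
    summary = pd.read_csv(RESULTS / "profile_run" / "protein_summary.tsv", sep="\t")
    relevant = set(
        summary[
            summary["band"].isin(["MDP", "PDP"]) | (summary["n_long_idrs"] >= 1)
        ]["accession"]
    )
    annotation = read_annotation_table(STUDY / "annotations.tsv")
    annotated = set(annotation["accession"])
    print(
        f"{len(relevant)} disorder-relevant proteins; "
        f"{len(relevant & annotated)} of them annotated"
    )

    ids = read_identification_table(STUDY / "ids.tsv")
    subsets = {"total": relevant}
    for treatment in ("heated", "non-heated"):
        members = set(ids[ids["treatment"] == treatment]["accession"])
        subsets[treatment.replace("-", "_")] = relevant & members

    for name, subset in subsets.items():
        tally = tally_functions(annotation, subset, threshold=4.0)
        table = tally.to_frame()
        write_table(table, RESULTS / f"functional_tally_{name}.tsv")
        top = table.head(3)
        print(f"{name}: {tally.total_hits} hits over {len(subset)} proteins, "
              f"{tally.n_unannotated} unannotated; top categories:")
        for _, row in top.iterrows():
            print(f"    {row['category']}: {row['hits']} hits ({row['percent']:.1f}%)")


if __name__ == "__main__":
    main()
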