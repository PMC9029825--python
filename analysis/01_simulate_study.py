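#!/usr/bin/env python
"""Simulate a two-cohort heat-enrichment proteomics study.

Generates a synthetic proteome with known disorder architecture, then
draws identification lists for two cohorts — a baseline cohort (NCA)
and a metabolically depressed cohort (CA, lower detection probability)
— each split into heated and non-heated sample types.  A bespoke
functional-annotation table covers part of the proteome.

Bulky inputs (FASTA, per-protein score tables) go to scratch/study/;
downstream scripts read them from there.
"""

from dataclasses import replace
from pathlib import Path

import numpy as np

from idrscan.io import write_fasta, write_score_table
from idrscan.synthetic import (
    SyntheticConfig,
    simulate_heat_enrichment,
    synthesize_proteome,
)

SEED = 42
ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "scratch" / "study"

CATEGORIES = [
    "Cytoskeleton",
    "Molecular chaperones",
    "Translation",
    "Protein and amino acid metabolism",
    "Nucleic acid binding",
    "Chitin binding and cuticle formation",
    "Carbohydrate metabolism",
    "Lipid metabolism",
    "Oxidoreduction",
    "Signal transduction",
]


def main() -> None:
    STUDY.mkdir(parents=True, exist_ok=True)
    (STUDY / "scores").mkdir(exist_ok=True)

    config = SyntheticConfig(seed=SEED)  # study-bed defaults: 500 proteins
    records, tracks, truths = synthesize_proteome(config)

    # cohorts: CA detects fewer proteins (depressed metabolism analogue)
    nca_cfg = config
    ca_cfg = replace(config, seed=SEED + 1, detection_prob=0.45)
    samples = []
    for group, cfg in (("NCA", nca_cfg), ("CA", ca_cfg)):
        heated, non_heated = simulate_heat_enrichment(truths, cfg, group=group)
        samples += [heated, non_heated]

    # sequences are only retrievable for identified proteins, so the FASTA
    # and score tables cover the union of the sample sets
    detected_accs = set().union(*(s.accessions for s in samples))
    records = [r for r in records if r.accession in detected_accs]
    tracks = [t for t in tracks if t.accession in detected_accs]
    write_fasta(records, STUDY / "proteins.fasta")
    for track in tracks:
        write_score_table(track, STUDY / "scores" / f"{track.accession}.scores.tsv")

    rows = ["accession\tgroup\ttreatment"]
    for sample in samples:
        rows += [
            f"{acc}\t{sample.group}\t{sample.treatment}"
            for acc in sorted(sample.accessions)
        ]
    (STUDY / "ids.tsv").write_text("\n".join(rows) + "\n")

    # annotate ~60% of the proteome; every third annotated protein gets a
    # second category so hits exceed unique proteins, as in real tallies
    annot_rng = np.random.default_rng(SEED + 100)
    annot = ["accession\tcategory"]
    n_annotated = 0
    for truth in truths:
        if annot_rng.random() < 0.6:
            cat = CATEGORIES[int(annot_rng.integers(len(CATEGORIES)))]
            annot.append(f"{truth.accession}\t{cat}")
            if n_annotated % 3 == 0:
                other = CATEGORIES[int(annot_rng.integers(len(CATEGORIES)))]
                if other != cat:
                    annot.append(f"{truth.accession}\t{other}")
            n_annotated += 1
    (STUDY / "annotations.tsv").write_text("\n".join(annot) + "\n")

    detected = set().union(*(s.accessions for s in samples))
    print(f"simulated proteome: {len(records)} proteins (seed {SEED})")
    print(f"identified in at least one sample: {len(detected)}")
    for sample in samples:
        print(f"  {sample.group}/{sample.treatment}: {len(sample)} proteins")
    print(f"annotated proteins: {n_annotated}")
    print(f"inputs written under {STUDY}")


if __name__ == "__main__":
    main()
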