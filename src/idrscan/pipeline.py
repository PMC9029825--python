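"""End-to-end orchestration: from input files to a directory of report tables.

``run_profile`` reads a FASTA, a directory of per-accession score
tables, an identification table and (optionally) an annotation table,
then writes every downstream result — per-protein disorder summaries,
band-count tables, long-IDR histograms, composition tables, pairwise
partition reports and functional tallies — plus a machine-readable
manifest recording input checksums and thresholds.  Identical inputs
and configuration produce byte-identical outputs.

The numbered scripts under ``analysis/`` are thin drivers over this
module and the rest of the library; they are the command-line surface
of the project.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import select_disorder_relevant, tally_functions
from .cohort import (
    SampleSet,
    band_count_table,
    long_idr_distribution,
    partition,
    partition_to_frame,
)
from .composition import aggregate_by_band, composition_profile, profiles_to_frame
from .io import (
    read_annotation_table,
    read_fasta,
    read_identification_table,
    read_score_table,
    write_table,
)
from .profile import (
    DEFAULT_THRESHOLDS,
    DisorderThresholds,
    summaries_to_frame,
    summarize_proteome,
)

logger = logging.getLogger("idrscan")


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run."""

    fasta: Path
    scores_dir: Path
    ids: Path
    out_dir: Path
    annotations: Path | None = None
    thresholds: DisorderThresholds = field(default_factory=DisorderThresholds)
    strict: bool = False
    tally_threshold: float = 4.0

    def __post_init__(self) -> None:
        for attr in ("fasta", "scores_dir", "ids", "out_dir"):
            setattr(self, attr, Path(getattr(self, attr)))
        if self.annotations is not None:
            self.annotations = Path(self.annotations)
        for path in (self.fasta, self.scores_dir, self.ids):
            if not path.exists():
                raise FileNotFoundError(f"input path does not exist: {path}")
        if self.annotations is not None and not self.annotations.exists():
            raise FileNotFoundError(f"annotation table does not exist: {self.annotations}")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _sample_sets(ids: pd.DataFrame) -> list[SampleSet]:
    sets = []
    for (group, treatment), rows in ids.groupby(["group", "treatment"], sort=True):
        sets.append(
            SampleSet(group=group, treatment=treatment, accessions=set(rows["accession"]))
        )
    return sets


def run_profile(config: RunConfig) -> Path:
    """Run the full pipeline; returns the output directory.

    On any failure partial outputs are removed so a run directory is
    either complete or absent.
    """
    out = config.out_dir
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _run_profile_inner(config, out)
    except Exception:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        raise


def _run_profile_inner(config: RunConfig, out: Path) -> Path:
    thresholds = config.thresholds
    records = read_fasta(config.fasta, strict=config.strict)
    logger.info("read %d protein records from %s", len(records), config.fasta)

    tracks = {}
    for record in records:
        track_path = config.scores_dir / f"{record.accession}.scores.tsv"
        if not track_path.exists():
            raise FileNotFoundError(
                f"no score table for accession {record.accession!r} "
                f"(expected {track_path})"
            )
        track = read_score_table(track_path, accession=record.accession)
        track.check_sequence(record.sequence)
        tracks[record.accession] = track

    summaries = summarize_proteome(records, tracks, thresholds)
    summary_frame = summaries_to_frame(summaries)
    write_table(summary_frame, out / "protein_summary.tsv")

    ids = read_identification_table(config.ids)
    sets = _sample_sets(ids)
    bands = band_count_table(summaries, sets)
    bands.insert(0, "band", bands.index)
    write_table(bands.reset_index(drop=True), out / "band_counts.tsv")

    idr_hist = long_idr_distribution(summaries)
    idr_hist.insert(0, "band", idr_hist.index)
    write_table(idr_hist.reset_index(drop=True), out / "long_idr_histogram.tsv")

    profiles = [composition_profile(r) for r in records]
    write_table(profiles_to_frame(profiles), out / "composition.tsv")
    band_of = {s.accession: s.band for s in summaries}
    write_table(aggregate_by_band(profiles, band_of), out / "band_composition.tsv")

    partition_frames = []
    for sample_a, sample_b in combinations(sets, 2):
        result = partition(sample_a, sample_b)
        frame = partition_to_frame(result, sample_a.label, sample_b.label)
        frame.insert(0, "comparison", f"{sample_a.label} vs {sample_b.label}")
        partition_frames.append(frame)
    if partition_frames:
        write_table(pd.concat(partition_frames, ignore_index=True), out / "partitions.tsv")

    if config.annotations is not None:
        annotation = read_annotation_table(config.annotations)
        relevant = select_disorder_relevant(summaries)
        subsets = {"total": relevant}
        for sample in sets:
            subsets[sample.label.replace("/", "_")] = relevant & sample.accessions
        for name, subset in subsets.items():
            tally = tally_functions(annotation, subset, config.tally_threshold)
            write_table(tally.to_frame(), out / f"functional_tally_{name}.tsv")
    else:
        logger.info("no annotation table supplied; skipping functional tallies")

    manifest = {
        "tool": "idrscan",
        "version": __version__,
        "inputs": {
            "fasta": {"path": str(config.fasta), "sha256": _sha256(config.fasta)},
            "ids": {"path": str(config.ids), "sha256": _sha256(config.ids)},
            "annotations": (
                {
                    "path": str(config.annotations),
                    "sha256": _sha256(config.annotations),
                }
                if config.annotations is not None
                else None
            ),
            "n_score_tables": len(tracks),
        },
        "thresholds": {
            "residue_cutoff": thresholds.residue_cutoff,
            "band_bounds": list(thresholds.band_bounds),
            "min_idr_length": thresholds.min_idr_length,
            "boundary_convention": thresholds.boundary_convention,
        },
        "n_proteins": len(records),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return out
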