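"""Synthetic proteomes with known disorder architecture.

Real identification lists from heat-enriched insect lysates are not
redistributable, so the test bed generates proteomes whose ground truth
is known by construction:

* each protein is an alternating sequence of ordered and disordered
  blocks with geometric block lengths;
* residues are drawn from block-specific frequency vectors — disordered
  blocks are rich in disorder-promoting residues (70% of probability
  mass by default), ordered blocks lean order-promoting (45%);
* the matching score track is the block's mean score (0.25 ordered,
  0.75 disordered by default) plus clamped Gaussian noise, so with zero
  noise the thresholded track reproduces the block architecture exactly;
* heat treatment is emulated as a survival filter whose probability is
  logistic in the protein's true disorder rate, composed with an
  independent detection draw — mirroring how boiling a lysate
  precipitates globular proteins and enriches heat-stable, largely
  disordered ones in the soluble fraction.

All draws derive from one global seed through named substreams, so
adding a new generator call never perturbs existing draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alphabet import CANONICAL, DISORDER_PROMOTING
from .cohort import SampleSet
from .io import ProteinRecord, ScoreTrack
from .profile import (
    DEFAULT_THRESHOLDS,
    DisorderThresholds,
    IDRSegment,
    classify_band,
)

_DP_LIST = [aa for aa in CANONICAL if aa in DISORDER_PROMOTING]
_OP_LIST = [aa for aa in CANONICAL if aa not in DISORDER_PROMOTING]

# substream ids: one fixed integer per purpose, appended to the root
# SeedSequence spawn key
_SUBSTREAMS = {
    "architecture": 0,
    "sequence": 1,
    "noise": 2,
    "detection": 3,
    "survival": 4,
}


def class_biased_frequencies(dp_mass: float) -> np.ndarray:
    """Residue frequencies placing *dp_mass* total probability on the
    disorder-promoting class, uniform within each class."""
    if not 0.0 < dp_mass < 1.0:
        raise ValueError("dp_mass must lie in (0, 1)")
    freqs = np.empty(len(CANONICAL))
    for i, aa in enumerate(CANONICAL):
        freqs[i] = dp_mass / 10.0 if aa in DISORDER_PROMOTING else (1 - dp_mass) / 10.0
    return freqs


@dataclass
class SyntheticConfig:
    """Generator settings; defaults describe a heat-enrichment study bed.

    Lengths are uniform over ``length_range``; block lengths are
    geometric with the given means; ``dp_mass_*`` set the probability
    mass on disorder-promoting residues per block type; score tracks are
    block means plus clamped N(0, score_noise_sd); the heated sample
    keeps a detected protein with probability
    ``logistic(survival_slope * (rate - survival_midpoint))``.
    """

    n_proteins: int = 500
    length_range: tuple[int, int] = (80, 600)
    p_start_disordered: float = 0.35
    mean_block_ordered: float = 120.0
    mean_block_disordered: float = 60.0
    dp_mass_disordered: float = 0.70
    dp_mass_ordered: float = 0.45
    score_mean_ordered: float = 0.25
    score_mean_disordered: float = 0.75
    score_noise_sd: float = 0.1
    detection_prob: float = 0.7
    survival_slope: float = 0.1
    survival_midpoint: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError("length_range must satisfy 1 <= min <= max")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        for mean in (self.mean_block_ordered, self.mean_block_disordered):
            if mean < 1:
                raise ValueError("mean block lengths must be >= 1")
        for p in (self.score_mean_ordered, self.score_mean_disordered):
            if not 0.0 < p < 1.0:
                raise ValueError("block score means must lie in (0, 1)")
        if self.score_noise_sd < 0:
            raise ValueError("score_noise_sd must be >= 0")
        if not 0.0 < self.detection_prob <= 1.0:
            raise ValueError("detection_prob must lie in (0, 1]")

    def rng(self, purpose: str) -> np.random.Generator:
        """Deterministic per-purpose substream of the global seed."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_SUBSTREAMS[purpose],))
        )


@dataclass
class ProteinTruth:
    """Ground-truth architecture for one synthetic protein."""

    accession: str
    blocks: list[tuple[int, int, bool]]  # (start, end, is_disordered), 1-based
    true_rate: float
    true_band: str
    true_long_idrs: list[IDRSegment]
    survival_prob: float

    @property
    def length(self) -> int:
        return self.blocks[-1][1]


def _draw_blocks(
    length: int, config: SyntheticConfig, rng: np.random.Generator
) -> list[tuple[int, int, bool]]:
    """Alternating ordered/disordered blocks covering 1..length."""
    blocks: list[tuple[int, int, bool]] = []
    disordered = bool(rng.random() < config.p_start_disordered)
    pos = 1
    while pos <= length:
        mean = (
            config.mean_block_disordered if disordered else config.mean_block_ordered
        )
        size = int(rng.geometric(1.0 / mean))
        end = min(pos + size - 1, length)
        blocks.append((pos, end, disordered))
        pos = end + 1
        disordered = not disordered
    return blocks


def _truth_from_blocks(
    accession: str,
    blocks: list[tuple[int, int, bool]],
    config: SyntheticConfig,
    thresholds: DisorderThresholds,
) -> ProteinTruth:
    length = blocks[-1][1]
    dis_residues = sum(e - s + 1 for s, e, d in blocks if d)
    rate = 100.0 * dis_residues / length
    idrs = [
        IDRSegment(s, e)
        for s, e, d in blocks
        if d and (e - s + 1) >= thresholds.min_idr_length
    ]
    z = np.clip(config.survival_slope * (rate - config.survival_midpoint), -500, 500)
    return ProteinTruth(
        accession=accession,
        blocks=blocks,
        true_rate=rate,
        true_band=classify_band(rate, thresholds),
        true_long_idrs=idrs,
        survival_prob=float(1.0 / (1.0 + np.exp(-z))),
    )


def synthesize_proteome(
    config: SyntheticConfig,
    thresholds: DisorderThresholds = DEFAULT_THRESHOLDS,
    accession_prefix: str = "SYN",
) -> tuple[list[ProteinRecord], list[ScoreTrack], list[ProteinTruth]]:
    """Generate records, matching score tracks and ground truth.

    Deterministic given ``config.seed``; with ``score_noise_sd = 0`` the
    thresholded tracks reproduce the planted architecture exactly.
    """
    arch_rng = config.rng("architecture")
    seq_rng = config.rng("sequence")
    noise_rng = config.rng("noise")
    freq_dis = class_biased_frequencies(config.dp_mass_disordered)
    freq_ord = class_biased_frequencies(config.dp_mass_ordered)
    aa_array = np.array(list(CANONICAL))

    records, tracks, truths = [], [], []
    width = max(4, len(str(config.n_proteins)))
    for idx in range(config.n_proteins):
        accession = f"{accession_prefix}{idx + 1:0{width}d}"
        length = int(arch_rng.integers(config.length_range[0], config.length_range[1] + 1))
        blocks = _draw_blocks(length, config, arch_rng)
        truth = _truth_from_blocks(accession, blocks, config, thresholds)

        seq_parts: list[str] = []
        score_parts: list[np.ndarray] = []
        for start, end, disordered in blocks:
            n = end - start + 1
            freqs = freq_dis if disordered else freq_ord
            seq_parts.append("".join(seq_rng.choice(aa_array, size=n, p=freqs)))
            mean = (
                config.score_mean_disordered
                if disordered
                else config.score_mean_ordered
            )
            noise = (
                noise_rng.normal(0.0, config.score_noise_sd, size=n)
                if config.score_noise_sd > 0
                else np.zeros(n)
            )
            score_parts.append(np.clip(mean + noise, 0.0, 1.0))

        sequence = "".join(seq_parts)
        records.append(
            ProteinRecord(accession, f"synthetic protein {idx + 1}", sequence)
        )
        tracks.append(
            ScoreTrack(accession, np.concatenate(score_parts), sequence)
        )
        truths.append(truth)
    return records, tracks, truths


def simulate_heat_enrichment(
    truths: Sequence[ProteinTruth],
    config: SyntheticConfig,
    group: str = "NCA",
) -> tuple[SampleSet, SampleSet]:
    """Draw (heated, non-heated) sample sets from ground truth.

    Non-heated membership is an independent detection draw per protein;
    heated membership requires detection and heat survival, whose
    probability is logistic in the true disorder rate.  Deterministic
    given the config seed.
    """
    det_rng = config.rng("detection")
    sur_rng = config.rng("survival")
    heated = SampleSet(group=group, treatment="heated")
    non_heated = SampleSet(group=group, treatment="non-heated")
    for truth in truths:
        if det_rng.random() < config.detection_prob:
            non_heated.accessions.add(truth.accession)
        detected_heated = det_rng.random() < config.detection_prob
        survives = sur_rng.random() < truth.survival_prob
        if detected_heated and survives:
            heated.accessions.add(truth.accession)
    return heated, non_heated


def build_count_fixture(
    size_a: int,
    size_b: int,
    size_common: int,
    label_a: tuple[str, str] = ("A", "all"),
    label_b: tuple[str, str] = ("B", "all"),
    prefix: str = "FIX",
) -> tuple[SampleSet, SampleSet]:
    """Two accession sets with exactly the requested cardinalities.

    ``size_common`` accessions are shared; the remainders are exclusive.
    Useful for reproducing published set arithmetic exactly.
    """
    if size_common > min(size_a, size_b) or min(size_a, size_b, size_common) < 0:
        raise ValueError(
            f"inconsistent sizes: |A|={size_a}, |B|={size_b}, common={size_common}"
        )
    n_union = size_a + size_b - size_common
    accs = [f"{prefix}{i + 1:06d}" for i in range(n_union)]
    common = set(accs[:size_common])
    only_a = set(accs[size_common : size_a])
    only_b = set(accs[size_a : n_union])
    return (
        SampleSet(group=label_a[0], treatment=label_a[1], accessions=common | only_a),
        SampleSet(group=label_b[0], treatment=label_b[1], accessions=common | only_b),
    )
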