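"""Reference per-residue disorder scorer based on pairwise interaction energies.

The underlying idea: an ordered conformation is stabilized by favorable
inter-residue contacts, and the energy a residue can gain upon folding
can be estimated from the sequence alone by summing pairwise
interaction-energy terms over sequence neighbors within a separation
window.  Residues whose environment offers little stabilizing energy
are predicted disordered.

Concretely, for residue i with window bounds ``k_min <= |i - j| <= k_max``:

    e_i = mean over eligible j of  M[a_i, a_j]

where ``M`` is a symmetric 20x20 interaction matrix (a residue with no
eligible neighbor gets e_i = 0).  The raw profile is smoothed with a
centered moving average of odd width ``w`` (truncated at chain ends) and
mapped to a disorder score in (0, 1) through a logistic with slope ``a``
and midpoint ``b``; the orientation is "higher energy (less stabilizing)
=> more disordered", so ``M`` entries should be fitted or supplied on
that convention.

``fit_interaction_matrix`` calibrates ``M`` from per-residue binary
disorder labels by linear least squares: each residue contributes a
feature vector of (smoothed, window-normalized) unordered-pair counts
over the 210 unique matrix entries, and a target equal to the inverse
logistic of its (clipped) label.

This scorer is a reference implementation of the energy-estimation
principle, not a reproduction of any published predictor's matrix or
numerical output; externally supplied score tables remain the primary
input path for downstream analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence, TextIO

import numpy as np

from .alphabet import CANONICAL, NONSTANDARD_INDEX, encode
from .io import ScoreTrack

N_AA = len(CANONICAL)
N_PAIRS = N_AA * (N_AA + 1) // 2  # 210 unique symmetric entries

# pair (x, y) with x <= y  ->  flat index 0..209
_PAIR_INDEX = np.zeros((N_AA, N_AA), dtype=np.intp)
_k = 0
for _x in range(N_AA):
    for _y in range(_x, N_AA):
        _PAIR_INDEX[_x, _y] = _PAIR_INDEX[_y, _x] = _k
        _k += 1


@dataclass
class InteractionModel:
    """Symmetric interaction matrix plus window and calibration parameters."""

    M: np.ndarray
    k_min: int = 2
    k_max: int = 25
    w: int = 11
    a: float = 2.0
    b: float = 0.0

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.shape != (N_AA, N_AA):
            raise ValueError(f"M must be {N_AA}x{N_AA}")
        if not np.allclose(self.M, self.M.T, atol=1e-9):
            raise ValueError("M must be symmetric")
        if not 1 <= self.k_min <= self.k_max:
            raise ValueError("require 1 <= k_min <= k_max")
        if self.w < 1 or self.w % 2 == 0:
            raise ValueError("w must be odd and >= 1")
        if self.a <= 0:
            raise ValueError("logistic slope a must be positive")

    def extended_matrix(self) -> np.ndarray:
        """21x21 matrix where the extra row/column holds column means of M,
        used for nonstandard residues in lenient mode."""
        ext = np.zeros((N_AA + 1, N_AA + 1))
        ext[:N_AA, :N_AA] = self.M
        col_mean = self.M.mean(axis=0)
        ext[N_AA, :N_AA] = col_mean
        ext[:N_AA, N_AA] = col_mean
        ext[N_AA, N_AA] = self.M.mean()
        return ext


def _moving_average(values: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average of odd width *w*, truncated at the ends."""
    if w == 1:
        return values.astype(float)
    half = w // 2
    csum = np.concatenate(([0.0], np.cumsum(values, dtype=float)))
    n = values.size
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def pair_energy_profile(
    sequence: str, model: InteractionModel, strict: bool = False
) -> np.ndarray:
    """Raw (unsmoothed) per-residue mean pairwise energy."""
    if not sequence:
        raise ValueError("empty sequence")
    s = encode(sequence, strict=strict)
    m = model.extended_matrix()
    n = s.size
    total = np.zeros(n)
    count = np.zeros(n)
    for d in range(model.k_min, min(model.k_max, n - 1) + 1):
        pair = m[s[: n - d], s[d:]]
        total[: n - d] += pair
        total[d:] += pair
        count[: n - d] += 1
        count[d:] += 1
    with np.errstate(invalid="ignore"):
        energy = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    return energy


def predict_energy(
    sequence: str, model: InteractionModel, strict: bool = False
) -> np.ndarray:
    """Smoothed per-residue interaction-energy profile."""
    return _moving_average(pair_energy_profile(sequence, model, strict), model.w)


def energies_to_scores(
    energies: np.ndarray, model: InteractionModel, accession: str = ""
) -> ScoreTrack:
    """Logistic calibration of energies to disorder scores in (0, 1)."""
    e = np.asarray(energies, dtype=float)
    z = np.clip(model.a * (e - model.b), -500.0, 500.0)
    scores = 1.0 / (1.0 + np.exp(-z))
    return ScoreTrack(accession, scores)


def predict_scores(
    sequence: str,
    model: InteractionModel,
    accession: str = "",
    strict: bool = False,
) -> ScoreTrack:
    """Full scorer: energies, smoothing, then logistic calibration."""
    return energies_to_scores(predict_energy(sequence, model, strict), model, accession)


def _pair_features(s: np.ndarray, k_min: int, k_max: int, w: int) -> np.ndarray:
    """Per-residue feature matrix over the 210 unique pair entries.

    Row i holds the window-normalized unordered-pair counts whose dot
    product with the flattened unique entries of M equals residue i's raw
    energy; rows are then smoothed exactly as the energies would be.
    """
    n = s.size
    feats = np.zeros((n, N_PAIRS))
    count = np.zeros(n)
    rows = np.arange(n)
    for d in range(k_min, min(k_max, n - 1) + 1):
        pidx = _PAIR_INDEX[s[: n - d], s[d:]]
        np.add.at(feats, (rows[: n - d], pidx), 1.0)
        np.add.at(feats, (rows[d:], pidx), 1.0)
        count[: n - d] += 1
        count[d:] += 1
    nonzero = count > 0
    feats[nonzero] /= count[nonzero, None]
    if w > 1:
        feats = np.column_stack(
            [_moving_average(feats[:, j], w) for j in range(N_PAIRS)]
        )
    return feats


def fit_interaction_matrix(
    training: Sequence[tuple[str, Sequence[int]]],
    k_min: int = 2,
    k_max: int = 25,
    w: int = 11,
    ridge: float = 0.0,
    a: float = 2.0,
    b: float = 0.0,
    label_clip: float = 0.05,
) -> InteractionModel:
    """Fit the 210 unique entries of M from labeled training sequences.

    *training* is a list of (sequence, labels) pairs with one binary
    disorder label per residue.  Labels are clipped to
    [label_clip, 1 - label_clip] and mapped through the inverse logistic
    at the fixed (a, b) to give per-residue target energies; M then
    solves the resulting linear least-squares problem (optionally ridge-
    regularized).  Training sequences must be over canonical residues.

    Raises if all labels share one value (degenerate, nothing to separate)
    or if the system is rank-deficient and *ridge* is zero.
    """
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    feats_list, target_list = [], []
    for sequence, labels in training:
        s = encode(sequence, strict=False)
        if np.any(s == NONSTANDARD_INDEX):
            raise ValueError("training sequences must contain canonical residues only")
        labels = np.asarray(labels, dtype=float)
        if labels.size != s.size:
            raise ValueError("labels must align with the sequence")
        feats_list.append(_pair_features(s, k_min, k_max, w))
        p = np.clip(labels, label_clip, 1.0 - label_clip)
        target_list.append(b + np.log(p / (1.0 - p)) / a)
    if not feats_list:
        raise ValueError("no training data")
    features = np.vstack(feats_list)
    target = np.concatenate(target_list)
    raw_labels = np.concatenate([np.asarray(l, dtype=float) for _, l in training])
    if np.all(raw_labels == raw_labels[0]):
        raise ValueError("degenerate training set: all residues share one label")
    if features.shape[0] < N_PAIRS and ridge == 0:
        raise ValueError(
            f"need >= {N_PAIRS} labeled residues (or ridge > 0); "
            f"got {features.shape[0]}"
        )
    if ridge > 0:
        features = np.vstack([features, np.sqrt(ridge) * np.eye(N_PAIRS)])
        target = np.concatenate([target, np.zeros(N_PAIRS)])
    solution, _, rank, _ = np.linalg.lstsq(features, target, rcond=None)
    if ridge == 0 and rank < N_PAIRS:
        raise ValueError(
            f"rank-deficient system (rank {rank} < {N_PAIRS}); "
            "supply more varied training data or set ridge > 0"
        )
    m = np.zeros((N_AA, N_AA))
    for x in range(N_AA):
        for y in range(x, N_AA):
            m[x, y] = m[y, x] = solution[_PAIR_INDEX[x, y]]
    return InteractionModel(M=m, k_min=k_min, k_max=k_max, w=w, a=a, b=b)


def matrix_entries(model: InteractionModel) -> np.ndarray:
    """The 210 unique entries of M as a flat vector (upper triangle)."""
    iu = np.triu_indices(N_AA)
    return model.M[iu]


def write_model(model: InteractionModel, dest: str | Path | TextIO) -> None:
    """Serialize a model as a key-value header plus a labeled 20x20 matrix."""
    lines = [
        f"# k_min {model.k_min}\n",
        f"# k_max {model.k_max}\n",
        f"# w {model.w}\n",
        f"# a {model.a!r}\n",
        f"# b {model.b!r}\n",
        "\t" + "\t".join(CANONICAL) + "\n",
    ]
    for i, aa in enumerate(CANONICAL):
        lines.append(aa + "\t" + "\t".join(f"{v:.10g}" for v in model.M[i]) + "\n")
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8") as handle:
            handle.writelines(lines)
    else:
        dest.writelines(lines)


def read_model(source: str | Path | TextIO) -> InteractionModel:
    """Parse a model file written by :func:`write_model`."""
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as handle:
            lines = handle.readlines()
    else:
        lines = source.readlines()
    params: dict[str, float] = {}
    matrix_rows: dict[str, list[float]] = {}
    for line in lines:
        line = line.rstrip("\n")
        if line.startswith("#"):
            key, value = line[1:].split(None, 1)
            params[key] = float(value)
        elif line.strip() and not line.startswith("\t"):
            label, *values = line.split("\t")
            matrix_rows[label] = [float(v) for v in values]
    m = np.array([matrix_rows[aa] for aa in CANONICAL])
    return InteractionModel(
        M=m,
        k_min=int(params["k_min"]),
        k_max=int(params["k_max"]),
        w=int(params["w"]),
        a=params["a"],
        b=params["b"],
    )


def symmetric_random_matrix(rng: np.random.Generator, scale: float = 1.0) -> np.ndarray:
    """A random symmetric 20x20 matrix (convenience for planted-model tests)."""
    m = rng.normal(scale=scale, size=(N_AA, N_AA))
    return (m + m.T) / 2.0


def perturb(model: InteractionModel, **changes) -> InteractionModel:
    """Return a copy of *model* with the given fields replaced."""
    return replace(model, **changes)
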