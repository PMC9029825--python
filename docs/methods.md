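# Methods

## Disorder metrics and band classification

All per-protein metrics derive from a per-residue disorder score track
`s ∈ [0,1]^L` aligned to the sequence. A residue is disordered when
`s_i ≥ c` with residue cutoff `c = 0.5` (inclusive — a score of exactly
0.5 counts as disordered). Percental disorder is
`PD = 100 · #{i : s_i ≥ c} / L`, kept unrounded internally; report
tables round to two decimals only at serialization. Mean disorder
`\bar{s}` is reported but drives no classification.

Band labels partition `PD ∈ [0, 100]` at 10 / 30 / 70. The literature
wording is ambiguous about which band owns the boundary values
("below 10%" in one place, "no higher than 10%" in another), so the
package fixes one convention and exposes the other:

* `boundary_convention="lower"` (default): `[0,10) → OP`,
  `[10,30) → NOP`, `[30,70) → PDP`, `[70,100] → MDP` — each bound
  belongs to the more-disordered band;
* `boundary_convention="upper"`: `[0,10] → OP`, `(10,30] → NOP`,
  `(30,70] → PDP`, `(70,100] → MDP`.

Because empirical disorder rates almost never land exactly on a bound,
the two conventions differ only on measure-zero inputs; all shipped
analyses use the default.

Long IDRs are maximal runs of consecutive disordered residues with
length ≥ 20 (configurable `min_idr_length`), reported as 1-based
inclusive segments matching the score-table coordinate convention.
Maximality is part of the contract: extending any returned segment by
one residue crosses the cutoff or the chain end.

Nonstandard residues (B, Z, X, U, O, J) are accepted in lenient mode
(the default; NCBI predicted proteins often contain X runs). They keep
their score, count toward length and percental disorder like any other
residue, but are excluded from composition numerators *and*
denominators so residue fractions stay comparable across proteins;
their count is carried in a diagnostics column. Strict mode rejects
them at parse time.

## Composition aggregation

Per-band composition is the unweighted mean over member proteins of
each per-protein fraction vector (and of the disorder-/order-promoting
percentages). Averaging per protein rather than pooling residues
matches the "percent of total amino acids in a sequence, on average"
reading and keeps long proteins from dominating a band; a pooled-counts
mode is available behind the `pooled` flag for sensitivity checks.
Display order of residues in the band table is each class sorted by
abundance in the MDP band, recomputed from the data at hand.

## Cohort set algebra

A protein is identified with its accession string; no cross-species
sequence clustering is attempted, because identification lists built
against several related species' databases offer no principled
redundancy key at this layer. Partitions are exact set operations and
satisfy `|A-only| + |common| = |A|`, `|B-only| + |common| = |B|` and
inclusion–exclusion on the union; these invariants are asserted in
property tests over random sets. Headline percentages are rounded
half-up to integers at the reporting layer; other tables use one or
two decimals.

## Reference interaction-energy scorer

The optional predictor estimates the stabilizing energy a residue can
gain upon folding from sequence alone:

    e_i = (1/N_i) · Σ_{j : k_min ≤ |i−j| ≤ k_max} M[a_i, a_j]

with a symmetric 20×20 interaction matrix `M`, window `k_min = 2`,
`k_max = 25` by default (long-range contacts, immediate neighbors
excluded), normalized by the number of contributing positions `N_i` so
chain-end residues are not biased low (`N_i = 0` gives `e_i = 0`). The
profile is smoothed with a centered moving average of odd width
`w = 11`, truncated at the ends, and calibrated to a score through
`s_i = 1/(1 + exp(−a(ê_i − b)))` with `a = 2`, `b = 0` — monotone, so
higher (less stabilizing) energy means more disorder. None of these
values is canonical; all are config-exposed, and external score tables
bypass the scorer entirely. The implementation is an original
realization of the energy-estimation principle; it does not reproduce
any published predictor's matrix or absolute outputs, and downstream
analyses never depend on its absolute values.

Calibration (`fit_interaction_matrix`) solves for the 210 unique
entries of `M` by linear least squares: residue `i` contributes a
feature row of window-normalized unordered-pair counts (smoothed the
same way energies are) and a target equal to the inverse logistic, at
fixed `(a, b)`, of its binary label clipped to `[0.05, 0.95]` (the
inverse logistic is unbounded at 0/1; the clip is a design constant,
not fitted). Optional ridge regularization stabilizes rank-deficient
systems; with `ridge = 0` a rank check raises instead of silently
returning a minimum-norm solution. Training sequences must be over the
canonical alphabet: the lenient column-mean treatment of nonstandard
residues would smear 1/20 of feature mass over a whole matrix row and
muddy the fit, so it applies at prediction time only. An all-one-label
training set raises (nothing to separate). Duplication invariance
(doubling the training data leaves the fit unchanged when ridge scales
with it) is covered by tests.

The planted-matrix recovery experiment — draw a random symmetric `M*`,
generate Dirichlet-composition training sequences, label residues by
thresholding the planted model's own scores, refit, and correlate the
210 entries — uses `w = 1` and window 2–10. Smoothing is by design an
information discard (it averages away exactly the positional signal the
regression needs), and binarized labels already cost information, so
the calibration benchmark is run in the unsmoothed setting; at 300
training sequences of length 100–300 the recovered matrix correlates
with `M*` at Pearson r ≈ 0.94–0.97 across seeds. The fit itself
supports any odd `w`.

## Synthetic study bed

`synthesize_proteome` plants a known architecture: each protein
alternates ordered and disordered blocks (geometric lengths, mean 120
and 60 residues; a protein starts disordered with probability 0.35),
with chain lengths uniform on 80–600. These defaults give a mix of
fully ordered chains, chains with isolated long IDRs and mostly
disordered chains at desk-scale `n = 500`. Residues are drawn from
block-specific frequency vectors placing 70% of probability mass on
disorder-promoting residues in disordered blocks and 45% in ordered
blocks — the disordered-block figure sits near the disorder-promoting
content typical of mostly disordered proteins (~69%), the ordered-block
figure below the balanced ~56% of ordered ones, so composition trends
have the right direction without being tuned to any dataset. Score
tracks are the block mean (0.75 disordered / 0.25 ordered) plus
N(0, sd) noise clamped to [0, 1]; truncation by clamping is simpler
than a logit-normal model and adequate for recovery experiments. With
`sd = 0` the thresholded track reproduces the planted architecture
exactly, giving an end-to-end identity test; at the default `sd = 0.1`
band recovery stays ≈ 99% on 500 proteins.

Heat enrichment is emulated, not modeled thermodynamically: the
non-heated sample detects each protein independently with probability
0.7 (a stand-in for LC–MS/MS incompleteness), the heated sample
requires detection *and* survival, with survival probability logistic
in true percental disorder (slope 0.1 per percentage point, midpoint
30%) — roughly 5% survival for a fully ordered chain, ~88% at 50%
disorder. Survival is monotone in disorder by construction, so the
heated set's band distribution shifts toward PDP/MDP; tests check the
direction, not magnitudes.

All draws come from one global seed through named substreams
(architecture, sequence letters, score noise, detection, survival), so
adding a generator call never perturbs existing draws and every
artifact is byte-reproducible from the seed.

What the generator does **not** emulate: peptide-level sampling and
protein inference, shared peptides between homologs, abundance-
dependent detection, real residue-level disorder autocorrelation, or
database redundancy across related species. Passing recovery tests
therefore demonstrates that the pipeline's arithmetic and segmentation
are correct on tracks of the stated form — not that any upstream
identification or prediction step is accurate on real data.

## Problem sizes and determinism

Shipped analyses and tests run at n = 120–800 synthetic proteins,
300 training sequences for calibration, and 500-track oracle sweeps —
sizes chosen so the full suite completes in well under a minute on one
core while keeping binomial/recovery checks comfortably powered.
`scripts/acceptance.py` derives all randomness from its `--seed`; the
count-arithmetic outputs are fully deterministic, and the stochastic
metrics vary only within the tolerances the tests assert.

## Known limitations

* Band boundary semantics are convention-dependent (see above); results
  for rates exactly on a bound depend on the flag.
* Accession-string identity is the only uniqueness key; homologous
  entries from different source databases count separately.
* The reference scorer is sequence-composition driven within a window;
  it cannot capture context the published energy-estimation predictors
  learn from structured training corpora, and is not intended to.
* Functional tallies depend entirely on the user-supplied category
  mapping; no ontology reasoning or ID mapping is performed.
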