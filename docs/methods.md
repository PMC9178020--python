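# Methods

## The transformation

`psd_transform` maps a non-negative features × cells matrix to latent
features in `[0, 1]` through four deterministic stages (correlation
transform, per-cell power spectrum, spectral-entropy encoding, per-cell
min–max scaling; see the README for the formulas). The design intuition:
autocorrelation-based spectral analysis assumes an ordered signal, but
genomic features are arbitrarily ordered, so the pairwise feature
correlation matrix is used to mix each cell's profile before the Fourier
step. The magnitude spectrum, renormalized per cell, is read as a
probability distribution and encoded by its entropy per unit, with each
feature's mean entropy across cells subtracted to remove the "background"
information that feature carries everywhere.

Numerical conventions, chosen where the formulas are silent:

- **Zero-variance features.** Only all-zero features are filtered.  A
  constant non-zero feature has undefined Pearson correlations; it is kept
  with off-diagonal correlations set to 0 and diagonal 1, so it passes
  through the linear mix scaled only by itself.  This avoids NaN
  propagation without changing the feature count.
- **`0·log₂0 = 0`** in the entropy stage (the standard convention).
- **Degenerate cells.** A cell whose entropy-referenced column is constant
  (e.g. `m = 1`, or identical spectra) min–max scales to an all-zero
  column; it is flagged in `provenance["degenerate_cells"]` rather than
  raised, so batch runs survive degenerate inputs.  A cell with an all-zero
  spectrum (impossible after zero-feature filtering) raises
  `"degenerate cell spectrum"` naming the cell.
- **DFT length** is exactly `n` with no padding or windowing; `numpy.fft`
  supplies the algorithm, and the test suite pins the stage to a direct
  O(n²) summation oracle at `max |Δ| < 1e−9`.
- **Precision.** Correlations and entropies are accumulated in float64
  regardless of input dtype.
- **Memory.** `block_size` evaluates `ρ·A` in row blocks from unit-norm
  centred rows without materializing the n × n correlation matrix
  (peak extra memory `O(block_size · n)`), agreeing with the dense product
  to ~1e−10.  With blocks of ~1000 rows, n ≈ 20,000 features fit
  comfortably in a few GB.
- **Orientation** is fixed as features × cells; dense inputs with cells in
  rows are transposed only when the caller passes `cells_in_rows`/
  `--cells-in-rows` (no silent guessing).

## Order-invariance: what is measured and why two scales

`order_invariance` transforms a reference ordering once, then for each
shuffle permutes the feature rows (the same permutation for every cell),
transforms, restores the reference order, and accumulates per-(feature,
cell) RMSD across shuffles.

The correlation stage is exactly permutation-equivariant, the Fourier
stage is not, so the deviation is small but nonzero.  Two scales are
reported because they answer different questions:

- `rmsd_entropy` — deviation of the entropy-referenced features (stage 3).
  These values shrink like `log n / n`, and so do their permutation
  deviations; this is the scale on which the extraction is meaningfully
  "order-independent" (median ≈ 8e−3, max ≈ 4e−2 at 500 features ×
  200 cells; identity permutations give exactly 0).
- `rmsd` — deviation of the final min–max-scaled output.  The per-cell
  stretch renormalizes the same fluctuations to each column's range, so
  this reading is necessarily O(0.1) for any data whose spectrum is not
  concentrated (it shrinks only like `1/√log n`).  It is reported for
  completeness, not as the headline invariance measure.

## Cluster-separability statistics

- **VRC** `= (BGSS/(k−1)) / (WGSS/(n−k))`; returns `+inf` with a warning
  when `WGSS = 0`.
- **Silhouette** `s(i) = (b(i) − a(i))/max(a(i), b(i))` with `a(i)` the
  mean within-cluster distance excluding self and `b(i)` the smallest mean
  distance to another cluster; singleton clusters get `s(i) = 0`.
  Distances: euclidean, standardized euclidean (per-feature sample SD over
  the whole dataset, zero SDs replaced by 1), cosine distance, correlation
  distance.
- **Fisher's ratio** `f_ij = (μ_i − μ_j)²/(σ_i² + σ_j²)` is computed per
  feature with unbiased (ddof = 1) variances and averaged over features;
  features with zero pooled variance contribute 0.  This aggregation keeps
  `f_ij` scale-free per feature; alternatives (integrating over features)
  are possible and the function is small enough to swap.
- **mFDR**: for each class the vector of its pairwise ratios (classes in
  sorted-name order, self-term 0) is integrated by the trapezoidal rule
  over the unit-spaced class index, and the integrals are averaged.  The
  integral depends on class ordering; sorted label names make it
  deterministic.
- **Kendall's W** `= 12 Σ(R_i − R̄)² / (m²(n³ − n))` on a midrank table;
  the permutation test permutes each judge's ranking independently and uses
  the `(c+1)/(n_perm+1)` estimator so p is never exactly zero.  Seeded and
  bit-reproducible.

## Synthetic data: what it emulates and what it does not

`simulate` draws lognormal baseline means per gene (log-mean 1, log-sd 1),
multiplies a random `marker_fraction` (default 10%) of genes per cluster by
`2^(±log2_effect)` (default effect 3, direction random per marker),
applies lognormal per-cell size factors (`libsize_sigma` 0.3),
draws negative-binomial counts with dispersion 0.4, and zeroes entries
with probability `logistic(slope·(midpoint − log1p(μ)))` (midpoint 1,
slope 1 — about half of the entries at the default settings, concentrated
in lowly expressed genes).  Cells are apportioned to clusters by largest
remainder, so cluster sizes are deterministic; a rare population is
requested through `cluster_proportions` (e.g. 0.01).  Defaults give a
500 × 200 matrix with four equal clusters.

This emulates clustered non-negative counts with overdispersion,
dropout-driven sparsity and library-size variation.  It does **not**
emulate batch effects beyond the size factor, gene–gene co-expression
modules beyond what markers induce, trajectories/continuous states, or
doublets.  Tests passing on this generator therefore demonstrate the
pipeline's internal contracts and the direction of its effects under a
standard noise model — not performance on any real dataset.

## Evaluation experiments

- `before_after_ivm` computes VRC/silhouette/mFDR on the (optionally
  CPM- or TF-IDF-normalized) matrix and on its transform; all-zero
  features are dropped first so both sides share a feature set.
- `holdout_experiment` uses a stratified 20% holdout (stratification
  guarantees rare classes appear in the test set) and an internal
  Euclidean k-NN (default k = 5) with deterministic tie-breaking (vote
  count, then aggregate distance, then lexicographic label).  The k-NN is
  deliberately dependency-free; any external classifier can reuse
  `stratified_split` directly.  The transform is applied to the full
  matrix before splitting — it is unsupervised, but test cells do
  participate in the feature–feature correlation, a whole-dataset
  convention to keep in mind when interpreting accuracies.
- `feature_coverage_curve` accumulates random features in 10% brackets and
  reports mean ± SD k-NN accuracy before/after the transform across
  repeats, all repeats sharing split seeds between the two arms.

Directional findings (improvement of VRC, of rare-class accuracy, of
low-coverage stability; harmonization across normalizations) are asserted
in the test suite as majority-of-seeds statements over 10–20 generator
seeds at the default conditions, never as universal claims; the null
configuration (`log2_effect = 0`) is checked to show no artifactual
improvement (mean log₁₀ VRC ratio within ±0.1 of zero).

## Problem sizes

Tests and the acceptance script run the default 500 × 200 condition for
the paired-metric and order-invariance experiments, 500 × 2000 with a 1%
rare cluster for rare-population classification, and 20 repeats × 10
coverage brackets for the coverage curve — sizes chosen so a full
from-scratch reproduction completes in well under a minute each on a
single CPU while leaving the Monte-Carlo margins comfortable.

## Normalizations

CPM rescales each cell to a fixed total (default 1e6); it is idempotent.
TF-IDF uses `TF = count/cell total`, `IDF = m / #cells detecting the
feature`, output `log1p(TF·IDF·scale)` with scale default 1e4 (the common
chromatin-accessibility convention); zeros are preserved exactly.  Both
refuse empty cells (and TF-IDF undetected features) by name.  Other
normalizations (TMM, scran, Seurat log-normalize, …) are out of scope;
the transform accepts whatever matrix the caller passes, so external
normalizations can be applied upstream.

## Known limitations

- The correlation matrix is dense; even blocked, the transform is
  O(n²·m/block) time.  No sparse-preserving path exists (the mixed matrix
  is dense by construction) and none is planned.
- Silhouette's correlation distance is undefined for a cell that is
  constant across features; such cells are practically excluded by the
  transform's output but can occur on raw input.
- The min–max-scaled output discards each cell's entropy scale; use
  `keep_intermediates` to retain the unscaled stages when absolute
  magnitudes matter.
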