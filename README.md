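# scpsd

Power-spectral-density feature transformation for single-cell omics
matrices, with the cluster-separability statistics used to evaluate it and
a built-in synthetic count generator so everything runs end to end without
external data.

## The problem

Single-cell count matrices (scRNA-seq genes × cells, scATAC-seq peaks ×
cells) are noisy, sparse and heavily pipeline-dependent: the apparent
separation of annotated cell types changes with the normalization applied
upstream, and rare populations are easily swamped. `scpsd` implements a
deterministic, unsupervised feature transformation that recodes each cell's
profile through the power spectrum of its correlation-mixed signal, which
in practice tightens cell-type clusters, harmonizes differently normalized
inputs, and improves downstream classification — including of the smallest
population in a dataset.

## The transform

For a matrix `A ∈ R^{n×m}` of `n` features and `m` cells (all-zero
features removed first):

1. **Correlation transform.** `ρ ∈ R^{n×n}` is the Pearson correlation
   between every pair of feature rows across cells; `A1 = ρ·A`. This
   injects cross-feature dependency structure so that the Fourier step does
   not hinge on the arbitrary ordering of features.
2. **Power spectrum.** Per cell, `A2 = |DFT(|A1|)| / n`, a plain length-`n`
   discrete Fourier transform (computed with the FFT), no padding or
   windowing.
3. **Spectral entropy.** Each cell's spectrum is renormalized to a
   probability vector `P(k,j) = A2(k,j)/Σ_k A2(k,j)`; the entropy per unit
   `H = −P log₂ P` is referenced against each feature's mean entropy across
   cells: `A3(k,j) = (1/m)Σ_j H(k,j) − H(k,j)`.
4. **Scaling.** Each cell's column is min–max scaled to `[0, 1]`.

The pipeline contains no randomness: reruns are bit-identical.

Evaluation statistics included: the variance ratio criterion
(Calinski–Harabasz index), silhouette score under four distance metrics,
a multi-class Fisher's discriminant ratio (pairwise ratios aggregated by
trapezoidal integration), Kendall's W with a permutation test, holdout
k-nearest-neighbour classification with rare-class reporting, and an
order-invariance RMSD experiment.

## Worked example

```python
import scpsd

# clustered synthetic counts: 500 genes x 200 cells, 4 cell types,
# negative-binomial noise, logistic dropout, true labels attached
M = scpsd.simulate(scpsd.SimConfig(seed=7))

paired = scpsd.before_after_ivm(M)
print(f"VRC before {paired.before.vrc:.1f} after {paired.after.vrc:.1f}")
print(f"silhouette before {paired.before.ss['euclidean']:.3f} "
      f"after {paired.after.ss['euclidean']:.3f}")
```

prints

```
VRC before 53.3 after 313.4
silhouette before 0.246 after 0.627
```

i.e. on this matrix the variance ratio criterion (between- over
within-cluster dispersion of the annotated cell types) rises about
six-fold after the transform, and the mean silhouette more than doubles —
cells of the same type sit closer together, relative to other types, in
the transformed feature space than in the raw counts.

The same pipeline is available from the shell:

```bash
scpsd simulate --seed 7 --out sim/
scpsd transform --input sim/ --out transformed/ --normalize cpm
scpsd evaluate --input sim/ --labels sim/labels.tsv
scpsd order-invariance --input sim/ --n-shuffles 20 --seed 11
```

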