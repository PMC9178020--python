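"""Runnable evaluation experiments around the transform.

* ``order_invariance`` — shuffle feature order, transform, un-permute, and
  quantify per-(feature, cell) root-mean-square deviation from a reference
  ordering.  The correlation stage is exactly permutation-equivariant; the
  Fourier stage is not, so the deviation is small but nonzero.
* ``before_after_ivm`` — cluster-separability metrics (VRC, silhouette,
  mFDR) on a matrix before and after the transform.
* ``knn_classify`` / ``holdout_experiment`` — a dependency-free Euclidean
  k-nearest-neighbour classifier with a stratified holdout split, reporting
  overall, per-class and rare-class (smallest population) accuracy.  Any
  external classifier can be swapped in by reusing the split from
  ``stratified_split`` directly.
* ``feature_coverage_curve`` — accuracy versus random feature coverage
  (10%–100% brackets), before and after the transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import OmicsMatrix, filter_zero_features, psd_transform
from .metrics import MetricReport, metric_report
from .preprocess import NormalizationSpec, apply_normalization

__all__ = [
    "OrderInvarianceReport",
    "ClassificationReport",
    "PairedMetricReport",
    "order_invariance",
    "before_after_ivm",
    "knn_classify",
    "stratified_split",
    "holdout_experiment",
    "feature_coverage_curve",
]


def _rmsd_summary(rmsd: np.ndarray) -> dict[str, float]:
    return {
        "min": float(rmsd.min()),
        "median": float(np.median(rmsd)),
        "max": float(rmsd.max()),
    }


@dataclass
class OrderInvarianceReport:
    """Per-(feature, cell) RMSD across feature-order shuffles.

    Deviations are recorded at two stages of the transform.  ``rmsd_entropy``
    is measured on the entropy-referenced matrix — the stage whose absolute
    deviations quantify how much the extracted features depend on feature
    ordering (they shrink like ``log n / n``).  ``rmsd`` is measured on the
    final min-max-scaled output, where the per-cell stretch renormalises the
    same fluctuations to each column's range and therefore reads much larger
    for the identical underlying deviation.
    """

    rmsd: np.ndarray  # n x m, scaled-output stage
    rmsd_entropy: np.ndarray  # n x m, entropy stage (pre-scaling)
    feature_ids: list[str]
    cell_ids: list[str]
    n_shuffles: int
    seed: int

    @property
    def summary(self) -> dict[str, float]:
        return _rmsd_summary(self.rmsd)

    @property
    def entropy_summary(self) -> dict[str, float]:
        return _rmsd_summary(self.rmsd_entropy)

    @property
    def per_feature(self) -> np.ndarray:
        """RMS over cells of the per-entry scaled-output RMSD, per feature."""
        return np.sqrt((self.rmsd**2).mean(axis=1))


@dataclass
class ClassificationReport:
    accuracy: float
    confusion: pd.DataFrame  # rows: true class, columns: predicted
    rare_class: str
    rare_class_accuracy: float
    split_seed: int
    k_neighbors: int

    @property
    def per_class_accuracy(self) -> pd.Series:
        diag = pd.Series(np.diag(self.confusion.values), index=self.confusion.index)
        return diag / self.confusion.sum(axis=1)


@dataclass
class PairedMetricReport:
    before: MetricReport
    after: MetricReport
    log10_vrc_ratio: float
    log10_mfdr_ratio: float
    ss_delta: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "before": self.before.to_dict(),
            "after": self.after.to_dict(),
            "log10_vrc_ratio": self.log10_vrc_ratio,
            "log10_mfdr_ratio": self.log10_mfdr_ratio,
            "ss_delta": dict(self.ss_delta),
        }


def order_invariance(
    M: OmicsMatrix,
    n_shuffles: int = 20,
    seed: int = 0,
    block_size: int | None = None,
    permutations: Sequence[np.ndarray] | None = None,
) -> OrderInvarianceReport:
    """Quantify the transform's dependence on initial feature ordering.

    The input's own ordering is the reference.  Each shuffle permutes the
    feature rows (the same permutation in every cell), transforms, and
    restores the reference order before comparing; RMSD is taken across
    shuffles for every (feature, cell) entry.

    ``permutations`` overrides the seeded random shuffles with explicit
    permutation arrays (of the post-filter feature count), e.g. identity
    permutations to verify the zero-deviation baseline.
    """
    if permutations is not None:
        permutations = [np.asarray(p) for p in permutations]
        n_shuffles = len(permutations)
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    ref = psd_transform(M, keep_intermediates=True, block_size=block_size)
    ref_entropy = ref.intermediates["A3"]
    n = len(ref.feature_ids)
    base = M.subset_features(
        np.array([M.feature_ids.index(f) for f in ref.feature_ids])
    )
    rng = np.random.default_rng(seed)
    sq_scaled = np.zeros_like(ref.transformed)
    sq_entropy = np.zeros_like(ref.transformed)
    for s in range(n_shuffles):
        perm = rng.permutation(n) if permutations is None else permutations[s]
        shuffled = psd_transform(base.subset_features(perm),
                                 keep_intermediates=True, block_size=block_size)
        inv = np.argsort(perm)
        sq_scaled += (shuffled.transformed[inv] - ref.transformed) ** 2
        sq_entropy += (shuffled.intermediates["A3"][inv] - ref_entropy) ** 2
    rmsd = np.sqrt(sq_scaled / n_shuffles)
    rmsd_entropy = np.sqrt(sq_entropy / n_shuffles)
    return OrderInvarianceReport(rmsd, rmsd_entropy, list(ref.feature_ids),
                                 list(ref.cell_ids), n_shuffles, seed)


def before_after_ivm(
    M: OmicsMatrix,
    labels: Sequence | None = None,
    normalize: NormalizationSpec | None = None,
    ss_metrics: Sequence[str] = ("euclidean",),
    block_size: int | None = None,
) -> PairedMetricReport:
    """Separability metrics on the (optionally normalized) input and its transform.

    All-zero features are dropped first so the before and after matrices
    (and any normalization) share one feature set.
    """
    if labels is None:
        labels = M.labels
    if labels is None:
        raise ValueError("cell-type labels are required")
    N = apply_normalization(filter_zero_features(M), normalize)
    result = psd_transform(N, block_size=block_size)
    before = metric_report(N.values.T, labels, ss_metrics)
    after = metric_report(result.transformed.T, labels, ss_metrics)
    return PairedMetricReport(
        before=before,
        after=after,
        log10_vrc_ratio=float(np.log10(after.vrc / before.vrc)),
        log10_mfdr_ratio=float(
            np.log10(after.mfdr / before.mfdr) if before.mfdr > 0 and after.mfdr > 0
            else np.nan
        ),
        ss_delta={m: after.ss[m] - before.ss[m] for m in before.ss},
    )


def knn_classify(
    train_X: np.ndarray,
    train_labels: Sequence,
    test_X: np.ndarray,
    k_neighbors: int = 5,
) -> np.ndarray:
    """Euclidean k-NN majority vote.

    Ties in the vote are broken by the smaller aggregate distance of the
    tied label's neighbours, then lexicographically.
    """
    train_X = np.asarray(train_X, dtype=np.float64)
    test_X = np.asarray(test_X, dtype=np.float64)
    train_labels = np.asarray([str(x) for x in train_labels])
    if train_X.shape[0] == 0:
        raise ValueError("empty training set")
    if not 1 <= k_neighbors <= train_X.shape[0]:
        raise ValueError("k_neighbors must be in [1, n_train]")
    D = cdist(test_X, train_X)
    nearest = np.argsort(D, axis=1, kind="stable")[:, :k_neighbors]
    out = []
    for row, idx in enumerate(nearest):
        votes: dict[str, list[float]] = {}
        for t in idx:
            votes.setdefault(train_labels[t], []).append(D[row, t])
        best = min(
            votes.items(), key=lambda kv: (-len(kv[1]), sum(kv[1]), kv[0])
        )
        out.append(best[0])
    return np.asarray(out)


def stratified_split(
    labels: Sequence, test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random split; every class contributes at least one test cell."""
    lab = np.asarray([str(x) for x in labels])
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    test_idx = []
    for c in sorted(set(lab)):
        members = np.flatnonzero(lab == c)
        if members.size < 2:
            raise ValueError(
                f"class {c!r} has a single member; merge or remove it before splitting"
            )
        n_test = max(1, int(round(test_fraction * members.size)))
        n_test = min(n_test, members.size - 1)
        test_idx.append(rng.permutation(members)[:n_test])
    test = np.sort(np.concatenate(test_idx))
    train = np.setdiff1d(np.arange(len(lab)), test)
    return train, test


def holdout_experiment(
    M: OmicsMatrix,
    labels: Sequence | None = None,
    test_fraction: float = 0.2,
    split_seed: int = 0,
    transform: bool = False,
    k_neighbors: int = 5,
    block_size: int | None = None,
) -> ClassificationReport:
    """Stratified holdout k-NN evaluation, optionally after the transform.

    The transform is unsupervised and applied to the full matrix before
    splitting (it uses no labels, but the test cells do participate in the
    feature-feature correlation — a deliberate whole-dataset convention).
    The split depends only on the labels and ``split_seed``, so runs with
    and without the transform consume identical splits.
    """
    if labels is None:
        labels = M.labels
    if labels is None:
        raise ValueError("cell-type labels are required")
    lab = np.asarray([str(x) for x in labels])
    train, test = stratified_split(lab, test_fraction, split_seed)

    if transform:
        X = psd_transform(M, block_size=block_size).transformed.T
    else:
        X = M.values.T
    pred = knn_classify(X[train], lab[train], X[test], k_neighbors)

    classes = sorted(set(lab))
    cm = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(lab[test], pred):
        cm.loc[t, p] += 1
    sizes = pd.Series(lab).value_counts()
    rare = min(classes, key=lambda c: (sizes[c], c))
    rare_mask = lab[test] == rare
    return ClassificationReport(
        accuracy=float((pred == lab[test]).mean()),
        confusion=cm,
        rare_class=rare,
        rare_class_accuracy=float((pred[rare_mask] == rare).mean()),
        split_seed=split_seed,
        k_neighbors=k_neighbors,
    )


def feature_coverage_curve(
    M: OmicsMatrix,
    labels: Sequence | None = None,
    n_repeats: int = 10,
    seed: int = 0,
    coverages: Sequence[float] = tuple(np.arange(1, 11) / 10),
    test_fraction: float = 0.2,
    k_neighbors: int = 5,
) -> pd.DataFrame:
    """Accuracy versus random feature accumulation, before and after transform.

    Each repeat draws a random feature order; for every coverage bracket the
    leading fraction of features is kept and a stratified holdout k-NN
    experiment is run on the raw and on the transformed subset (same split).
    Returns a tidy frame with mean and SD accuracy per coverage level.
    """
    if labels is None:
        labels = M.labels
    if labels is None:
        raise ValueError("cell-type labels are required")
    if M.n_features < 10:
        raise ValueError("need at least 10 features for coverage brackets")
    M = OmicsMatrix(M.values, M.feature_ids, M.cell_ids, [str(x) for x in labels])
    rng = np.random.default_rng(seed)
    acc: dict[tuple[float, str], list[float]] = {}
    for _ in range(n_repeats):
        order = rng.permutation(M.n_features)
        split_seed = int(rng.integers(2**31))
        for cov in coverages:
            keep = order[: max(2, math.ceil(cov * M.n_features))]
            sub = M.subset_features(keep)
            for name, flag in (("before", False), ("after", True)):
                rep = holdout_experiment(
                    sub, test_fraction=test_fraction, split_seed=split_seed,
                    transform=flag, k_neighbors=k_neighbors,
                )
                acc.setdefault((cov, name), []).append(rep.accuracy)
    rows = []
    for cov in coverages:
        rows.append({
            "coverage": cov,
            "mean_before": float(np.mean(acc[(cov, "before")])),
            "sd_before": float(np.std(acc[(cov, "before")], ddof=1)) if n_repeats > 1 else 0.0,
            "mean_after": float(np.mean(acc[(cov, "after")])),
            "sd_after": float(np.std(acc[(cov, "after")], ddof=1)) if n_repeats > 1 else 0.0,
            "n_repeats": n_repeats,
        })
    return pd.DataFrame(rows)
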