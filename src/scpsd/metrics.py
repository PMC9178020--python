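"""Cluster-separability and rank-concordance statistics.

All statistics take points as a ``cells x features`` array with per-cell
categorical labels:

* ``vrc`` — variance ratio criterion (Calinski-Harabasz index),
  ``(BGSS / (k - 1)) / (WGSS / (n - k))``.
* ``silhouette`` — mean and per-point silhouette coefficient
  ``s(i) = (b(i) - a(i)) / max(a(i), b(i))`` under euclidean,
  standardized-euclidean, cosine or correlation distance.
* ``pairwise_fisher`` / ``mfdr`` — two-class Fisher's discriminant ratio
  ``f_ij = (mu_i - mu_j)^2 / (s_i^2 + s_j^2)`` averaged over features, and
  its multi-class aggregate via trapezoidal integration over the (sorted)
  class axis.
* ``kendalls_w`` — coefficient of concordance among rankings, with a
  permutation p-value.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist
from scipy.stats import rankdata

__all__ = [
    "MetricReport",
    "RankTable",
    "SILHOUETTE_METRICS",
    "vrc",
    "silhouette",
    "pairwise_fisher",
    "mfdr",
    "kendalls_w",
    "rank_table_from_scores",
    "metric_report",
]

SILHOUETTE_METRICS = (
    "euclidean",
    "standardized-euclidean",
    "cosine-distance",
    "correlation-distance",
)

_SCIPY_METRIC = {
    "euclidean": "euclidean",
    "standardized-euclidean": "seuclidean",
    "cosine-distance": "cosine",
    "correlation-distance": "correlation",
}


@dataclass
class MetricReport:
    """Named collection of internal validation measures for one labelling."""

    vrc: float
    ss: dict[str, float]
    mfdr: float
    n_cells: int
    n_clusters: int
    distance_metrics_used: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "vrc": self.vrc,
            "ss": dict(self.ss),
            "mfdr": self.mfdr,
            "n_cells": self.n_cells,
            "n_clusters": self.n_clusters,
            "distance_metrics_used": list(self.distance_metrics_used),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_tsv(self) -> str:
        rows = [("vrc", self.vrc), ("mfdr", self.mfdr)]
        rows += [(f"ss_{m}", v) for m, v in self.ss.items()]
        rows += [("n_cells", self.n_cells), ("n_clusters", self.n_clusters)]
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


@dataclass
class RankTable:
    """``n`` items ranked by ``m`` judges; columns use midranks for ties."""

    ranks: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.ranks, dtype=np.float64)
        if R.ndim != 2 or R.shape[0] < 2 or R.shape[1] < 2:
            raise ValueError("rank table must be n>=2 items by m>=2 judges")
        n = R.shape[0]
        expected = n * (n + 1) / 2.0
        for j in range(R.shape[1]):
            col = R[:, j]
            if col.min() < 1 or col.max() > n or not np.isclose(col.sum(), expected):
                raise ValueError(
                    f"column {j} is not a 1..{n} midrank ranking (sum {col.sum()})"
                )
        self.ranks = R


def _split_labels(labels: Sequence) -> tuple[np.ndarray, list[str]]:
    lab = np.asarray([str(x) for x in labels])
    classes = sorted(set(lab))
    return lab, classes


def vrc(X: np.ndarray, labels: Sequence) -> float:
    """Variance ratio criterion: between- over within-cluster dispersion.

    Returns ``+inf`` (with a warning) when every cluster is perfectly tight
    (WGSS = 0).
    """
    X = np.asarray(X, dtype=np.float64)
    lab, classes = _split_labels(labels)
    k, n = len(classes), X.shape[0]
    if k < 2:
        raise ValueError("VRC requires at least 2 clusters")
    if n <= k:
        raise ValueError("VRC requires more points than clusters")
    grand = X.mean(axis=0)
    bgss = wgss = 0.0
    for c in classes:
        pts = X[lab == c]
        centroid = pts.mean(axis=0)
        bgss += len(pts) * float(((centroid - grand) ** 2).sum())
        wgss += float(((pts - centroid) ** 2).sum())
    if wgss == 0.0:
        warnings.warn("WGSS is zero: clusters are singletons or repeated points")
        return float("inf")
    return (bgss / (k - 1)) / (wgss / (n - k))


def _distance_matrix(X: np.ndarray, metric: str) -> np.ndarray:
    if metric not in _SCIPY_METRIC:
        raise ValueError(
            f"unknown metric {metric!r}; choose from {SILHOUETTE_METRICS}"
        )
    kwargs = {}
    if metric == "standardized-euclidean":
        # per-feature sample SD over the whole dataset; zero SDs -> 1
        v = X.var(axis=0, ddof=1)
        kwargs["V"] = np.where(v == 0, 1.0, v)
    return squareform(pdist(X, metric=_SCIPY_METRIC[metric], **kwargs))


def silhouette(
    X: np.ndarray, labels: Sequence, metric: str = "euclidean"
) -> tuple[float, np.ndarray]:
    """Mean and per-point silhouette coefficient.

    ``a(i)`` is the mean within-cluster distance excluding the point itself;
    ``b(i)`` the smallest mean distance to another cluster.  Points in
    singleton clusters get ``s(i) = 0``.
    """
    X = np.asarray(X, dtype=np.float64)
    lab, classes = _split_labels(labels)
    if len(classes) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    D = _distance_matrix(X, metric)
    n = len(lab)
    members = {c: np.flatnonzero(lab == c) for c in classes}
    s = np.zeros(n)
    for i in range(n):
        own = members[lab[i]]
        if own.size == 1:
            continue  # singleton convention: s = 0
        a = D[i, own].sum() / (own.size - 1)
        b = min(D[i, members[c]].mean() for c in classes if c != lab[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean()), s


def pairwise_fisher(X: np.ndarray, labels: Sequence, i, j) -> float:
    """Two-class Fisher's discriminant ratio, averaged over features.

    Per feature ``(mu_i - mu_j)^2 / (s_i^2 + s_j^2)`` with unbiased sample
    variances; features with zero pooled variance contribute 0.
    """
    X = np.asarray(X, dtype=np.float64)
    lab, _ = _split_labels(labels)
    i, j = str(i), str(j)
    Xi, Xj = X[lab == i], X[lab == j]
    if Xi.shape[0] == 0 or Xj.shape[0] == 0:
        raise ValueError(f"empty class among ({i!r}, {j!r})")
    mu = (Xi.mean(axis=0) - Xj.mean(axis=0)) ** 2
    var = (Xi.var(axis=0, ddof=1) if Xi.shape[0] > 1 else np.zeros(X.shape[1])) + (
        Xj.var(axis=0, ddof=1) if Xj.shape[0] > 1 else np.zeros(X.shape[1])
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(var > 0, mu / np.where(var > 0, var, 1.0), 0.0)
    return float(f.mean())


def mfdr(X: np.ndarray, labels: Sequence) -> float:
    """Multi-class Fisher's discriminant ratio.

    For each class ``i`` the vector ``f_i = (f_i1, ..., f_iN)`` (classes in
    sorted-name order, ``f_ii = 0``) is integrated by the trapezoidal rule
    over the unit-spaced class index; the result is the mean of these
    integrals over classes.
    """
    X = np.asarray(X, dtype=np.float64)
    lab, classes = _split_labels(labels)
    N = len(classes)
    if N < 2:
        raise ValueError("mFDR requires at least 2 classes")
    F = np.empty(N)
    for a, ci in enumerate(classes):
        f_i = np.array(
            [0.0 if ci == cj else pairwise_fisher(X, lab, ci, cj) for cj in classes]
        )
        F[a] = np.trapezoid(f_i)
    return float(F.mean())


def _w_statistic(R: np.ndarray) -> float:
    n, m = R.shape
    Ri = R.sum(axis=1)
    return float(12.0 * ((Ri - Ri.mean()) ** 2).sum() / (m**2 * (n**3 - n)))


def kendalls_w(
    R: RankTable | np.ndarray, n_perm: int = 9999, seed: int = 0
) -> tuple[float, float]:
    """Kendall's coefficient of concordance with a permutation p-value.

    The null is generated by independently permuting each judge's ranking;
    ``p = (#{W_perm >= W_obs} + 1) / (n_perm + 1)``.  Deterministic for a
    fixed seed.
    """
    if not isinstance(R, RankTable):
        R = RankTable(np.asarray(R))
    ranks = R.ranks
    w_obs = _w_statistic(ranks)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permuted(ranks, axis=0)
        if _w_statistic(perm) >= w_obs:
            count += 1
    return w_obs, (count + 1) / (n_perm + 1)


def rank_table_from_scores(scores: np.ndarray, higher_is_better: bool = True) -> RankTable:
    """Build a midrank table from raw scores (items x judges)."""
    S = np.asarray(scores, dtype=np.float64)
    if not higher_is_better:
        S = -S
    return RankTable(rankdata(S, axis=0))


def metric_report(
    X: np.ndarray,
    labels: Sequence,
    ss_metrics: Sequence[str] = ("euclidean",),
) -> MetricReport:
    """Compute VRC, silhouette (per requested metric) and mFDR for one matrix."""
    lab, classes = _split_labels(labels)
    ss = {m: silhouette(X, lab, m)[0] for m in ss_metrics}
    return MetricReport(
        vrc=vrc(X, lab),
        ss=ss,
        mfdr=mfdr(X, lab),
        n_cells=int(np.asarray(X).shape[0]),
        n_clusters=len(classes),
        distance_metrics_used=list(ss_metrics),
    )
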