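"""Seeded generator of clustered single-cell-like count matrices.

The model is the minimal standard scRNA-seq noise stack: lognormal baseline
expression per gene, per-cluster marker genes shifted up or down on the
log2 scale, lognormal per-cell size factors, negative-binomial counts with
a gene-level dispersion, and logistic mean-dependent dropout.  It is a
stand-in for real data regimes (clustered populations, overdispersion,
sparsity, library-size variation, optionally a rare population), not a
model of any particular dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .core import OmicsMatrix

__all__ = ["SimConfig", "simulate"]


@dataclass
class SimConfig:
    """Full parameterization of the synthetic count generator.

    Parameters
    ----------
    n_features, n_cells, n_clusters
        Matrix shape and number of cell populations.
    cluster_proportions
        Simplex vector of population sizes; ``None`` means equal.  Supports
        a rare population (e.g. ``[0.01, ...]``).
    marker_fraction
        Fraction of features acting as markers per cluster.
    log2_effect
        Log2 fold-change applied to each marker (direction random per
        marker); 0 gives label-free null data.
    nb_dispersion
        Negative-binomial dispersion ``phi`` (variance ``mu + phi mu^2``).
    dropout_midpoint, dropout_slope
        Dropout probability is ``logistic(slope * (midpoint - log1p(mu)))``:
        lowly expressed entries are zeroed more often.
    libsize_sigma
        SD of the lognormal per-cell size factor.
    seed
        Reproducibility seed; same seed, same matrix, bit for bit.
    """

    n_features: int = 500
    n_cells: int = 200
    n_clusters: int = 4
    cluster_proportions: list[float] | None = None
    marker_fraction: float = 0.1
    log2_effect: float = 3.0
    nb_dispersion: float = 0.4
    dropout_midpoint: float = 1.0
    dropout_slope: float = 1.0
    libsize_sigma: float = 0.3
    seed: int = 0

    def proportions(self) -> np.ndarray:
        if self.cluster_proportions is None:
            p = np.full(self.n_clusters, 1.0 / self.n_clusters)
        else:
            p = np.asarray(self.cluster_proportions, dtype=np.float64)
            if len(p) != self.n_clusters:
                raise ValueError("cluster_proportions length != n_clusters")
            if (p <= 0).any() or not np.isclose(p.sum(), 1.0):
                raise ValueError("cluster_proportions must be positive and sum to 1")
        return p


def _cluster_sizes(cfg: SimConfig) -> np.ndarray:
    """Largest-remainder apportionment of cells to clusters."""
    p = cfg.proportions()
    expected = p * cfg.n_cells
    if (expected < 1).any():
        raise ValueError(
            "infeasible proportions: expected cluster size below 1 cell"
        )
    sizes = np.floor(expected).astype(int)
    remainder = cfg.n_cells - sizes.sum()
    order = np.argsort(-(expected - sizes), kind="stable")
    sizes[order[:remainder]] += 1
    return sizes


def simulate(cfg: SimConfig) -> OmicsMatrix:
    """Draw one clustered count matrix with true labels attached."""
    if cfg.n_features < 1 or cfg.n_cells < 1 or cfg.n_clusters < 1:
        raise ValueError("n_features, n_cells, n_clusters must be positive")
    if not 0 <= cfg.marker_fraction <= 1:
        raise ValueError("marker_fraction must be in [0, 1]")
    if cfg.nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    rng = np.random.default_rng(cfg.seed)
    sizes = _cluster_sizes(cfg)

    # baseline mean expression per gene (lognormal, heavy right tail)
    base = rng.lognormal(mean=1.0, sigma=1.0, size=cfg.n_features)

    # per-cluster marker multipliers
    mult = np.ones((cfg.n_features, cfg.n_clusters))
    n_markers = int(round(cfg.marker_fraction * cfg.n_features))
    for c in range(cfg.n_clusters):
        markers = rng.choice(cfg.n_features, size=n_markers, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_markers)
        mult[markers, c] = 2.0 ** (signs * cfg.log2_effect)

    cluster_of = np.repeat(np.arange(cfg.n_clusters), sizes)
    size_factors = rng.lognormal(mean=0.0, sigma=cfg.libsize_sigma, size=cfg.n_cells)
    mu = base[:, None] * mult[:, cluster_of] * size_factors[None, :]

    r = 1.0 / cfg.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu)).astype(np.float64)

    p_drop = expit(cfg.dropout_slope * (cfg.dropout_midpoint - np.log1p(mu)))
    counts[rng.random(mu.shape) < p_drop] = 0.0

    width = len(str(cfg.n_features - 1))
    feature_ids = [f"gene{i:0{width}d}" for i in range(cfg.n_features)]
    width = len(str(cfg.n_cells - 1))
    cell_ids = [f"cell{j:0{width}d}" for j in range(cfg.n_cells)]
    labels = [f"cluster{c}" for c in cluster_of]
    return OmicsMatrix(counts, feature_ids, cell_ids, labels)
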