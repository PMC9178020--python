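"""Optional upstream normalizations: CPM and TF-IDF.

CPM (counts per million) rescales each cell's profile to a fixed library
size.  TF-IDF is the chromatin-accessibility convention: term frequency is
each peak's share of its cell's total accessibility, inverse document
frequency up-weights peaks detected in few cells, and the product is
log-transformed.  Both leave zeros at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import OmicsMatrix

__all__ = ["NormalizationSpec", "cpm_normalize", "tfidf_normalize", "apply_normalization"]

_DEFAULT_SCALE = {"cpm": 1e6, "tfidf": 1e4}


@dataclass
class NormalizationSpec:
    """Which normalization to apply upstream of the transform.

    ``scale_factor`` defaults to 1e6 for CPM and 1e4 for TF-IDF when left
    unset; ``log_transform`` only affects TF-IDF (on by default).
    """

    method: str = "none"
    scale_factor: float | None = None
    log_transform: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("none", "cpm", "tfidf"):
            raise ValueError(f"unknown normalization method {self.method!r}")
        if self.scale_factor is None and self.method != "none":
            self.scale_factor = _DEFAULT_SCALE[self.method]
        if self.scale_factor is not None and self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")


def _checked_colsums(M: OmicsMatrix) -> np.ndarray:
    colsums = M.values.sum(axis=0)
    bad = np.flatnonzero(colsums <= 0)
    if bad.size:
        raise ValueError(f"cell {M.cell_ids[bad[0]]!r} has zero total counts")
    return colsums


def cpm_normalize(M: OmicsMatrix, scale_factor: float = 1e6) -> OmicsMatrix:
    """Scale each cell column to sum to ``scale_factor`` (default one million)."""
    colsums = _checked_colsums(M)
    return M.with_values(M.values * (scale_factor / colsums))


def tfidf_normalize(
    M: OmicsMatrix, scale_factor: float = 1e4, log_transform: bool = True
) -> OmicsMatrix:
    """TF-IDF normalization of a peak-by-cell matrix.

    ``TF(k,j) = M(k,j) / colsum_j``; ``IDF(k) = m / #cells with peak k``;
    output ``log1p(TF * IDF * scale_factor)`` (or the raw product when
    ``log_transform`` is off).
    """
    colsums = _checked_colsums(M)
    n_detected = (M.values > 0).sum(axis=1)
    absent = np.flatnonzero(n_detected == 0)
    if absent.size:
        raise ValueError(
            f"peak {M.feature_ids[absent[0]]!r} present in zero cells; "
            "filter all-zero features first"
        )
    tf = M.values / colsums
    idf = M.n_cells / n_detected
    out = tf * idf[:, None] * scale_factor
    if log_transform:
        out = np.log1p(out)
    return M.with_values(out)


def apply_normalization(M: OmicsMatrix, spec: NormalizationSpec | None) -> OmicsMatrix:
    if spec is None or spec.method == "none":
        return M
    if spec.method == "cpm":
        return cpm_normalize(M, spec.scale_factor)
    return tfidf_normalize(M, spec.scale_factor, spec.log_transform)
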