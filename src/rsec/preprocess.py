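"""Dimensionality reduction, variable-gene filtering and sample distances.

These are the standard preparatory steps applied independently per
clustering run: PCA on samples (genes centred, not scaled), selection of
the most variable genes by median absolute deviation (MAD), and Euclidean
or correlation-based between-sample distances, the latter defined as
d(i, j) = (1 - rho(i, j)) / 2 so that entries lie in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.decomposition import PCA

from .core import ExpressionMatrix

MAD_SCALE = 1.4826  # consistency constant for Gaussian data; irrelevant to ranking

METRICS = ("euclidean", "pearson", "spearman")


@dataclass
class ReducedMatrix:
    """d dimensions x n samples; columns align with sample_ids."""

    values: np.ndarray
    method: str
    sample_ids: list[str]

    @property
    def d(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def reduce_pca(X: ExpressionMatrix, d: int) -> ReducedMatrix:
    """Top-d principal-component scores of the samples.

    Genes (features) are centred before the decomposition; components are
    ordered by decreasing explained variance with a deterministic sign
    convention.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    max_d = min(X.n_genes - 1, X.n_samples)
    if d > max_d:
        raise ValueError(f"d={d} exceeds min(G-1, n)={max_d}")
    pca = PCA(n_components=d, svd_solver="full")
    scores = pca.fit_transform(X.values.T)  # samples x d
    return ReducedMatrix(values=scores.T, method="PCA", sample_ids=list(X.sample_ids))


def gene_mad(X: ExpressionMatrix) -> np.ndarray:
    """Per-gene median absolute deviation across samples (scaled by 1.4826)."""
    med = np.median(X.values, axis=1, keepdims=True)
    return MAD_SCALE * np.median(np.abs(X.values - med), axis=1)


def filter_mad(X: ExpressionMatrix, n_genes: int) -> ExpressionMatrix:
    """Keep the ``n_genes`` most variable genes by MAD.

    Ties are broken by original gene order; the returned matrix preserves
    the input gene order among the kept genes.
    """
    if not 1 <= n_genes <= X.n_genes:
        raise ValueError(f"n_genes must be in [1, {X.n_genes}]")
    mad = gene_mad(X)
    # stable sort on -mad keeps earlier genes first among ties
    top = np.sort(np.argsort(-mad, kind="stable")[:n_genes])
    return X.subset_genes(top)


def sample_distance(values: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Symmetric between-sample distance matrix from a features x samples array.

    ``euclidean`` is the L2 distance on the column profiles.  ``pearson``
    and ``spearman`` use d = (1 - rho)/2, mapping perfect correlation to 0
    and perfect anti-correlation to 1.  Zero-variance profiles under a
    correlation metric get distance 1 to everything (with a warning).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("need a 2-D array with at least 2 sample columns")
    if metric == "euclidean":
        return squareform(pdist(values.T, metric="euclidean"))
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    profiles = values
    if metric == "spearman":
        profiles = np.apply_along_axis(rankdata, 0, values)  # average ranks for ties
    sd = profiles.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance profile(s) under {metric} "
            "metric; treated as maximally distant", RuntimeWarning)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(profiles.T)
    D = (1.0 - rho) / 2.0
    D[np.isnan(D)] = 1.0
    np.fill_diagonal(D, 0.0)
    # clip tiny negative values from rho rounding above 1
    return np.clip((D + D.T) / 2.0, 0.0, 1.0)
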