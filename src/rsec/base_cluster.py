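"""Base clustering algorithms plugged into the ensemble workflow.

Four methods ship by default:

``kmeans``
    Lloyd's algorithm on feature vectors, best of ``restarts`` runs.
``pam``
    Partitioning around medoids on a dissimilarity matrix (classic
    deterministic BUILD + SWAP).
``hierK``
    Average-linkage hierarchical clustering cut to K groups.
``hier01``
    Average-linkage clustering of a 0-1 dissimilarity matrix cut at height
    alpha, so that the mean within-cluster dissimilarity of every returned
    cluster is at most alpha.  This is the natural way to cluster a
    co-occurrence dissimilarity, where entries live on a fixed 0-1 scale:
    rather than requesting K clusters one constrains how dissimilar members
    of a cluster may be.

Additional methods can be registered by name through ``register_method``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .core import UNASSIGNED, ClusterLabels, renumber_by_size

K_METHODS = ("kmeans", "pam", "hierK")


@dataclass(frozen=True)
class BaseMethod:
    """Descriptor of a base algorithm: what it needs and what it consumes."""

    name: str
    requires: str  # "K" or "alpha"
    input_kind: str  # "features" or "dissimilarity"


BUILTIN_METHODS = {
    "kmeans": BaseMethod("kmeans", "K", "features"),
    "pam": BaseMethod("pam", "K", "dissimilarity"),
    "hierK": BaseMethod("hierK", "K", "dissimilarity"),
    "hier01": BaseMethod("hier01", "alpha", "dissimilarity"),
}

_REGISTRY: dict[str, Callable] = {}


def register_method(name: str, fn: Callable) -> None:
    """Register a user-supplied clusterer ``fn(data, K, seed) -> labels``."""
    _REGISTRY[name] = fn


def get_method(name: str) -> BaseMethod:
    if name in BUILTIN_METHODS:
        return BUILTIN_METHODS[name]
    if name in _REGISTRY:
        return BaseMethod(name, "K", "features")
    raise ValueError(f"unknown clustering method {name!r}")


def _as_dissimilarity(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.shape[0] == data.shape[1] and np.allclose(data, data.T) and \
            np.allclose(np.diag(data), 0):
        return data
    # features x samples -> Euclidean dissimilarity between samples
    return squareform(pdist(data.T, metric="euclidean"))


def _check_square(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError(f"dissimilarity matrix must be square, got {D.shape}")
    return D


def _pam(D: np.ndarray, K: int, max_sweeps: int = 200) -> np.ndarray:
    """Classic PAM: greedy BUILD then first-improvement SWAP sweeps.

    Deterministic: no random initialisation, ties broken by lowest index.
    """
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < K:
        dist_to_med = D[:, medoids].min(axis=1)
        gains = np.maximum(dist_to_med[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)
    for _ in range(max_sweeps):
        dmat = D[:, medoids]
        cost = dmat.min(axis=1).sum()
        best = (0.0, None)
        for mi, m in enumerate(medoids):
            others = [x for j, x in enumerate(medoids) if j != mi]
            base = D[:, others].min(axis=1) if others else np.full(n, np.inf)
            for h in range(n):
                if h in medoids:
                    continue
                new_cost = np.minimum(base, D[:, h]).sum()
                delta = new_cost - cost
                if delta < best[0] - 1e-12:
                    best = (delta, (mi, h))
        if best[1] is None:
            break
        mi, h = best[1]
        medoids[mi] = h
        medoids = sorted(medoids)
    assign = np.argmin(D[:, medoids], axis=1)
    return assign + 1


def cluster_k(data: np.ndarray, method: str | BaseMethod, K: int,
              restarts: int = 10, seed: int | None = None) -> ClusterLabels:
    """Cluster into exactly K groups with the named base method.

    ``data`` is features x samples for feature methods, or a square
    dissimilarity matrix for dissimilarity methods.  k-means takes the best
    of ``restarts`` runs by within-cluster sum of squares and is
    deterministic given ``seed``.
    """
    spec = get_method(method) if isinstance(method, str) else method
    if K < 2:
        raise ValueError("K must be >= 2")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    if spec.name in _REGISTRY:
        labels = np.asarray(_REGISTRY[spec.name](data, K, seed), dtype=int)
        return ClusterLabels(labels, name=spec.name, params={"K": K})
    if spec.name == "kmeans":
        X = np.asarray(data, dtype=float).T  # samples x features
        n = X.shape[0]
        if K > n:
            raise ValueError(f"K={K} exceeds n={n}")
        km = KMeans(n_clusters=K, n_init=restarts,
                    random_state=None if seed is None else int(seed) % (2**31))
        labels = km.fit_predict(X) + 1
    else:
        D = _check_square(_as_dissimilarity(data))
        n = D.shape[0]
        if K > n:
            raise ValueError(f"K={K} exceeds n={n}")
        if spec.name == "pam":
            labels = _pam(D, K)
        elif spec.name == "hierK":
            Z = linkage(squareform(D, checks=False), method="average")
            labels = fcluster(Z, t=K, criterion="maxclust")
        else:
            raise ValueError(f"method {spec.name!r} does not take K")
    return ClusterLabels(renumber_by_size(labels), name=spec.name, params={"K": K})


def _tree_blocks(node, D: np.ndarray, alpha: float, blocks: list[list[int]]) -> None:
    """Cut the linkage tree at height alpha; additionally require the mean
    pairwise dissimilarity within a block to be <= alpha, splitting at the
    next lower merge otherwise."""
    leaves = node.pre_order(lambda x: x.id)
    if node.is_leaf():
        blocks.append(leaves)
        return
    if node.dist <= alpha:
        sub = D[np.ix_(leaves, leaves)]
        m = len(leaves)
        if sub.sum() / (m * (m - 1)) <= alpha:
            blocks.append(leaves)
            return
    _tree_blocks(node.get_left(), D, alpha, blocks)
    _tree_blocks(node.get_right(), D, alpha, blocks)


def cluster_01(D: np.ndarray, alpha: float, min_size: int = 1) -> ClusterLabels:
    """Cluster a 0-1 dissimilarity by constraining within-cluster dissimilarity.

    Average-linkage tree on D cut at height ``alpha``; blocks with fewer
    than ``min_size`` members become unassigned.  Every returned cluster has
    mean pairwise dissimilarity <= alpha.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    D = _check_square(D)
    if D.min() < -1e-9 or D.max() > 1 + 1e-9:
        raise ValueError("hier01 requires dissimilarities in [0, 1]")
    n = D.shape[0]
    if n == 1:
        return ClusterLabels(np.array([1 if min_size <= 1 else UNASSIGNED]),
                             name="hier01", params={"alpha": alpha})
    Z = linkage(squareform(D, checks=False), method="average")
    blocks: list[list[int]] = []
    _tree_blocks(to_tree(Z), D, alpha, blocks)
    labels = np.full(n, UNASSIGNED, dtype=int)
    nxt = 1
    for b in blocks:
        if len(b) >= min_size:
            labels[b] = nxt
            nxt += 1
    return ClusterLabels(renumber_by_size(labels), name="hier01",
                         params={"alpha": alpha, "min_size": min_size})


def select_k_silhouette(data: np.ndarray, method: str | BaseMethod,
                        k_range, restarts: int = 10,
                        seed: int | None = None) -> int:
    """K maximising the mean silhouette width; ties go to the smallest K."""
    ks = [int(k) for k in k_range]
    if not ks:
        raise ValueError("empty k_range")
    spec = get_method(method) if isinstance(method, str) else method
    if len(ks) == 1:
        return ks[0]
    if spec.input_kind == "dissimilarity" or spec.name == "hier01":
        D = _as_dissimilarity(data)
        sil_input, sil_metric = D, "precomputed"
    else:
        sil_input, sil_metric = np.asarray(data, dtype=float).T, "euclidean"
    best_k, best_s = None, -np.inf
    for k in sorted(ks):
        labels = cluster_k(data, spec, k, restarts=restarts, seed=seed).labels
        s = silhouette_score(sil_input, labels, metric=sil_metric)
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    return best_k


def filter_min_size(labels: ClusterLabels, min_size: int) -> ClusterLabels:
    """Unassign clusters smaller than ``min_size``; renumber the rest by size."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    out = labels.labels.copy()
    for c in labels.cluster_ids():
        if (out == c).sum() < min_size:
            out[out == c] = UNASSIGNED
    return ClusterLabels(renumber_by_size(out), name=labels.name,
                         params={**labels.params, "min_size": min_size})
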