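"""Robustness wrappers: subsampling co-occurrence and sequential detection.

Subsampling clusters many random subsets of the samples with a base
algorithm and summarises the ensemble as a dissimilarity
``D_ij = 1 - p_ij``, where ``p_ij`` is the proportion of subsamples
containing both i and j in which the pair landed in the same cluster.
Pairs on a 0-1 scale like this can then be clustered by constraining the
within-cluster dissimilarity (``cluster_01``) instead of fixing K.

Sequential detection generalises tight clustering: clusters are found one
at a time.  At each round the remaining samples are re-clustered via
subsampling at K = k0, k0+1, ...; candidate clusters at successive K are
compared by their Jaccard overlap |A n B| / |A u B|, and the first
candidate whose best overlap reaches beta is declared found and removed.
Samples never captured by a stable cluster stay unassigned, which is the
desired behaviour for boundary or contaminant cells.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .base_cluster import BaseMethod, cluster_01, cluster_k, get_method
from .core import UNASSIGNED, ClusterLabels, renumber_by_size
from ._rng import child_seed

logger = logging.getLogger(__name__)


@dataclass
class SubsampleSpec:
    """How to build the co-occurrence dissimilarity.

    B subsamples of size floor(prop * n) are drawn without replacement and
    clustered with ``method`` at ``K`` clusters.
    """

    B: int = 100
    prop: float = 0.7
    method: str = "kmeans"
    K: int = 4
    restarts: int = 10
    seed: int = 0
    strict_coverage: bool = False
    denominator: str = "pair"  # "pair": subsamples containing both; "B": all

    def __post_init__(self) -> None:
        if self.B < 2:
            raise ValueError("B must be >= 2")
        if not 0 < self.prop < 1:
            raise ValueError("prop must be in (0, 1)")
        if self.denominator not in ("pair", "B"):
            raise ValueError("denominator must be 'pair' or 'B'")


@dataclass
class SequentialSpec:
    """Controls the sequential (tight-cluster style) detection loop."""

    k0: int = 4
    beta: float = 0.8
    k_max: int | None = None  # default k0 + 10
    top_candidates: int = 5
    remain_min: int | None = None  # default min_size
    alpha: float = 0.1
    min_size: int = 5

    def __post_init__(self) -> None:
        if self.k0 < 2:
            raise ValueError("k0 must be >= 2")
        if not 0 <= self.beta < 1:
            raise ValueError("beta must be in [0, 1)")
        if self.k_max is None:
            self.k_max = self.k0 + 10
        if self.k_max < self.k0:
            raise ValueError("k_max must be >= k0")
        if self.remain_min is None:
            self.remain_min = max(self.min_size, 2)


@dataclass
class CoDissimilarity:
    """n x n dissimilarity plus, in subsample mode, co-draw counts."""

    D: np.ndarray
    counts: np.ndarray | None = None
    label_rows: np.ndarray | None = None  # B x n per-subsample labels, -1 absent

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        if not np.allclose(D, D.T):
            raise ValueError("dissimilarity must be symmetric")
        if np.any(np.diag(D) != 0):
            raise ValueError("dissimilarity diagonal must be zero")
        if D.min() < 0 or D.max() > 1:
            raise ValueError("dissimilarity entries must lie in [0, 1]")
        self.D = D


def cooccurrence_from_labels(label_rows: np.ndarray,
                             denominator: str = "pair",
                             n_total: int | None = None) -> CoDissimilarity:
    """Pair-counting summary of a stack of (partial) label vectors.

    ``label_rows`` is m x n with -1 for samples absent/unassigned in a row.
    p_ij = (# rows with i, j co-clustered) / (# rows with both assigned)
    (or / m when ``denominator='B'``).  Pairs never jointly assigned get
    dissimilarity 1 and are reported through ``counts``.
    """
    L = np.asarray(label_rows, dtype=int)
    m, n = L.shape
    together = np.zeros((n, n))
    both = np.zeros((n, n))
    for r in range(m):
        row = L[r]
        a = row != UNASSIGNED
        both[np.ix_(a, a)] += 1
        for c in np.unique(row[a]):
            mem = row == c
            together[np.ix_(mem, mem)] += 1
    denom = both if denominator == "pair" else float(m)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(np.asarray(denom) > 0, together / denom, 0.0)
    D = 1.0 - p
    never = both == 0
    np.fill_diagonal(never, False)
    if never.any():
        D[never] = 1.0
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, 1.0)
    return CoDissimilarity(D=D, counts=both.astype(int))


def subsample_cooccurrence(data: np.ndarray, spec: SubsampleSpec) -> CoDissimilarity:
    """Co-occurrence dissimilarity from B clustered subsamples.

    ``data`` is features x samples (or a square dissimilarity for
    dissimilarity-based base methods).  Only drawn samples are clustered;
    held-out samples simply do not contribute to that subsample's pairs.
    """
    data = np.asarray(data, dtype=float)
    method = get_method(spec.method)
    n = data.shape[1]
    size = int(np.floor(spec.prop * n))
    if size < spec.K:
        raise ValueError(
            f"subsample size floor({spec.prop}*{n})={size} < K={spec.K}")
    rows = np.full((spec.B, n), UNASSIGNED, dtype=int)
    for b in range(spec.B):
        rng = np.random.default_rng(child_seed(spec.seed, f"subsample:{b}"))
        idx = np.sort(rng.choice(n, size=size, replace=False))
        sub = data[np.ix_(idx, idx)] if _is_square_dissim(data, method) \
            else data[:, idx]
        labs = cluster_k(sub, method, spec.K, restarts=spec.restarts,
                         seed=child_seed(spec.seed, f"cluster:{b}"))
        rows[b, idx] = labs.labels
    co = cooccurrence_from_labels(rows, denominator=spec.denominator)
    co.label_rows = rows
    never = (co.counts == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        msg = (f"{int(never.sum() // 2)} sample pair(s) never co-subsampled at "
               f"B={spec.B}, prop={spec.prop}; their dissimilarity is set to 1")
        if spec.strict_coverage:
            raise RuntimeError(msg + " (strict coverage requested)")
        warnings.warn(msg, RuntimeWarning)
    return co


def _is_square_dissim(data: np.ndarray, method: BaseMethod) -> bool:
    return (method.input_kind == "dissimilarity"
            and data.shape[0] == data.shape[1]
            and np.allclose(data, data.T))


def overlap_ratio(A, B) -> float:
    """Jaccard overlap |A n B| / |A u B| between two sample sets."""
    A, B = set(A), set(B)
    if not A or not B:
        raise ValueError("overlap_ratio requires nonempty sets")
    return len(A & B) / len(A | B)


def _candidates(labels: ClusterLabels, top: int) -> list[np.ndarray]:
    """The ``top`` largest clusters as index arrays, largest first."""
    ids = labels.cluster_ids()
    sized = sorted(ids, key=lambda c: (-(labels.labels == c).sum(), c))
    return [np.flatnonzero(labels.labels == c) for c in sized[:top]]


def sequential_detect(data: np.ndarray, sub: SubsampleSpec,
                      seq: SequentialSpec) -> ClusterLabels:
    """Iteratively find and remove one stable cluster at a time.

    Returns labels over all samples; samples for which no stable cluster
    was ever found are unassigned.  Fresh subsample draws are used at every
    K (seeded deterministically from ``sub.seed``).
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[1]
    out = np.full(n, UNASSIGNED, dtype=int)
    remaining = np.arange(n)
    next_label = 1
    rounds = 0
    while remaining.size >= seq.remain_min:
        found = _one_round(data, remaining, sub, seq, round_id=rounds)
        rounds += 1
        if found is None:
            logger.info("sequential: no stable cluster in %d remaining samples; "
                        "stopping", remaining.size)
            break
        out[remaining[found]] = next_label
        next_label += 1
        keep = np.ones(remaining.size, dtype=bool)
        keep[found] = False
        remaining = remaining[keep]
    return ClusterLabels(renumber_by_size(out), name="sequential",
                         params={"k0": seq.k0, "beta": seq.beta,
                                 "alpha": seq.alpha, "min_size": seq.min_size})


def _one_round(data, remaining, sub: SubsampleSpec, seq: SequentialSpec,
               round_id: int):
    """One sequential round: escalate K until a candidate is stable."""
    method = get_method(sub.method)
    sub_data = data[np.ix_(remaining, remaining)] \
        if _is_square_dissim(data, method) else data[:, remaining]
    n_rem = remaining.size
    prev: list[np.ndarray] | None = None
    for k in range(seq.k0, seq.k_max + 1):
        if int(np.floor(sub.prop * n_rem)) < k or k > n_rem:
            break
        spec_k = replace(sub, K=k,
                         seed=child_seed(sub.seed, f"round:{round_id}:k:{k}"))
        co = subsample_cooccurrence(sub_data, spec_k)
        labs = cluster_01(co.D, seq.alpha, seq.min_size)
        cands = _candidates(labs, seq.top_candidates)
        if prev is not None and prev and cands:
            best, best_j = -1.0, None
            for a in prev:
                for j, b in enumerate(cands):
                    r = overlap_ratio(a, b)
                    if r > best:
                        best, best_j = r, j
            if best >= seq.beta and best_j is not None:
                return cands[best_j]  # the (k+1)-side cluster of the best pair
        prev = cands
    return None
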