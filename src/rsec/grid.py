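"""Parameter-grid expansion and batch execution of candidate clusterings.

A grid declares axes (number of PCA dimensions, alpha, beta, k0, minimum
cluster size, base method, distance metric, subsampling and sequential
switches); every combination becomes one clustering run with its own
deterministic child seed derived from the run name, so results do not
depend on execution order or worker count.  The single-call ``rsec``
entry point runs the whole workflow: many clusterings with subsampling and
sequential detection, consensus, dendrogram and merge.
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
from joblib import Parallel, delayed

from ._rng import child_seed
from .base_cluster import cluster_01, cluster_k, filter_min_size, get_method
from .consensus import ConsensusSpec, make_consensus
from .core import (UNASSIGNED, ClusterLabels, ClusterMatrix, ExpressionMatrix,
                   RSECResult)
from .merge import (ClusterHierarchy, MergeSpec, cluster_medians,
                    make_dendrogram, merge_clusters)
from .preprocess import filter_mad, reduce_pca, sample_distance
from .robust import SequentialSpec, SubsampleSpec, sequential_detect, \
    subsample_cooccurrence

logger = logging.getLogger(__name__)

AXIS_NAMES = ("dims", "alpha", "beta", "k0", "minSize", "method", "metric",
              "subsample", "sequential")

_DEFAULTS = {"dims": None, "alpha": 0.1, "beta": 0.8, "k0": 4, "minSize": 1,
             "method": "kmeans", "metric": "euclidean",
             "subsample": True, "sequential": True}


@dataclass
class ParameterGrid:
    """Axes (cartesian) plus fixed, non-varied options.

    ``options`` holds scalar settings shared by all runs (subsample count
    B, subsample fraction, k-means restarts, k_max, ...).
    """

    axes: dict[str, list[Any]] = field(default_factory=dict)
    options: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, values in self.axes.items():
            if name not in AXIS_NAMES:
                raise ValueError(f"unknown grid axis {name!r}; "
                                 f"allowed: {AXIS_NAMES}")
            if not isinstance(values, (list, tuple)) or len(values) == 0:
                raise ValueError(f"axis {name!r} must be a nonempty list")


@dataclass
class RunSpec:
    """One grid combination with its canonical name."""

    name: str
    params: dict[str, Any]


def _canonical_name(axes: list[str], combo: tuple) -> str:
    return ",".join(f"{a}={v}" for a, v in zip(axes, combo))


def _incompatible(params: dict[str, Any], axes: dict[str, list]) -> str | None:
    """Reason a combination is dropped, or None if it is runnable.

    Combinations whose value on an inert axis differs from that axis's
    first value are duplicates of an already-kept combination and are
    dropped with a logged reason.
    """
    method = get_method(str(params.get("method", _DEFAULTS["method"])))
    subsample = bool(params.get("subsample", _DEFAULTS["subsample"]))
    sequential = bool(params.get("sequential", _DEFAULTS["sequential"]))
    metric = params.get("metric", _DEFAULTS["metric"])
    if method.name == "kmeans" and metric != "euclidean":
        return f"kmeans requires features; metric {metric!r} yields a dissimilarity"
    if method.requires == "alpha" and (subsample or sequential):
        pass  # hier01 inside resampling is fine
    uses_alpha = subsample or sequential or method.requires == "alpha"
    if "alpha" in axes and not uses_alpha and \
            params["alpha"] != axes["alpha"][0]:
        return "alpha is unused by a pure-K method without subsampling"
    if "beta" in axes and not sequential and params["beta"] != axes["beta"][0]:
        return "beta is unused when sequential detection is off"
    return None


def expand_grid(grid: ParameterGrid,
                return_dropped: bool = False):
    """Cartesian product of the axes in declared order, minus incompatibles."""
    axis_names = list(grid.axes.keys())
    if not axis_names:
        raise ValueError("grid has no axes")
    kept: list[RunSpec] = []
    dropped: list[tuple[str, str]] = []
    for combo in itertools.product(*(grid.axes[a] for a in axis_names)):
        params = dict(zip(axis_names, combo))
        name = _canonical_name(axis_names, combo)
        reason = _incompatible(params, grid.axes)
        if reason is not None:
            logger.info("dropping combination %s: %s", name, reason)
            dropped.append((name, reason))
            continue
        kept.append(RunSpec(name=name, params=params))
    if not kept:
        raise ValueError("grid expands to zero runnable combinations")
    return (kept, dropped) if return_dropped else kept


def _prepare_data(X: ExpressionMatrix, params: dict[str, Any],
                  options: dict[str, Any]) -> np.ndarray:
    """Per-run preprocessing: PCA scores or a correlation dissimilarity."""
    metric = params.get("metric", _DEFAULTS["metric"])
    dims = params.get("dims", _DEFAULTS["dims"])
    if metric == "euclidean":
        if dims is not None:
            d = min(int(dims), X.n_genes - 1, X.n_samples)
            return reduce_pca(X, d).values
        return X.values
    n_var = int(options.get("mad_genes", min(1000, X.n_genes)))
    Xf = filter_mad(X, min(n_var, X.n_genes))
    return sample_distance(Xf.values, metric)


def run_one(X: ExpressionMatrix, rp: RunSpec, seed: int,
            options: dict[str, Any]) -> ClusterLabels:
    """Execute a single grid combination."""
    p = {**_DEFAULTS, **rp.params}
    run_seed = child_seed(seed, rp.name)
    data = _prepare_data(X, p, options)
    min_size = int(p["minSize"])
    restarts = int(options.get("restarts", 10))
    if p["sequential"]:
        sub = SubsampleSpec(B=int(options.get("B", 100)),
                            prop=float(options.get("prop", 0.7)),
                            method=str(p["method"]), K=int(p["k0"]),
                            restarts=restarts, seed=run_seed)
        seq = SequentialSpec(k0=int(p["k0"]), beta=float(p["beta"]),
                             k_max=options.get("k_max"),
                             top_candidates=int(options.get("top_candidates", 5)),
                             remain_min=options.get("remain_min"),
                             alpha=float(p["alpha"]), min_size=min_size)
        labels = sequential_detect(data, sub, seq)
    elif p["subsample"]:
        sub = SubsampleSpec(B=int(options.get("B", 100)),
                            prop=float(options.get("prop", 0.7)),
                            method=str(p["method"]), K=int(p["k0"]),
                            restarts=restarts, seed=run_seed)
        co = subsample_cooccurrence(data, sub)
        labels = cluster_01(co.D, float(p["alpha"]), min_size)
    else:
        labels = cluster_k(data, str(p["method"]), K=int(p["k0"]),
                           restarts=restarts, seed=run_seed)
        labels = filter_min_size(labels, min_size)
    return ClusterLabels(labels.labels, name=rp.name, params=dict(rp.params))


def run_cluster_many(X: ExpressionMatrix, grid: ParameterGrid,
                     seed: int = 0, workers: int = 1) -> ClusterMatrix:
    """Run every grid combination and stack the results.

    Individual run failures become all-unassigned rows annotated with the
    error; the batch only fails if no run succeeds.
    """
    runs = expand_grid(grid)

    def safe(rp: RunSpec) -> ClusterLabels:
        t0 = time.perf_counter()
        try:
            labels = run_one(X, rp, seed, grid.options)
            status = "ok"
        except Exception as exc:  # failure isolation across a large grid
            labels = ClusterLabels(np.full(X.n_samples, UNASSIGNED, dtype=int),
                                   name=rp.name,
                                   params={**rp.params, "error": str(exc)})
            status = f"failed: {exc}"
        logger.info("run %s: %s (%.2fs, %d assigned, K=%d)", rp.name, status,
                    time.perf_counter() - t0,
                    int((labels.labels != UNASSIGNED).sum()), labels.n_clusters)
        return labels

    if workers > 1:
        rows = Parallel(n_jobs=workers)(delayed(safe)(rp) for rp in runs)
    else:
        rows = [safe(rp) for rp in runs]
    if all("error" in r.params for r in rows):
        raise RuntimeError("every grid run failed")
    return ClusterMatrix(rows=list(rows), sample_ids=list(X.sample_ids))


def rsec(X: ExpressionMatrix, grid: ParameterGrid,
         consensus_spec: ConsensusSpec | None = None,
         merge_spec: MergeSpec | None = None,
         seed: int = 0, workers: int = 1) -> RSECResult:
    """The full workflow in one call.

    Subsampling and sequential detection are switched on for every run (the
    recommended robust configuration); the resulting clusterings are
    combined into a consensus, the consensus clusters are ordered on their
    gene medians, and similar sister clusters are merged.
    """
    consensus_spec = consensus_spec or ConsensusSpec()
    merge_spec = merge_spec or MergeSpec()
    grid = ParameterGrid(
        axes={**grid.axes, "subsample": [True], "sequential": [True]},
        options=dict(grid.options))
    cm = run_cluster_many(X, grid, seed=seed, workers=workers)
    consensus = make_consensus(cm, consensus_spec)
    hierarchy: Optional[ClusterHierarchy] = None
    node_estimates: dict[str, float] = {}
    if consensus.n_clusters >= 2:
        med = cluster_medians(X, consensus)
        hierarchy = make_dendrogram(med, [int(c) for c in consensus.cluster_ids()])
        merged, hierarchy = merge_clusters(X, consensus, hierarchy, merge_spec)
        node_estimates = {n.name: float(n.estimate)
                          for n in hierarchy.internal_nodes()}
    else:
        merged = ClusterLabels(consensus.labels.copy(), name="merged",
                               params={"note": "single consensus cluster"})
    result = RSECResult(
        cluster_matrix=cm, consensus=consensus, merged=merged,
        hierarchy=hierarchy, node_estimates=node_estimates,
        provenance={"seed": int(seed),
                    "grid_axes": {k: list(v) for k, v in grid.axes.items()},
                    "grid_options": dict(grid.options),
                    "consensus": vars(consensus_spec).copy(),
                    "merge": vars(merge_spec).copy()})
    result.check_coarsening()
    return result
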