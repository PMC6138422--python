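"""Cluster hierarchy construction and DE-guided cluster merging.

Consensus clustering tends to oversplit: it favours agreement across many
runs, so one biological population can end up as several small clusters.
Rather than comparing all pairs of clusters, the clusters are first ordered
hierarchically (average-linkage tree on the per-cluster gene medians); each
internal node then defines a two-group comparison between the samples under
its left and right children.  Every gene is tested with the moderated-t
engine, the proportion of differentially expressed genes at the node is
estimated, and sister nodes whose estimate falls below a cutoff are merged,
working from the leaves upward.  A node only merges if everything below it
already merged, so the merged clustering is always a coarsening of the
consensus along the fixed tree.

Three estimators of the DE proportion are provided:

``adjP``
    Fraction of genes significant after Benjamini-Hochberg adjustment at
    ``fdr_level``, optionally also requiring |logFC| >= ``lfc_min``.
``pi0-storey``
    1 - pi0 with Storey's pi0 = #{p > lambda} / ((1 - lambda) G) at
    lambda = 0.5.
``locfdr-lite``
    1 - pi0 from central matching on folded z-scores z = Phi^-1(1 - p/2):
    the fraction of z in the null-central window [0, 1] is compared with
    the N(0,1) mass of that window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .core import UNASSIGNED, ClusterLabels, ExpressionMatrix, renumber_by_size
from .markers import ContrastSet, fit_de

ESTIMATORS = ("adjP", "pi0-storey", "locfdr-lite")


@dataclass
class HNode:
    """A node of the cluster hierarchy.

    Leaves carry a single consensus cluster id; internal nodes carry the
    merge height, the per-node DE-proportion estimate and the merged flag.
    """

    name: str
    clusters: tuple[int, ...]
    height: float = 0.0
    left: Optional["HNode"] = None
    right: Optional["HNode"] = None
    estimate: Optional[float] = None
    merged: bool = False

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class ClusterHierarchy:
    """Binary tree over consensus cluster ids."""

    root: HNode
    cluster_ids: list[int] = field(default_factory=list)

    def leaf_clusters(self) -> list[int]:
        return sorted(self.root.clusters)

    def internal_nodes(self) -> list[HNode]:
        """Internal nodes in post-order (children before parents)."""
        out: list[HNode] = []

        def rec(node: HNode) -> None:
            if node.is_leaf:
                return
            rec(node.left)
            rec(node.right)
            out.append(node)

        rec(self.root)
        return out

    def iter_nodes(self) -> Iterator[HNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            if not node.is_leaf:
                stack.extend([node.right, node.left])


@dataclass
class MergeSpec:
    """Cutoff and estimator for the merge decision."""

    cutoff: float = 0.05
    method: str = "adjP"
    lfc_min: float = 0.0
    fdr_level: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.cutoff < 1:
            raise ValueError("cutoff must be in (0, 1)")
        if self.method not in ESTIMATORS:
            raise ValueError(f"method must be one of {ESTIMATORS}")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")


def cluster_medians(X: ExpressionMatrix, labels: ClusterLabels) -> np.ndarray:
    """K x G matrix of per-cluster gene medians (unassigned samples excluded).

    Rows follow the sorted cluster ids of ``labels``.
    """
    ids = labels.cluster_ids()
    if ids.size < 2:
        raise ValueError("need at least 2 clusters to build a hierarchy")
    rows = []
    for c in ids:
        members = labels.members(int(c))
        if members.size == 0:
            raise ValueError(f"cluster {c} is empty")
        rows.append(np.median(X.values[:, members], axis=1))
    return np.vstack(rows)


def make_dendrogram(medians: np.ndarray,
                    cluster_ids: list[int] | None = None) -> ClusterHierarchy:
    """Average-linkage tree on Euclidean distances between median profiles."""
    medians = np.asarray(medians, dtype=float)
    K = medians.shape[0]
    if K < 2:
        raise ValueError("need at least 2 clusters")
    ids = list(cluster_ids) if cluster_ids is not None else list(range(1, K + 1))
    Z = linkage(medians, method="average", metric="euclidean")
    stree = to_tree(Z)
    counter = {"n": 0}

    def convert(snode) -> HNode:
        if snode.is_leaf():
            cid = ids[snode.id]
            return HNode(name=f"c{cid}", clusters=(cid,), height=0.0)
        left = convert(snode.get_left())
        right = convert(snode.get_right())
        # deterministic child order: smaller minimum leaf id on the left
        if min(right.clusters) < min(left.clusters):
            left, right = right, left
        counter["n"] += 1
        return HNode(name=f"node{counter['n']}",
                     clusters=tuple(sorted(left.clusters + right.clusters)),
                     height=float(snode.dist), left=left, right=right)

    root = convert(stree)
    # rename internal nodes top-down (root = node1) for stable reporting
    idx = {"n": 0}

    def rename(node: HNode) -> None:
        if node.is_leaf:
            return
        idx["n"] += 1
        node.name = f"node{idx['n']}"
        rename(node.left)
        rename(node.right)

    rename(root)
    return ClusterHierarchy(root=root, cluster_ids=ids)


def node_de_pvalues(X: ExpressionMatrix, labels: ClusterLabels,
                    node: HNode) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene p-values and logFCs for left-child vs right-child samples.

    Samples under each child are pooled into one group; the moderated-t
    engine then performs the two-group comparison.  The logFC is the
    difference between group means on the log scale.
    """
    if node.is_leaf:
        raise ValueError("node DE is defined for internal nodes only")
    lab = labels.labels
    grp = np.full(lab.size, UNASSIGNED, dtype=int)
    for c in node.left.clusters:
        grp[lab == c] = 1
    for c in node.right.clusters:
        grp[lab == c] = 2
    if (grp == 1).sum() < 2 or (grp == 2).sum() < 2:
        raise ValueError(f"degenerate node {node.name}: a child has < 2 samples")
    two = ClusterLabels(grp, name=node.name)
    cs = ContrastSet(contrasts=[(node.name, np.array([1.0, -1.0]))],
                     family="pairwise", cluster_ids=[1, 2])
    res = fit_de(X, two, cs)
    return res["p"].to_numpy(), res["logFC"].to_numpy()


def estimate_prop_de(p: np.ndarray, lfc: np.ndarray | None,
                     spec: MergeSpec) -> float:
    """Estimated proportion of DE genes from a p-value vector."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    G = p.size
    if spec.method == "adjP":
        sig = multipletests(p, method="fdr_bh")[1] <= spec.fdr_level
        if spec.lfc_min > 0:
            if lfc is None:
                raise ValueError("lfc_min > 0 requires log-fold-changes")
            sig &= np.abs(np.asarray(lfc)) >= spec.lfc_min
        return float(sig.mean())
    if spec.method == "pi0-storey":
        lam = 0.5
        pi0 = (p > lam).sum() / ((1 - lam) * G)
        return float(np.clip(1.0 - pi0, 0.0, 1.0))
    # locfdr-lite: central matching on folded z
    z = norm.isf(np.clip(p, 1e-300, 1.0) / 2.0)
    window_mass = norm.cdf(1.0) - norm.cdf(-1.0)
    pi0 = (z <= 1.0).mean() / window_mass
    return float(np.clip(1.0 - pi0, 0.0, 1.0))


def annotate_estimates(X: ExpressionMatrix, labels: ClusterLabels,
                       hierarchy: ClusterHierarchy, spec: MergeSpec) -> None:
    """Compute and store the DE-proportion estimate at every internal node.

    Estimates are computed once on the fixed tree; degenerate nodes (a
    child with < 2 samples) get estimate 1.0, i.e. are never merged.
    """
    for node in hierarchy.internal_nodes():
        try:
            p, lfc = node_de_pvalues(X, labels, node)
        except ValueError:
            node.estimate = 1.0
            continue
        node.estimate = estimate_prop_de(p, lfc, spec)


def merge_clusters(X: ExpressionMatrix, labels: ClusterLabels,
                   hierarchy: ClusterHierarchy,
                   spec: MergeSpec) -> tuple[ClusterLabels, ClusterHierarchy]:
    """Collapse sister nodes with few DE genes, from the leaves upward.

    A node is merged iff its estimate is below ``spec.cutoff`` and all its
    internal descendants merged; each maximal merged subtree collapses into
    a single cluster.  Returns the relabeled clustering (renumbered by
    size) and the annotated hierarchy.
    """
    if any(n.estimate is None for n in hierarchy.internal_nodes()):
        annotate_estimates(X, labels, hierarchy, spec)
    for node in hierarchy.internal_nodes():  # post-order: children first
        kids_ok = all(
            child.is_leaf or child.merged
            for child in (node.left, node.right))
        node.merged = bool(kids_ok and node.estimate < spec.cutoff)

    groups: list[tuple[int, ...]] = []

    def collect(node: HNode) -> None:
        if node.is_leaf or node.merged:
            groups.append(node.clusters)
            return
        collect(node.left)
        collect(node.right)

    collect(hierarchy.root)
    out = np.full(labels.labels.size, UNASSIGNED, dtype=int)
    for new_id, clusters in enumerate(groups, start=1):
        for c in clusters:
            out[labels.labels == c] = new_id
    merged = ClusterLabels(renumber_by_size(out), name="merged",
                           params={"cutoff": spec.cutoff, "method": spec.method,
                                   "lfc_min": spec.lfc_min})
    return merged, hierarchy
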