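"""Comparison utilities: label alignment, cross-tabulation, Newick export.

These are the algorithmic cores behind the usual comparison plots: aligning
cluster labels across many clusterings so similar clusters share an id,
ordering samples so aligned blocks are contiguous, expressing one
clustering as column-proportions of another, and serialising the cluster
hierarchy to Newick.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .core import UNASSIGNED, ClusterLabels, ClusterMatrix
from .merge import ClusterHierarchy, HNode


@dataclass
class Alignment:
    """Relabeled cluster matrix (shared ids) plus a sample ordering."""

    relabeled: ClusterMatrix
    sample_order: np.ndarray


def _match_row(labels: np.ndarray, reference: np.ndarray,
               next_id: int) -> tuple[np.ndarray, int]:
    """Map one row's clusters onto the reference's shared ids.

    Hungarian assignment on the contingency table maximises the total
    overlap; clusters with no overlapping match get fresh ids.
    """
    out = np.full(labels.size, UNASSIGNED, dtype=int)
    row_ids = np.unique(labels[labels != UNASSIGNED])
    ref_ids = np.unique(reference[reference != UNASSIGNED])
    if row_ids.size == 0:
        return out, next_id
    if ref_ids.size == 0:
        for c in row_ids:
            out[labels == c] = next_id
            next_id += 1
        return out, next_id
    table = np.zeros((row_ids.size, ref_ids.size))
    for i, c in enumerate(row_ids):
        for j, r in enumerate(ref_ids):
            table[i, j] = np.sum((labels == c) & (reference == r))
    ri, cj = linear_sum_assignment(-table)
    assigned = {}
    for i, j in zip(ri, cj):
        if table[i, j] > 0:
            assigned[row_ids[i]] = int(ref_ids[j])
    for c in row_ids:
        if c in assigned:
            out[labels == c] = assigned[c]
        else:
            out[labels == c] = next_id
            next_id += 1
    return out, next_id


def align_clusterings(M: ClusterMatrix, reference_first: int | None = None) -> Alignment:
    """Greedy sequential alignment of clusterings onto shared cluster ids.

    The first row keeps its own labels; each later row is matched against
    the previously aligned row.  ``reference_first`` moves one row (e.g.
    the consensus) to the front of the matching order, which tends to
    produce cleaner shared blocks.  Samples are ordered lexicographically
    by their aligned label sequence, unassigned sorting last.
    """
    if M.n_clusterings < 1:
        raise ValueError("need at least one clustering")
    order = list(range(M.n_clusterings))
    if reference_first is not None:
        order.remove(reference_first)
        order.insert(0, reference_first)
    L = M.to_array()
    aligned = np.full_like(L, UNASSIGNED)
    first = L[order[0]]
    aligned[order[0]] = first
    next_id = int(first.max()) + 1 if (first != UNASSIGNED).any() else 1
    prev = aligned[order[0]]
    for r in order[1:]:
        aligned[r], next_id = _match_row(L[r], prev, next_id)
        prev = aligned[r]
    # lexicographic sample order; keys are per-row first-appearance ranks so
    # the ordering is invariant to how input rows were labeled; -1 sorts last
    keys = np.empty((len(order), aligned.shape[1]), dtype=int)
    for pos, r in enumerate(order):
        row = aligned[r]
        rank: dict[int, int] = {}
        for lab in row:
            if lab != UNASSIGNED and lab not in rank:
                rank[lab] = len(rank)
        keys[pos] = [rank[lab] if lab != UNASSIGNED else len(rank) + 1
                     for lab in row]
    sample_order = np.lexsort(keys[::-1])
    rows = [ClusterLabels(aligned[r], name=M.rows[r].name,
                          params=dict(M.rows[r].params))
            for r in range(M.n_clusterings)]
    return Alignment(relabeled=ClusterMatrix(rows=rows, sample_ids=M.sample_ids),
                     sample_order=sample_order)


def crosstab_proportions(A: ClusterLabels, B: ClusterLabels) -> pd.DataFrame:
    """B-clusters x A-clusters table of proportions; columns sum to 1.

    Entry (b, a) is the fraction of A-cluster ``a`` (among samples assigned
    in both clusterings) that falls in B-cluster ``b``.
    """
    if len(A) != len(B):
        raise ValueError("clusterings must cover the same samples")
    joint = (A.labels != UNASSIGNED) & (B.labels != UNASSIGNED)
    if not joint.any():
        raise ValueError("no samples are assigned in both clusterings")
    a, b = A.labels[joint], B.labels[joint]
    a_ids, b_ids = np.unique(a), np.unique(b)
    table = np.zeros((b_ids.size, a_ids.size))
    for i, bb in enumerate(b_ids):
        for j, aa in enumerate(a_ids):
            table[i, j] = np.sum((a == aa) & (b == bb))
    table /= table.sum(axis=0, keepdims=True)
    return pd.DataFrame(table,
                        index=pd.Index(b_ids, name=B.name or "B"),
                        columns=pd.Index(a_ids, name=A.name or "A"))


def newick_export(h: ClusterHierarchy) -> str:
    """Serialise the cluster hierarchy to Newick.

    Leaf names are cluster ids (``c3``); branch lengths are differences of
    merge heights, so the tree is ultrametric with leaves at height 0.
    """

    def rec(node: HNode, parent_height: float) -> str:
        length = max(parent_height - node.height, 0.0)
        if node.is_leaf:
            return f"{node.name}:{length:.10g}"
        inner = f"({rec(node.left, node.height)},{rec(node.right, node.height)})"
        return f"{inner}:{length:.10g}"

    root = h.root
    if root.is_leaf:
        return f"({root.name}:0);"
    body = f"({rec(root.left, root.height)},{rec(root.right, root.height)})"
    return body + ";"
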