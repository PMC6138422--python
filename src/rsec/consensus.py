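"""Consensus clustering across the ensemble of candidate clusterings.

The ensemble is summarised by the co-clustering dissimilarity
``D_ij = 1 - p_ij`` with ``p_ij`` the proportion of clusterings in which
samples i and j share a cluster, counting only clusterings where both are
assigned.  The consensus is obtained by clustering D with the 0-1
constrained method; samples assigned in too few clusterings are left
unassigned up front, mirroring the conservative treatment of samples that
the ensemble could not place consistently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .base_cluster import cluster_01
from .core import UNASSIGNED, ClusterLabels, ClusterMatrix, renumber_by_size
from .robust import CoDissimilarity, cooccurrence_from_labels

logger = logging.getLogger(__name__)


@dataclass
class ConsensusSpec:
    """Parameters of the consensus step.

    ``alpha`` bounds the mean within-cluster co-clustering dissimilarity;
    ``min_assigned_prop`` is the minimum fraction of clusterings in which a
    sample must be assigned to take part in the consensus at all.
    """

    alpha: float = 0.1
    min_size: int = 5
    min_assigned_prop: float = 0.5
    denominator: str = "pair"  # see cooccurrence_from_labels

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.min_assigned_prop <= 1:
            raise ValueError("min_assigned_prop must be in [0, 1]")


def coclustering_matrix(M: ClusterMatrix, denominator: str = "pair") -> CoDissimilarity:
    """Ensemble co-clustering dissimilarity over the rows of M."""
    if M.n_clusterings < 1:
        raise ValueError("need at least one clustering")
    return cooccurrence_from_labels(M.to_array(), denominator=denominator)


def make_consensus(M: ClusterMatrix, spec: ConsensusSpec) -> ClusterLabels:
    """Single consensus clustering from the stack of clusterings."""
    L = M.to_array()
    m, n = L.shape
    assigned_frac = (L != UNASSIGNED).mean(axis=0)
    # a sample with no assignment anywhere carries no evidence at all and
    # stays unassigned even when min_assigned_prop is 0
    eligible = (assigned_frac >= spec.min_assigned_prop) & (assigned_frac > 0)
    if not eligible.any():
        raise ValueError(
            "no sample is assigned in enough clusterings to build a consensus "
            f"(min_assigned_prop={spec.min_assigned_prop})")
    n_forced = int((~eligible).sum())
    if n_forced:
        logger.info("consensus: %d/%d samples assigned in < %.0f%% of "
                    "clusterings, left unassigned", n_forced, n,
                    100 * spec.min_assigned_prop)
    co = cooccurrence_from_labels(L[:, eligible], denominator=spec.denominator)
    sub_labels = cluster_01(co.D, spec.alpha, spec.min_size)
    out = np.full(n, UNASSIGNED, dtype=int)
    out[eligible] = sub_labels.labels
    return ClusterLabels(renumber_by_size(out), name="consensus",
                         params={"alpha": spec.alpha, "min_size": spec.min_size,
                                 "min_assigned_prop": spec.min_assigned_prop})
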