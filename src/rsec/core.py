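"""Shared container types for the ensemble-clustering workflow.

The workflow operates on a genes x samples expression matrix and produces,
stage by stage, a stack of candidate clusterings, a consensus clustering,
and a merged clustering guided by a hierarchy of clusters.  All of these are
kept together in :class:`RSECResult` so that intermediate results remain
inspectable after the final clustering is produced.

Unassigned samples carry the sentinel label ``-1`` everywhere; positive
labels ``1..K`` denote clusters and are renumbered by decreasing cluster
size after every stage so that outputs are deterministic and comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

UNASSIGNED = -1


def renumber_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel positive cluster ids as 1..K by decreasing size.

    Ties are broken by the smallest original label, making the mapping
    deterministic.  ``-1`` entries are preserved.
    """
    labels = np.asarray(labels)
    out = np.full(labels.shape, UNASSIGNED, dtype=int)
    ids, counts = np.unique(labels[labels != UNASSIGNED], return_counts=True)
    order = sorted(range(len(ids)), key=lambda i: (-counts[i], ids[i]))
    for new, old_idx in enumerate(order, start=1):
        out[labels == ids[old_idx]] = new
    return out


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log-scale expression values."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        g, n = self.values.shape
        self.gene_ids = [str(x) for x in self.gene_ids]
        self.sample_ids = [str(x) for x in self.sample_ids]
        if len(self.gene_ids) != g:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {g} rows")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} columns")
        if len(set(self.sample_ids)) != n:
            dups = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValueError(f"duplicate sample ids: {dups}")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains NaN or Inf")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, idx: Sequence[int]) -> "ExpressionMatrix":
        idx = np.asarray(idx, dtype=int)
        return ExpressionMatrix(
            self.values[:, idx],
            self.gene_ids,
            [self.sample_ids[i] for i in idx],
        )

    def subset_genes(self, idx: Sequence[int]) -> "ExpressionMatrix":
        idx = np.asarray(idx, dtype=int)
        return ExpressionMatrix(
            self.values[idx, :],
            [self.gene_ids[i] for i in idx],
            self.sample_ids,
        )


@dataclass
class ClusterLabels:
    """One clustering: per-sample integer assignments with provenance.

    ``labels`` contains ``-1`` for unassigned samples and ``1..K``
    otherwise; every positive label must have at least one member.
    """

    labels: np.ndarray
    name: str = "clustering"
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        bad = self.labels[(self.labels != UNASSIGNED) & (self.labels < 1)]
        if bad.size:
            raise ValueError(f"invalid labels {sorted(set(bad.tolist()))}: "
                             "only -1 and positive integers allowed")

    def __len__(self) -> int:
        return self.labels.size

    @property
    def n_clusters(self) -> int:
        return int(np.unique(self.labels[self.labels != UNASSIGNED]).size)

    def cluster_ids(self) -> np.ndarray:
        return np.unique(self.labels[self.labels != UNASSIGNED])

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)

    def renumbered(self) -> "ClusterLabels":
        return ClusterLabels(renumber_by_size(self.labels), self.name, dict(self.params))


def assigned_mask(labels: ClusterLabels | np.ndarray) -> np.ndarray:
    """Boolean vector, True exactly where a sample is assigned."""
    arr = labels.labels if isinstance(labels, ClusterLabels) else np.asarray(labels)
    return arr != UNASSIGNED


@dataclass
class ClusterMatrix:
    """A stack of clusterings of the same samples (m clusterings x n samples)."""

    rows: list[ClusterLabels] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        names = [r.name for r in self.rows]
        if len(set(names)) != len(names):
            dups = sorted({x for x in names if names.count(x) > 1})
            raise ValueError(f"duplicate clustering names: {dups}")
        for r in self.rows:
            if len(r) != n:
                raise ValueError(
                    f"clustering {r.name!r} has {len(r)} labels for {n} samples")

    @property
    def n_clusterings(self) -> int:
        return len(self.rows)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def __iter__(self) -> Iterator[ClusterLabels]:
        return iter(self.rows)

    def names(self) -> list[str]:
        return [r.name for r in self.rows]

    def to_array(self) -> np.ndarray:
        """m x n integer array of labels."""
        return np.vstack([r.labels for r in self.rows]) if self.rows else \
            np.empty((0, self.n_samples), dtype=int)

    def to_frame(self) -> pd.DataFrame:
        """Samples x clusterings table, indexed by sample id."""
        return pd.DataFrame(
            {r.name: r.labels for r in self.rows},
            index=pd.Index(self.sample_ids, name="sample_id"),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ClusterMatrix":
        rows = [ClusterLabels(df[c].to_numpy(dtype=int), name=str(c)) for c in df.columns]
        return cls(rows=rows, sample_ids=[str(i) for i in df.index])


def add_clustering(result: "RSECResult", labels: ClusterLabels) -> "RSECResult":
    """Return a new result whose cluster matrix gains one row."""
    cm = result.cluster_matrix
    if len(labels) != cm.n_samples:
        raise ValueError(
            f"labels length {len(labels)} does not match {cm.n_samples} samples")
    if labels.name in cm.names():
        raise ValueError(f"clustering name {labels.name!r} already present")
    new_cm = ClusterMatrix(rows=list(cm.rows) + [labels], sample_ids=cm.sample_ids)
    return RSECResult(
        cluster_matrix=new_cm,
        consensus=result.consensus,
        merged=result.merged,
        hierarchy=result.hierarchy,
        node_estimates=dict(result.node_estimates),
        provenance=dict(result.provenance),
    )


@dataclass
class RSECResult:
    """Everything the workflow produced, from candidate clusterings to the
    merged clustering, plus the hierarchy and per-node estimates."""

    cluster_matrix: ClusterMatrix
    consensus: Optional[ClusterLabels] = None
    merged: Optional[ClusterLabels] = None
    hierarchy: Optional[Any] = None  # merge.ClusterHierarchy
    node_estimates: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    def check_coarsening(self) -> None:
        """Assert that merged is a coarsening of consensus.

        Every consensus cluster must map into exactly one merged cluster and
        samples unassigned in consensus must stay unassigned.
        """
        if self.consensus is None or self.merged is None:
            return
        cons, merg = self.consensus.labels, self.merged.labels
        if np.any((cons == UNASSIGNED) & (merg != UNASSIGNED)):
            raise AssertionError("sample unassigned in consensus but assigned in merged")
        for c in np.unique(cons[cons != UNASSIGNED]):
            targets = np.unique(merg[cons == c])
            if targets.size != 1:
                raise AssertionError(
                    f"consensus cluster {c} split across merged clusters {targets}")
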