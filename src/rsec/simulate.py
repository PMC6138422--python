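"""Synthetic expression data with known cluster structure.

The generator emulates the situation the workflow is designed for:
log-scale expression of G genes in n samples drawn from K Gaussian
clusters.  Each cluster has a planted fraction of marker genes shifted by
+/- ``effect`` log-units from a shared baseline; within-cluster noise is
i.i.d. Gaussian with standard deviation ``sigma``.  Two optional wrinkles
mirror common real-data features: nested splits (a cluster subdivided by a
weaker secondary signal, for testing the merge step) and noise samples
placed on the segment between two cluster centres (boundary cells, which a
robust workflow should leave unassigned; their true label is -1).

Everything is driven by a single seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import UNASSIGNED, ClusterLabels, ClusterMatrix, ExpressionMatrix


@dataclass
class SimSpec:
    """Study-design parameters of a simulated dataset.

    ``prop_de`` is the fraction of genes shifted per cluster, ``effect``
    the mean shift in log-units, ``sigma`` the within-cluster standard
    deviation (so ``effect = 5 * sigma`` gives crisply separated
    clusters).  ``nested`` lists (cluster, split_fraction, sub_effect)
    triples; ``noise_frac`` is the fraction of samples turned into
    between-cluster boundary samples.
    """

    n: int = 200
    G: int = 100
    K: int = 4
    cluster_props: Optional[Sequence[float]] = None
    prop_de: float = 0.2
    effect: float = 5.0
    sigma: float = 1.0
    baseline_mean: float = 6.0
    nested: list[tuple[int, float, float]] = field(default_factory=list)
    noise_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K > self.n:
            raise ValueError(f"K={self.K} exceeds n={self.n}")
        if self.cluster_props is None:
            self.cluster_props = [1.0 / self.K] * self.K
        props = np.asarray(self.cluster_props, dtype=float)
        if props.size != self.K or not np.isclose(props.sum(), 1.0):
            raise ValueError("cluster_props must have length K and sum to 1")
        if not 0 <= self.prop_de <= 1 or not 0 <= self.noise_frac <= 1:
            raise ValueError("prop_de and noise_frac must lie in [0, 1]")
        if self.effect < 0 or self.sigma < 0:
            raise ValueError("effect and sigma must be >= 0")


@dataclass
class SimResult:
    """Simulated matrix, ground-truth labels and marker bookkeeping."""

    X: ExpressionMatrix
    truth: ClusterLabels
    markers: dict[int, np.ndarray]  # cluster -> indices of its DE genes
    centers: np.ndarray  # K x G cluster mean profiles (before nesting)
    nested_members: dict[int, np.ndarray] = field(default_factory=dict)
    nested_genes: dict[int, np.ndarray] = field(default_factory=dict)


def simulate_clusters(spec: SimSpec) -> SimResult:
    """Draw a Gaussian log-expression mixture with planted markers."""
    rng = np.random.default_rng(spec.seed)
    baseline = rng.normal(spec.baseline_mean, 1.0, size=spec.G)
    centers = np.tile(baseline, (spec.K, 1))
    markers: dict[int, np.ndarray] = {}
    n_de = int(round(spec.prop_de * spec.G))
    for k in range(spec.K):
        de_genes = rng.choice(spec.G, size=n_de, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        centers[k, de_genes] += signs * spec.effect
        markers[k + 1] = np.sort(de_genes)

    # cluster sizes: largest-remainder allocation of n across props
    props = np.asarray(spec.cluster_props, dtype=float)
    sizes = np.floor(props * spec.n).astype(int)
    for i in np.argsort(-(props * spec.n - sizes))[: spec.n - sizes.sum()]:
        sizes[i] += 1
    labels = np.repeat(np.arange(1, spec.K + 1), sizes)

    n_noise = int(round(spec.noise_frac * spec.n))
    if n_noise > 0 and spec.K >= 2:
        noise_idx = rng.choice(spec.n, size=n_noise, replace=False)
        labels = labels.copy()
        labels[noise_idx] = UNASSIGNED

    values = np.empty((spec.G, spec.n))
    for i in range(spec.n):
        if labels[i] == UNASSIGNED:
            a, b = rng.choice(spec.K, size=2, replace=False)
            w = rng.uniform(0.25, 0.75)  # strictly between the two centres
            mean = w * centers[a] + (1 - w) * centers[b]
        else:
            mean = centers[labels[i] - 1]
        values[:, i] = rng.normal(mean, spec.sigma)

    # nested splits: secondary shift applied to a random half (or given
    # fraction) of one cluster's samples on fresh genes
    nested_members: dict[int, np.ndarray] = {}
    nested_genes: dict[int, np.ndarray] = {}
    for cluster, frac, sub_effect in spec.nested:
        members = np.flatnonzero(labels == cluster)
        n_sub = int(round(frac * members.size))
        sub = rng.choice(members, size=n_sub, replace=False)
        sub_genes = rng.choice(spec.G, size=max(n_de, 1), replace=False)
        shift = rng.choice([-1.0, 1.0], size=sub_genes.size) * sub_effect
        values[np.ix_(sub_genes, sub)] += shift[:, None]
        nested_members[cluster] = np.sort(sub)
        nested_genes[cluster] = np.sort(sub_genes)

    X = ExpressionMatrix(values,
                         gene_ids=[f"g{j+1}" for j in range(spec.G)],
                         sample_ids=[f"s{i+1}" for i in range(spec.n)])
    truth = ClusterLabels(labels, name="truth",
                          params={"seed": spec.seed, "K": spec.K})
    return SimResult(X=X, truth=truth, markers=markers, centers=centers,
                     nested_members=nested_members, nested_genes=nested_genes)


def simulate_label_matrix(truth: ClusterLabels, m: int,
                          flip_rate: float = 0.0, unassign_rate: float = 0.0,
                          seed: int = 0) -> ClusterMatrix:
    """m noisy copies of a true clustering, for consensus/alignment tests.

    Each sample is independently reassigned to a random *other* cluster
    with probability ``flip_rate`` and unassigned with probability
    ``unassign_rate`` (unassignment wins when both fire).
    """
    if not 0 <= flip_rate <= 1 or not 0 <= unassign_rate <= 1:
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = truth.cluster_ids()
    rows = []
    for r in range(m):
        labels = truth.labels.copy()
        for i in range(labels.size):
            if labels[i] == UNASSIGNED:
                continue
            if rng.uniform() < flip_rate and ids.size > 1:
                others = ids[ids != labels[i]]
                labels[i] = rng.choice(others)
            if rng.uniform() < unassign_rate:
                labels[i] = UNASSIGNED
        rows.append(ClusterLabels(labels, name=f"noisy{r+1}",
                                  params={"flip_rate": flip_rate,
                                          "unassign_rate": unassign_rate}))
    n = len(truth)
    return ClusterMatrix(rows=rows, sample_ids=[f"s{i+1}" for i in range(n)])


def tight_plus_scatter(n_tight: int = 20, n_scatter: int = 20, d: int = 10,
                       tight_sd: float = 0.2, scatter_halfwidth: float = 8.0,
                       seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """One tight point-mass plus uniform scatter, as features x samples.

    Returns (data, truth) where truth is 1 for the tight cluster and -1
    for scatter.  This is the canonical stress test for sequential
    detection: the tight mass should be found first and most of the
    scatter should stay unassigned.
    """
    rng = np.random.default_rng(seed)
    tight = rng.normal(0.0, tight_sd, size=(d, n_tight))
    tight += np.full((d, 1), 3.0 * scatter_halfwidth)  # well away from scatter
    scatter = rng.uniform(-scatter_halfwidth, scatter_halfwidth,
                          size=(d, n_scatter))
    data = np.concatenate([tight, scatter], axis=1)
    truth = np.concatenate([np.ones(n_tight, dtype=int),
                            np.full(n_scatter, UNASSIGNED, dtype=int)])
    return data, truth
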