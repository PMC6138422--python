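"""Reference study configurations used for validation.

These frozen, desk-scale configurations exercise the full workflow on
synthetic data with known truth: parameter grids matching the two
published-style analyses (a wide exploratory grid and a minimal one), a
cluster-recovery study, a nested-split merge study, and the
tight-cluster-plus-scatter stress test for sequential detection.  Both the
test suite and the reproduction script run them, so every reported number
is recomputed from scratch.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .consensus import ConsensusSpec
from .core import ClusterLabels
from .grid import ParameterGrid, rsec
from .merge import MergeSpec, cluster_medians, make_dendrogram, merge_clusters
from .robust import SequentialSpec, SubsampleSpec, sequential_detect
from .simulate import SimSpec, simulate_clusters, tight_plus_scatter


def wide_exploratory_grid() -> ParameterGrid:
    """The wide demonstration grid: 3 x 2 x 2 x 12 x 3 = 432 combinations."""
    return ParameterGrid(axes={
        "dims": [20, 50, 100],
        "alpha": [0.1, 0.2],
        "beta": [0.8, 0.9],
        "k0": list(range(4, 16)),
        "minSize": [1, 5, 10],
    })


def minimal_grid() -> ParameterGrid:
    """The minimal large-dataset grid: 1 x 2 x 1 x 7 x 1 = 14 combinations."""
    return ParameterGrid(axes={
        "dims": [50],
        "alpha": [0.1, 0.3],
        "beta": [0.9],
        "k0": [5, 10, 15, 20, 25, 30, 35],
        "minSize": [5],
    })


# ---------------------------------------------------------------------------
# cluster recovery: 4 clusters of unequal abundance, strong markers

RECOVERY_SIM = dict(n=200, G=100, K=4, effect=5.0, sigma=1.0,
                    cluster_props=(0.35, 0.30, 0.20, 0.15))


def recovery_grid() -> ParameterGrid:
    """Eight-combination grid for the recovery study (desk-scale sizes)."""
    return ParameterGrid(
        axes={"dims": [10, 20], "alpha": [0.2, 0.3], "k0": [3, 4],
              "beta": [0.8], "minSize": [5]},
        options={"B": 20, "restarts": 2, "k_max": 8})


def pipeline_recovery(seed: int) -> dict:
    """Full workflow on simulated 4-cluster data; ARI over assigned samples."""
    sim = simulate_clusters(SimSpec(seed=seed, **RECOVERY_SIM))
    result = rsec(sim.X, recovery_grid(),
                  consensus_spec=ConsensusSpec(alpha=0.1, min_size=5),
                  merge_spec=MergeSpec(cutoff=0.05, method="adjP"),
                  seed=seed)
    merged = result.merged.labels
    mask = merged != -1
    ari = adjusted_rand_score(sim.truth.labels[mask], merged[mask]) \
        if mask.sum() > 1 else 0.0
    return {"ari": float(ari), "assigned_frac": float(mask.mean()),
            "merged_k": result.merged.n_clusters, "result": result}


# ---------------------------------------------------------------------------
# nested-split merge study

NESTED_SIM = dict(n=120, G=200, K=2, effect=5.0, sigma=1.0)


def _oversplit_labels(truth: np.ndarray, halves: dict[int, np.ndarray]) -> ClusterLabels:
    split = np.zeros(truth.size, dtype=int)
    for c in (1, 2):
        split[truth == c] = 2 * c - 1
        split[halves[c]] = 2 * c
    return ClusterLabels(split, name="oversplit")


def merge_nested(seed: int) -> dict:
    """Merged K on oversplit data, without and with planted sister DE.

    Null arm: 2 true clusters, each split arbitrarily in half (no genes
    separate the sisters); correct merging returns K=2.  Signal arm: 30% of
    genes shifted by 3 SD between sisters; no node should merge (K=4).
    """
    sim = simulate_clusters(SimSpec(seed=seed, **NESTED_SIM))
    rng = np.random.default_rng(seed + 10_000)
    halves = {}
    for c in (1, 2):
        mem = np.flatnonzero(sim.truth.labels == c)
        halves[c] = rng.choice(mem, size=mem.size // 2, replace=False)
    labels = _oversplit_labels(sim.truth.labels, halves)
    med = cluster_medians(sim.X, labels)
    h = make_dendrogram(med, [1, 2, 3, 4])
    merged_null, _ = merge_clusters(sim.X, labels, h,
                                    MergeSpec(cutoff=0.05, method="adjP"))

    simb = simulate_clusters(SimSpec(seed=seed, prop_de=0.3,
                                     nested=[(1, 0.5, 3.0), (2, 0.5, 3.0)],
                                     **NESTED_SIM))
    labb = _oversplit_labels(simb.truth.labels, simb.nested_members)
    medb = cluster_medians(simb.X, labb)
    hb = make_dendrogram(medb, [1, 2, 3, 4])
    merged_alt, _ = merge_clusters(simb.X, labb, hb,
                                   MergeSpec(cutoff=0.05, method="adjP"))
    return {"null_k": merged_null.n_clusters, "alt_k": merged_alt.n_clusters}


# ---------------------------------------------------------------------------
# sequential stress test: tight point-mass plus featureless scatter

def sequential_scatter(seed: int) -> dict:
    """Sequential detection on 20 tight + 20 scatter samples at beta=0.8."""
    data, truth = tight_plus_scatter(n_tight=20, n_scatter=20, seed=seed)
    sub = SubsampleSpec(B=20, method="kmeans", restarts=2, seed=seed)
    seq = SequentialSpec(k0=2, beta=0.8, k_max=6, alpha=0.2, min_size=5)
    labs = sequential_detect(data, sub, seq)
    tight_in_first = set(range(20)) <= set(np.flatnonzero(labs.labels == 1))
    scatter_unassigned = float((labs.labels[20:] == -1).mean())
    return {"tight_found_first": bool(tight_in_first),
            "scatter_unassigned_frac": scatter_unassigned}
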