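import numpy as np
import pytest
from scipy import stats

import rsec
from rsec.merge import HNode, MergeSpec


def _hier_from_labels(X, labels):
    med = rsec.cluster_medians(X, labels)
    return rsec.make_dendrogram(med, [int(c) for c in labels.cluster_ids()])


class TestClusterMedians:
    def test_singleton_cluster_is_own_profile(self, expr_matrix):
        labels = rsec.ClusterLabels(np.array([1, 2, 2, 2, 2, 2]))
        med = rsec.cluster_medians(expr_matrix, labels)
        np.testing.assert_allclose(med[0], expr_matrix.values[:, 0])

    def test_median_robust_to_outlier(self):
        X = rsec.ExpressionMatrix(np.array([[1.0, 2.0, 100.0, 0.0, 0.0, 0.0]]),
                                  ["g"], list("abcdef"))
        labels = rsec.ClusterLabels(np.array([1, 1, 1, 2, 2, 2]))
        med = rsec.cluster_medians(X, labels)
        assert med[0, 0] == 2.0

    def test_unassigned_excluded(self):
        X = rsec.ExpressionMatrix(np.array([[1.0, 1.0, 9.0, 5.0, 5.0]]),
                                  ["g"], list("abcde"))
        labels = rsec.ClusterLabels(np.array([1, 1, -1, 2, 2]))
        med = rsec.cluster_medians(X, labels)
        assert med[0, 0] == 1.0 and med[1, 0] == 5.0


class TestMakeDendrogram:
    def test_hand_topology_close_pair_first(self):
        # d(A,B)=1, d(A,C)=d(B,C)~10 -> ((A,B),C)
        med = np.array([[0.0], [1.0], [10.0]])
        h = rsec.make_dendrogram(med, [1, 2, 3])
        root = h.root
        assert set(root.clusters) == {1, 2, 3}
        kids = sorted([root.left.clusters, root.right.clusters], key=len)
        assert kids == [(3,), (1, 2)]

    def test_two_leaves_single_root(self):
        h = rsec.make_dendrogram(np.array([[0.0], [5.0]]), [1, 2])
        assert h.root.left.is_leaf and h.root.right.is_leaf
        assert h.root.height == pytest.approx(5.0)

    def test_duplicate_medians_merge_at_zero(self):
        med = np.array([[0.0], [0.0], [8.0]])
        h = rsec.make_dendrogram(med, [1, 2, 3])
        inner = [n for n in h.internal_nodes() if len(n.clusters) == 2][0]
        assert inner.height == pytest.approx(0.0)
        assert set(inner.clusters) == {1, 2}


class TestNodeDE:
    def test_null_pvalues_roughly_uniform(self):
        rejections = 0
        for s in range(10):
            rng = np.random.default_rng(s)
            X = rsec.ExpressionMatrix(rng.normal(0, 1, size=(500, 40)),
                                      [f"g{i}" for i in range(500)],
                                      [f"s{i}" for i in range(40)])
            labels = rsec.ClusterLabels(np.repeat([1, 2], 20))
            h = _hier_from_labels(X, labels)
            p, _ = rsec.node_de_pvalues(X, labels, h.root)
            if stats.kstest(p, "uniform").pvalue < 0.01:
                rejections += 1
        assert rejections <= 2  # uniformity not systematically rejected

    def test_shifted_genes_dominate_small_pvalues(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, size=(200, 40))
        X[:20, 20:] += 5.0  # 10% of genes shifted by 5 SD in group 2
        Xm = rsec.ExpressionMatrix(X, [f"g{i}" for i in range(200)],
                                   [f"s{i}" for i in range(40)])
        labels = rsec.ClusterLabels(np.repeat([1, 2], 20))
        h = _hier_from_labels(Xm, labels)
        p, lfc = rsec.node_de_pvalues(Xm, labels, h.root)
        assert set(np.argsort(p)[:20]) == set(range(20))
        assert np.all(np.abs(lfc[:20]) > 3)

    def test_constant_gene_conventions(self):
        X = np.vstack([np.ones(20), np.random.default_rng(2).normal(size=20)])
        Xm = rsec.ExpressionMatrix(X, ["flat", "noisy"],
                                   [f"s{i}" for i in range(20)])
        labels = rsec.ClusterLabels(np.repeat([1, 2], 10))
        h = _hier_from_labels(Xm, labels)
        p, lfc = rsec.node_de_pvalues(Xm, labels, h.root)
        assert p[0] == 1.0 and lfc[0] == 0.0


class TestEstimateProp:
    @pytest.mark.parametrize("method", ["adjP", "pi0-storey", "locfdr-lite"])
    def test_all_ones_give_zero(self, method):
        spec = MergeSpec(cutoff=0.05, method=method)
        assert rsec.estimate_prop_de(np.ones(500), None, spec) == 0.0

    def test_adjp_exact_tenth(self):
        p = np.concatenate([np.full(100, 1e-6), np.linspace(0.5, 1, 900)])
        spec = MergeSpec(cutoff=0.05, method="adjP", fdr_level=0.05)
        assert rsec.estimate_prop_de(p, None, spec) == pytest.approx(0.10)

    def test_storey_near_zero_under_null(self):
        ests = []
        for s in range(20):
            p = np.random.default_rng(s).uniform(size=2000)
            ests.append(rsec.estimate_prop_de(
                p, None, MergeSpec(method="pi0-storey")))
        assert np.mean(ests) <= 0.05

    def test_adjp_non_increasing_in_lfc_floor(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 0.01, size=100)
        lfc = rng.normal(0, 2, size=100)
        prev = 1.1
        for floor in (0.0, 0.5, 1.0, 2.0, 4.0):
            est = rsec.estimate_prop_de(
                p, lfc, MergeSpec(method="adjP", lfc_min=floor))
            assert est <= prev
            prev = est

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            rsec.estimate_prop_de(np.array([]), None, MergeSpec())


class TestMergeClusters:
    def _constructed(self, estimates):
        """Four clusters, hand-built tree ((1,2),(3,4)); estimates keyed by
        node name: node1=root, node2=(1,2), node3=(3,4)."""
        rng = np.random.default_rng(0)
        X = rsec.ExpressionMatrix(rng.normal(size=(10, 40)),
                                  [f"g{i}" for i in range(10)],
                                  [f"s{i}" for i in range(40)])
        labels = rsec.ClusterLabels(np.repeat([1, 2, 3, 4], 10))
        n2 = HNode("node2", (1, 2), 1.0, HNode("c1", (1,)), HNode("c2", (2,)))
        n3 = HNode("node3", (3, 4), 1.0, HNode("c3", (3,)), HNode("c4", (4,)))
        root = HNode("node1", (1, 2, 3, 4), 5.0, n2, n3)
        h = rsec.ClusterHierarchy(root=root, cluster_ids=[1, 2, 3, 4])
        for node in h.internal_nodes():
            node.estimate = estimates[node.name]
        return X, labels, h

    def test_no_merge_when_all_estimates_high(self):
        X, labels, h = self._constructed(
            {"node1": 0.9, "node2": 0.8, "node3": 0.7})
        merged, _ = rsec.merge_clusters(X, labels, h, MergeSpec(cutoff=0.05))
        assert merged.n_clusters == 4

    def test_single_leaf_pair_collapses(self):
        X, labels, h = self._constructed(
            {"node1": 0.5, "node2": 0.01, "node3": 0.6})
        merged, hh = rsec.merge_clusters(X, labels, h, MergeSpec(cutoff=0.05))
        assert merged.n_clusters == 3
        assert [n.merged for n in hh.internal_nodes()] == [True, False, False]

    def test_parent_blocked_by_unmerged_child(self):
        # root estimate below cutoff but node3 above: root must not merge
        X, labels, h = self._constructed(
            {"node1": 0.01, "node2": 0.01, "node3": 0.6})
        merged, _ = rsec.merge_clusters(X, labels, h, MergeSpec(cutoff=0.05))
        assert merged.n_clusters == 3

    def test_full_collapse(self):
        X, labels, h = self._constructed(
            {"node1": 0.0, "node2": 0.0, "node3": 0.0})
        merged, _ = rsec.merge_clusters(X, labels, h, MergeSpec(cutoff=0.05))
        assert merged.n_clusters == 1

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(9)
        sim = rsec.simulate_clusters(rsec.SimSpec(n=80, G=100, K=4,
                                                  effect=2.0, seed=9))
        X, labels = sim.X, sim.truth
        prev_k = 100
        for cutoff in (0.01, 0.05, 0.2, 0.5, 0.9):
            h = _hier_from_labels(X, labels)
            merged, _ = rsec.merge_clusters(X, labels, h,
                                            MergeSpec(cutoff=cutoff))
            assert merged.n_clusters <= prev_k
            prev_k = merged.n_clusters

    def test_merged_is_coarsening(self):
        sim = rsec.simulate_clusters(rsec.SimSpec(n=60, G=80, K=3,
                                                  effect=1.0, seed=3))
        h = _hier_from_labels(sim.X, sim.truth)
        merged, _ = rsec.merge_clusters(sim.X, sim.truth, h,
                                        MergeSpec(cutoff=0.5))
        for c in sim.truth.cluster_ids():
            assert np.unique(merged.labels[sim.truth.labels == c]).size == 1


def test_oversplit_clusters_remerge_and_signal_blocks_merge():
    """Nested-split data: sisters with no DE collapse; planted sister DE
    (30% of genes at 3 SD) prevents merging."""
    merged_null = []
    merged_alt = []
    for s in range(3):
        sim = rsec.simulate_clusters(rsec.SimSpec(n=120, G=200, K=2,
                                                  effect=5.0, seed=s))
        rng = np.random.default_rng(100 + s)
        split = np.zeros(120, dtype=int)
        for c in (1, 2):
            mem = np.flatnonzero(sim.truth.labels == c)
            half = rng.choice(mem, size=mem.size // 2, replace=False)
            split[mem] = 2 * c - 1
            split[half] = 2 * c
        labels = rsec.ClusterLabels(split, name="oversplit")
        h = _hier_from_labels(sim.X, labels)
        merged, _ = rsec.merge_clusters(sim.X, labels, h, MergeSpec(cutoff=0.05))
        merged_null.append(merged.n_clusters)

        simb = rsec.simulate_clusters(rsec.SimSpec(
            n=120, G=200, K=2, effect=5.0, prop_de=0.3,
            nested=[(1, 0.5, 3.0), (2, 0.5, 3.0)], seed=s))
        splitb = np.zeros(120, dtype=int)
        for c in (1, 2):
            splitb[simb.truth.labels == c] = 2 * c - 1
            splitb[simb.nested_members[c]] = 2 * c
        labb = rsec.ClusterLabels(splitb, name="oversplit")
        hb = _hier_from_labels(simb.X, labb)
        mb, _ = rsec.merge_clusters(simb.X, labb, hb, MergeSpec(cutoff=0.05))
        merged_alt.append(mb.n_clusters)
    assert merged_null == [2, 2, 2]
    assert merged_alt == [4, 4, 4]
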