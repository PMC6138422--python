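import numpy as np
import pytest
from scipy import stats

import rsec
from rsec.markers import squeeze_variances
from rsec.merge import HNode


def _balanced_hierarchy(K):
    """A caterpillar binary tree over clusters 1..K."""
    node = HNode("c1", (1,))
    for c in range(2, K + 1):
        node = HNode(f"n{c}", tuple(range(1, c + 1)), float(c),
                     node, HNode(f"c{c}", (c,)))
    return rsec.ClusterHierarchy(root=node, cluster_ids=list(range(1, K + 1)))


class TestBuildContrasts:
    def test_pairwise_count_k13(self):
        cs = rsec.build_contrasts(13, "pairwise")
        assert len(cs) == 78

    def test_one_vs_all_weights_sum_zero(self):
        cs = rsec.build_contrasts(5, "one-vs-all")
        assert len(cs) == 5
        for _, w in cs.contrasts:
            assert w.sum() == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("K", [2, 4, 7])
    def test_hierarchical_count_is_k_minus_one(self, K):
        cs = rsec.build_contrasts(K, "hierarchical", _balanced_hierarchy(K))
        assert len(cs) == K - 1

    def test_all_families_weights_sum_zero(self):
        for family in ("pairwise", "one-vs-all"):
            cs = rsec.build_contrasts(6, family)
            for _, w in cs.contrasts:
                assert abs(w.sum()) < 1e-12

    def test_hierarchy_leaf_mismatch_rejected(self):
        with pytest.raises(ValueError, match="leaves"):
            rsec.build_contrasts(5, "hierarchical", _balanced_hierarchy(4))


def _two_group_data(n_per=20, G=50, delta=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, size=(G, 2 * n_per))
    X[0, n_per:] += delta
    Xm = rsec.ExpressionMatrix(X, [f"g{i}" for i in range(G)],
                               [f"s{i}" for i in range(2 * n_per)])
    labels = rsec.ClusterLabels(np.repeat([1, 2], n_per))
    return Xm, labels


class TestFitDE:
    def test_equal_means_give_null_result(self):
        X = rsec.ExpressionMatrix(np.tile([[1.0], [2.0]], (1, 12)),
                                  ["g1", "g2"], [f"s{i}" for i in range(12)])
        labels = rsec.ClusterLabels(np.repeat([1, 2, 3], 4))
        res = rsec.fit_de(X, labels, rsec.build_contrasts(3, "pairwise"))
        assert (res["logFC"] == 0).all()
        assert (res["p"] == 1).all()

    def test_planted_shift_detected(self):
        X, labels = _two_group_data(n_per=40, delta=3.0, seed=1)
        res = rsec.fit_de(X, labels, rsec.build_contrasts(2, "pairwise"))
        g0 = res[res["gene"] == "g0"].iloc[0]
        assert g0["p"] < 1e-6
        assert g0["logFC"] == pytest.approx(-3.0, abs=0.5)

    def test_single_gene_reduces_to_pooled_t(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 15), rng.normal(1, 1, 15)
        X = rsec.ExpressionMatrix(np.concatenate([a, b])[None, :], ["g"],
                                  [f"s{i}" for i in range(30)])
        labels = rsec.ClusterLabels(np.repeat([1, 2], 15))
        res = rsec.fit_de(X, labels, rsec.build_contrasts(2, "pairwise"))
        t_ref, p_ref = stats.ttest_ind(a, b)
        assert res["stat"].iloc[0] == pytest.approx(t_ref, rel=1e-9)
        assert res["p"].iloc[0] == pytest.approx(p_ref, rel=1e-9)

    def test_k2_families_identical_pvalues(self):
        X, labels = _two_group_data(n_per=15, delta=1.0, seed=2)
        h = _balanced_hierarchy(2)
        ps = {}
        for family in ("pairwise", "one-vs-all", "hierarchical"):
            hier = h if family == "hierarchical" else None
            res = rsec.fit_de(X, labels, rsec.build_contrasts(2, family, hier))
            first = res["contrast"].iloc[0]
            ps[family] = res[res["contrast"] == first]["p"].to_numpy()
        np.testing.assert_allclose(ps["pairwise"], ps["one-vs-all"], rtol=1e-9)
        np.testing.assert_allclose(ps["pairwise"], ps["hierarchical"], rtol=1e-9)

    def test_shrinkage_pulls_variances_toward_prior(self):
        rng = np.random.default_rng(7)
        s2 = rng.chisquare(10, size=500) / 10
        mod, d0, s02 = squeeze_variances(s2, 10)
        assert d0 > 0
        # moderated values are strictly between observed and prior (where distinct)
        inner = np.abs(mod - s02) <= np.abs(s2 - s02) + 1e-12
        assert inner.all()


class TestBHAdjustment:
    def test_step_up_matches_bruteforce(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            p = rng.uniform(size=40)
            X, labels = _two_group_data(n_per=5, G=1, seed=1)
            from statsmodels.stats.multitest import multipletests
            adj = multipletests(p, method="fdr_bh")[1]
            # brute-force BH step-up
            order = np.argsort(p)
            m = p.size
            raw = p[order] * m / (np.arange(m) + 1)
            stepup = np.minimum.accumulate(raw[::-1])[::-1]
            brute = np.empty(m)
            brute[order] = np.minimum(stepup, 1)
            np.testing.assert_allclose(adj, brute, rtol=1e-12)

    def test_p_adj_at_least_p(self):
        X, labels = _two_group_data(n_per=10, delta=0.5, seed=3)
        res = rsec.fit_de(X, labels, rsec.build_contrasts(2, "pairwise"))
        assert (res["p_adj"] >= res["p"] - 1e-15).all()


class TestGlobalF:
    def test_null_f_mean_near_expectation(self):
        rng = np.random.default_rng(5)
        X = rsec.ExpressionMatrix(rng.normal(size=(2000, 60)),
                                  [f"g{i}" for i in range(2000)],
                                  [f"s{i}" for i in range(60)])
        labels = rsec.ClusterLabels(np.repeat([1, 2, 3], 20))
        res = rsec.global_f(X, labels)
        df2 = 57
        assert res["F"].mean() == pytest.approx(df2 / (df2 - 2), rel=0.1)

    def test_outlying_cluster_dominates_ranking(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(100, 60))
        X[0, 40:] += 6.0  # gene 0 separates the third cluster only
        Xm = rsec.ExpressionMatrix(X, [f"g{i}" for i in range(100)],
                                   [f"s{i}" for i in range(60)])
        labels = rsec.ClusterLabels(np.repeat([1, 2, 3], 20))
        res = rsec.global_f(Xm, labels)
        assert res["F"].idxmax() == 0

    def test_k2_f_equals_t_squared(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 14)
        X = rsec.ExpressionMatrix(np.concatenate([a, b])[None, :], ["g"],
                                  [f"s{i}" for i in range(26)])
        labels = rsec.ClusterLabels(np.repeat([1, 2], [12, 14]))
        res = rsec.global_f(X, labels)
        t_ref = stats.ttest_ind(a, b).statistic
        assert res["F"].iloc[0] == pytest.approx(t_ref**2, rel=1e-9)


class TestTopFeatures:
    def _fake_result(self):
        import pandas as pd
        return pd.DataFrame({
            "contrast": ["A"] * 4 + ["B"] * 4,
            "gene": ["g1", "g2", "g3", "g4"] * 2,
            "logFC": [1.0, 2.0, 0.5, 3.0, 1.0, 1.0, 2.0, 0.1],
            "stat": [0.0] * 8,
            "p": [0.01, 0.001, 0.5, 0.001, 0.2, 0.04, 0.04, 0.9],
            "p_adj": [0.02, 0.004, 0.5, 0.004, 0.3, 0.1, 0.1, 0.9],
        })

    def test_sort_oracle_p_then_absfc(self):
        out = rsec.top_features(self._fake_result(), 3)
        a = out[out["contrast"] == "A"]["gene"].tolist()
        assert a == ["g4", "g2", "g1"]  # p ties broken by larger |logFC|
        b = out[out["contrast"] == "B"]["gene"].tolist()
        assert b == ["g3", "g2", "g1"]

    def test_n_larger_than_g_returns_all(self):
        out = rsec.top_features(self._fake_result(), 100)
        assert len(out) == 8

    def test_multi_contrast_genes_flagged(self):
        out = rsec.top_features(self._fake_result(), 3)
        assert (out[out["gene"] == "g2"]["n_contrasts"] == 2).all()
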