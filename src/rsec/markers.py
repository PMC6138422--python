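"""Marker-gene detection via structured contrasts over clusters.

A one-way cell-means linear model is fitted per gene across all K clusters.
Residual variances are pooled across clusters and moderated across genes by
empirical-Bayes shrinkage toward a prior variance (scaled inverse-chi-square
prior, prior df estimated by method of moments on the log variances).
Because the model uses all samples, small clusters borrow variance
information from the whole dataset.

Three contrast families are provided: all pairwise differences, each
cluster versus the average of the rest, and hierarchical contrasts -- one
per internal node of the cluster dendrogram, comparing the mean of the
cluster means under the left child against the right child.  Hierarchical
contrasts give a multi-resolution view: top nodes find broad markers,
deep nodes find markers of individual clusters.  A global one-way ANOVA
F-statistic is available as an omnibus test, but its top genes tend to be
dominated by whichever single cluster is most outlying.

These tests are exploratory: the clusters were estimated from the same
data, so the p-values are overfit and must not be read as confirmatory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .core import UNASSIGNED, ClusterLabels, ExpressionMatrix

OVERFIT_WARNING = (
    "Marker p-values are exploratory: clusters were estimated from the same "
    "data being tested, so significance is overstated."
)

FAMILIES = ("pairwise", "one-vs-all", "hierarchical", "globalF")


@dataclass
class ContrastSet:
    """Named signed weight vectors over the K clusters; weights sum to 0."""

    contrasts: list[tuple[str, np.ndarray]]
    family: str
    cluster_ids: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.contrasts)

    def names(self) -> list[str]:
        return [n for n, _ in self.contrasts]


def build_contrasts(K: int, family: str, hierarchy=None) -> ContrastSet:
    """Construct a contrast family over clusters 1..K.

    pairwise: K(K-1)/2 vectors (+1, -1 on the pair); one-vs-all: K vectors
    (+1 on the cluster, -1/(K-1) elsewhere); hierarchical: K-1 vectors, one
    per internal dendrogram node, +1/L on the L left-child leaves and -1/R
    on the R right-child leaves (mean of cluster means per side).
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    ids = list(range(1, K + 1))
    contrasts: list[tuple[str, np.ndarray]] = []
    if family == "pairwise":
        for i in range(K):
            for j in range(i + 1, K):
                w = np.zeros(K)
                w[i], w[j] = 1.0, -1.0
                contrasts.append((f"c{ids[i]}-c{ids[j]}", w))
    elif family == "one-vs-all":
        for i in range(K):
            w = np.full(K, -1.0 / (K - 1))
            w[i] = 1.0
            contrasts.append((f"c{ids[i]}-rest", w))
    elif family == "hierarchical":
        if hierarchy is None:
            raise ValueError("hierarchical contrasts require a cluster hierarchy")
        leafset = sorted(hierarchy.leaf_clusters())
        if leafset != ids:
            raise ValueError(
                f"hierarchy leaves {leafset} do not match clusters 1..{K}")
        for node in hierarchy.internal_nodes():
            left = sorted(node.left.clusters)
            right = sorted(node.right.clusters)
            w = np.zeros(K)
            for c in left:
                w[c - 1] = 1.0 / len(left)
            for c in right:
                w[c - 1] = -1.0 / len(right)
            contrasts.append((node.name, w))
    else:  # globalF: omnibus, no weight vectors
        return ContrastSet(contrasts=[], family="globalF", cluster_ids=ids)
    for name, w in contrasts:
        assert abs(w.sum()) < 1e-9, f"contrast {name} does not sum to 0"
    return ContrastSet(contrasts=contrasts, family=family, cluster_ids=ids)


def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if np.max(-dif / x) < 1e-8:
            break
    return x


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes moderation of per-gene variances.

    Fits a scaled inverse-chi-square prior (s0^2, d0) to the observed
    variances by method of moments on log s^2 and returns the posterior
    variances (d0*s0^2 + df*s^2)/(d0 + df) along with (d0, s0^2).  Genes
    with zero variance are excluded from the fit and keep variance 0.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2 > 0
    out = s2.copy()
    if pos.sum() == 0:
        return out, np.inf, 0.0
    if pos.sum() == 1:
        # a single informative gene: nothing to borrow strength from
        return out, 0.0, float(s2[pos][0])
    z = np.log(s2[pos])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = (e.var(ddof=1) if e.size > 1 else 0.0) - polygamma(1, df / 2.0)
    if evar > 0:
        d0 = float(2.0 * _trigamma_inverse(np.array([evar]))[0])
        s02 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        out[pos] = (d0 * s02 + df * s2[pos]) / (d0 + df)
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
        out[pos] = s02
    return out, d0, s02


def _cluster_stats(X: ExpressionMatrix, labels: ClusterLabels):
    """Cluster means, sizes and pooled residual variance per gene."""
    lab = labels.labels
    keep = lab != UNASSIGNED
    Y = X.values[:, keep]
    lab = lab[keep]
    ids = np.unique(lab)
    sizes = np.array([(lab == c).sum() for c in ids])
    means = np.column_stack([Y[:, lab == c].mean(axis=1) for c in ids])
    rss = np.zeros(X.n_genes)
    for c, nc in zip(ids, sizes):
        sub = Y[:, lab == c]
        rss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = int(Y.shape[1] - ids.size)
    if df < 1:
        raise ValueError(f"no residual degrees of freedom: N={Y.shape[1]}, "
                         f"K={ids.size}")
    return ids, sizes, means, rss / df, df


def fit_de(X: ExpressionMatrix, labels: ClusterLabels,
           contrasts: ContrastSet) -> pd.DataFrame:
    """Moderated-t statistics for every (gene, contrast) pair.

    Returns a tidy table with columns contrast, gene, logFC, stat, p,
    p_adj; BH adjustment is applied within each contrast.  Genes with zero
    pooled variance are reported with logFC 0 and p 1 so that uninformative
    genes cannot drive downstream decisions.
    """
    ids, sizes, means, s2, df = _cluster_stats(X, labels)
    id_to_col = {int(c): j for j, c in enumerate(ids)}
    G = X.n_genes
    s2_mod, d0, _ = squeeze_variances(s2, df)
    # total df capped at the pooled df so a single gene reduces to plain t
    df_total = min(d0 + df, G * df) if np.isfinite(d0) else G * df
    zero_var = s2 == 0
    frames = []
    for name, w in contrasts.contrasts:
        wv = np.zeros(ids.size)
        for c, j in id_to_col.items():
            if c - 1 < len(w):
                wv[j] = w[c - 1]
        if np.any((np.abs(wv) > 0) & (sizes == 0)):
            raise ValueError(f"contrast {name} touches an empty cluster")
        logfc = means @ wv
        se = np.sqrt(s2_mod * np.sum(wv**2 / sizes))
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(se > 0, logfc / se, 0.0)
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
        logfc = np.where(zero_var, 0.0, logfc)
        p = np.where(zero_var, 1.0, p)
        t = np.where(zero_var, 0.0, t)
        p_adj = multipletests(p, method="fdr_bh")[1]
        frames.append(pd.DataFrame({
            "contrast": name, "gene": X.gene_ids, "logFC": logfc,
            "stat": t, "p": p, "p_adj": p_adj,
        }))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["contrast", "gene", "logFC", "stat", "p", "p_adj"])


def global_f(X: ExpressionMatrix, labels: ClusterLabels) -> pd.DataFrame:
    """Per-gene one-way ANOVA F across all clusters, df (K-1, N-K)."""
    ids, sizes, means, s2, df2 = _cluster_stats(X, labels)
    K = ids.size
    if K < 2:
        raise ValueError("global F requires at least 2 clusters")
    N = int(sizes.sum())
    grand = (means * sizes).sum(axis=1) / N
    between = ((means - grand[:, None]) ** 2 * sizes).sum(axis=1) / (K - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = np.where(s2 > 0, between / s2, 0.0)
    p = np.where(s2 > 0, stats.f.sf(F, K - 1, df2), 1.0)
    return pd.DataFrame({"gene": X.gene_ids, "F": F, "p": p,
                         "p_adj": multipletests(p, method="fdr_bh")[1]})


def top_features(res: pd.DataFrame, n_per_contrast: int) -> pd.DataFrame:
    """Top genes per contrast, ranked by p then |logFC| then gene order.

    The union table keeps one row per (contrast, gene) and flags genes that
    appear in several contrasts through ``n_contrasts``.
    """
    if n_per_contrast < 1:
        raise ValueError("n_per_contrast must be >= 1")
    res = res.copy()
    res["_ord"] = np.arange(len(res))
    res["_absfc"] = res["logFC"].abs()
    pieces = []
    for name, grp in res.groupby("contrast", sort=False):
        grp = grp.sort_values(["p", "_absfc", "_ord"],
                              ascending=[True, False, True],
                              kind="stable").head(n_per_contrast)
        grp = grp.assign(rank=np.arange(1, len(grp) + 1))
        pieces.append(grp)
    out = pd.concat(pieces, ignore_index=True).drop(columns=["_ord", "_absfc"])
    counts = out.groupby("gene")["contrast"].transform("nunique")
    out["n_contrasts"] = counts
    return out
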