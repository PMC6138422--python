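# Methods

This note records the models, estimators and numerical choices behind the
package, what the synthetic data does and does not emulate, and the known
limitations.

## Co-occurrence dissimilarities

Both robustness layers reduce an ensemble of (partial) clusterings to the
dissimilarity `D_ij = 1 − p_ij`.  In subsampling mode, `p_ij` is the
fraction of subsamples *containing both i and j* in which the pair
co-clustered; in ensemble (consensus) mode it is the fraction of
clusterings *in which both are assigned* that co-cluster them.  The
conditional denominator is the default because it does not penalise a
sample for having been left out of a draw or left unassigned by
sequential detection; a `denominator="B"` flag provides the
unconditional alternative.  Pairs with an empty denominator get `D = 1`
and are reported through the `counts` matrix (a warning by default, an
error in strict-coverage mode).  Subsamples are drawn without
replacement, size `floor(prop·n)` with `prop = 0.7` by default and
`B = 100` subsamples; only drawn samples are clustered — there is no
classification of held-out samples back into subsample clusters.

## Clustering a 0–1 dissimilarity (`cluster_01`)

Since `D` lives on a fixed scale, the natural control parameter is the
amount of dissimilarity tolerated *within* a cluster, not the number of
clusters.  We build an average-linkage tree on `D` and accept a subtree
as a cluster iff its merge height is at most α **and** the mean pairwise
dissimilarity among its leaves is at most α; otherwise we descend into
its children.  (For average linkage the second condition is implied by
the first by induction, but it is checked explicitly so that any
registered linkage alternative keeps the contract.)  Blocks smaller than
`min_size` become unassigned.  Because the accepted subtrees at a larger
α always contain those at a smaller α, raising α can only decrease the
number of unassigned samples — a property the test suite asserts.

## Sequential detection

One cluster is found per round.  On the remaining samples, for
`k = k0, k0+1, …, k_max`, the subsampling co-occurrence is computed with
the base clusterer at K = k (fresh draws per k) and cut by `cluster_01`.
The `top_candidates` largest blocks at k are compared with those at k+1
by Jaccard overlap; at the first k whose best pair reaches β, the
k+1-side block is the found cluster.  Its samples are removed and the
search restarts at k0; the loop ends when fewer than `remain_min`
samples remain or k_max is exhausted with nothing stable.  Defaults:
`top_candidates = 5`, `k_max = k0 + 10`, `remain_min = min_size`.

Two behaviours of this scheme are worth knowing.  First, a group of
clusters that stays merged at both k and k+1 can be accepted as one
cluster; choosing k₀ near (or sweeping it across) the plausible cluster
number in the grid protects against this, which is one reason the
workflow varies k₀ as a grid axis.  Second, perfectly exchangeable
spherical clusters of identical size are a degenerate case: when k
exceeds the number of remaining clusters, the direction of the extra
split is arbitrary, co-occurrence blocks dissolve, and the last clusters
of a round may stay unassigned.  Real expression clusters (and the
reference simulations, which use unequal cluster abundances) are not
exchangeable, and the consensus over many runs recovers samples that any
single run missed.  Samples that never join a stable cluster end
unassigned — by design.

## Consensus

Samples assigned in fewer than `min_assigned_prop` (default 0.5) of the
clusterings are forced to unassigned before clustering; a sample assigned
nowhere is always unassigned.  The remaining samples are clustered by
`cluster_01(D, alpha, min_size)`.  All clusterings are weighted equally.
Cluster ids are renumbered 1..K by decreasing size after this and every
other stage, with ties broken by the smaller original id, so outputs are
deterministic.

## Hierarchy and merging

The cluster hierarchy is an average-linkage tree on Euclidean distances
between per-cluster gene medians (medians resist outlying cells; the
choice of distance/linkage is the package default, configurable nowhere
on purpose — a single fixed tree keeps the merge step interpretable).
Children of every node are ordered by smallest leaf id, and internal
nodes are named `node1, node2, …` in pre-order, so tree topology, Newick
export and node names are reproducible.

At every internal node, the samples under the left and right child form
two groups and each gene is tested with the moderated-t engine (below).
The per-node proportion of DE genes is estimated once on the fixed tree
by one of:

- **adjP** — the fraction of genes with Benjamini–Hochberg adjusted
  p ≤ `fdr_level` (default 0.05), optionally also requiring
  |logFC| ≥ `lfc_min`;
- **pi0-storey** — `1 − π̂₀` with `π̂₀ = #{p > λ} / ((1−λ)G)` at λ = 0.5,
  clipped to [0, 1];
- **locfdr-lite** — `1 − π̂₀` by central matching on folded z-scores
  `z = Φ⁻¹(1 − p/2)`: the fraction of z in the null-central window
  [0, 1] divided by the N(0,1) mass of that window.  Folding makes the
  degenerate all-null case (`p ≡ 1`, hence z ≡ 0) land inside the
  window and return 0, which the unfolded transform would not.

These are three representative estimators of the proportion of non-null
genes; numerical parity with any specific external implementation is not
claimed.  A node merges iff its estimate is below `cutoff` **and** all
its internal descendants merged; maximal merged subtrees collapse to
single clusters.  Nodes whose child has fewer than 2 samples get
estimate 1 (never merged).  Estimates are not recomputed during the
traversal: the tree and its scores are fixed once.

## The DE engine

Per gene, a one-way cell-means model across all K clusters: residual
variance is pooled over clusters (df = N − K) and moderated across genes
by empirical-Bayes shrinkage toward a scaled inverse-chi-square prior
whose scale `s₀²` and df `d₀` are estimated by method of moments on
`log s²` (Newton inversion of the trigamma function).  Moderated
t-statistics use `df = min(d₀ + df_res, G·df_res)`; with a single gene
there is nothing to borrow, `d₀ = 0`, and the statistic and p-value
reduce exactly to the ordinary pooled two-sample t.  Genes with zero
pooled variance are reported with `logFC = 0`, `p = 1` so they can never
drive a merge.  Using all samples to estimate variance means small
clusters inherit stable variance estimates — the reason contrasts are
preferred over per-pair subset tests.

Contrast weights: pairwise `(+1, −1)`; one-vs-rest `(+1, −1/(K−1))`;
hierarchical node contrasts `+1/L` on the L left-child clusters and
`−1/R` on the R right-child clusters, i.e. mean-of-cluster-means per
side (the alternative — pooled-sample means per side — would weight
clusters by size; the mean-of-means form keeps small clusters audible).
BH adjustment is applied within each contrast separately by default.

## Alignment and cross-tabulation

Label alignment across clusterings is greedy-sequential: the first row
keeps its labels and each later row is matched to the previously aligned
row by Hungarian assignment on their contingency table; clusters with no
overlapping match receive fresh ids.  Sample ordering is lexicographic
in per-row first-appearance ranks of the aligned labels (unassigned
last), which makes the ordering invariant to how the input rows were
labeled.  Cross-tabulation of two clusterings uses only samples assigned
in both and normalises columns to sum to 1.

## Synthetic data

`simulate_clusters` draws baseline gene means from N(μ₀, 1) with
μ₀ = 6 (a typical log-expression magnitude), shifts a `prop_de` fraction
of genes by ±`effect` per cluster, and adds i.i.d. N(0, σ²) noise.
Optional nested splits shift a secondary gene set within half of a
cluster; optional noise samples sit at convex combinations (weights in
[0.25, 0.75]) of two cluster centres with true label −1.  The generator
emulates what the workflow assumes — distinct populations with marker
genes plus boundary samples — and deliberately does **not** emulate
count noise, dropout, library-size or batch effects.  Passing tests
therefore demonstrate algorithmic correctness on well-specified
Gaussian structure, not robustness to single-cell technical artifacts;
on real counts the matrix should be normalised and log-transformed
upstream.

## Reference study sizes

The validation studies (`rsec/benchmarks.py`) use desk-scale sizes
chosen once: recovery on n = 200, G = 100, K = 4, effect 5σ, cluster
abundances (0.35, 0.30, 0.20, 0.15) — unequal, as real cell-type
frequencies are — with an 8-combination grid
(dims {10, 20} × α {0.2, 0.3} × k₀ {3, 4}, β = 0.8, minSize 5) and
B = 20 subsamples with 2 k-means restarts per run; the nested-split
merge study on n = 120, G = 200; the sequential stress test on 20 tight
plus 20 scatter samples in 10 dimensions (at very low dimension a
handful of "uniform" points genuinely clumps, which would make the
fixture a poor null).  Recovery is scored by ARI over the samples the
pipeline assigns, since leaving unstable samples unassigned is the
intended behaviour, not an error.

## Determinism

Every source of randomness descends from one master seed.  Grid runs,
subsample draws and restarts derive child seeds by hashing the master
seed with a descriptive name (`sha256 → 31 bits`), so results are
independent of execution order and worker count, and removing one grid
combination leaves all others bit-identical.  Results are guaranteed
identical across runs for a fixed seed and single worker; the worker
pool only changes scheduling, not seeds, so multi-worker runs match
single-worker runs as well.

## Known limitations

- PAM is a plain deterministic BUILD + SWAP; on thousands of samples the
  O(Kn²) swap sweeps become the bottleneck — prefer k-means there.
- The 0–1 cut rule is a documented interpretation of "constrain the
  within-cluster dissimilarity"; other packages' exact tie-breaking may
  differ.
- Marker p-values are overfit (clusters and tests share the data) and
  are flagged as exploratory in all CLI output.
- No count-model likelihoods, zero-inflation weights, gene-mode
  clustering or trajectory inference.
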