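# rsec — resampling-based sequential ensemble clustering

`rsec` clusters large gene-expression sample sets — bulk or single-cell
RNA-Seq — where cluster boundaries are fuzzy, contaminant samples are
common, and no single algorithm-plus-tuning choice can be trusted.  It is
aimed at analysts who would otherwise run many clusterings by hand and
reconcile them by eye.

The workflow has four stages:

1. **Many candidate clusterings.**  A parameter grid (PCA dimensions,
   dissimilarity cutoff α, stability threshold β, initial cluster number
   k₀, minimum cluster size, base method, distance metric) is expanded
   into runs.  Each run can wrap its base algorithm in two robustness
   layers:
   - *Subsampling*: B random subsets of the samples are clustered and
     summarised as the co-occurrence dissimilarity
     `D_ij = 1 − p_ij`, where `p_ij` is the proportion of subsamples
     containing both *i* and *j* in which the pair co-clustered.  Because
     `D` lives on a fixed 0–1 scale, it is clustered by *constraining the
     within-cluster dissimilarity to at most α* rather than fixing K.
   - *Sequential detection*: clusters are found one at a time, in the
     spirit of tight clustering.  Candidate clusters at successive K are
     compared by the Jaccard overlap `|A ∩ B| / |A ∪ B|`; the first
     candidate whose overlap reaches β is removed, and the search
     restarts.  Samples never captured by a stable cluster stay
     **unassigned** (label −1).
2. **Consensus.**  The ensemble is summarised by the same
   `D_ij = 1 − p_ij` construction across clusterings and clustered once
   more with the α-constrained method.
3. **Hierarchy and merging.**  Consensus clusters are ordered by
   average-linkage clustering of their per-cluster gene medians.  At each
   node of that tree, every gene is tested (moderated t) between the two
   children, the proportion of DE genes is estimated (BH-significant
   fraction, Storey's 1 − π̂₀, or a central-matching variant), and sister
   nodes below a cutoff are merged, leaves upward.
4. **Markers.**  Per-gene linear models across all clusters with
   empirical-Bayes variance moderation support three contrast families —
   all pairwise, one-vs-rest, and one contrast per dendrogram node — plus
   a global one-way ANOVA F.  Marker p-values are exploratory by
   construction: the clusters were estimated from the same data.

## Worked example

```python
import rsec
from sklearn.metrics import adjusted_rand_score

sim = rsec.simulate_clusters(rsec.SimSpec(
    n=200, G=100, K=4, effect=5.0,
    cluster_props=[0.35, 0.3, 0.2, 0.15], seed=1))

grid = rsec.ParameterGrid(
    axes={"dims": [10, 20], "alpha": [0.2, 0.3], "k0": [3, 4],
          "beta": [0.8], "minSize": [5]},
    options={"B": 20, "restarts": 2, "k_max": 8})

result = rsec.rsec(sim.X, grid, seed=1)

merged = result.merged.labels
mask = merged != -1
print("candidate clusterings:", result.cluster_matrix.n_clusterings)
print("consensus clusters:   ", result.consensus.n_clusters)
print("merged clusters:      ", result.merged.n_clusters)
print("assigned samples:     ", int(mask.sum()), "of", len(merged))
print("ARI vs truth (assigned):",
      round(adjusted_rand_score(sim.truth.labels[mask], merged[mask]), 3))
```

prints

```
candidate clusterings: 8
consensus clusters:    6
merged clusters:       3
assigned samples:      140 of 200
ARI vs truth (assigned): 1.0
```

The 8 grid combinations each ran subsampled sequential detection; the
consensus found 6 clusters, which the merge step collapsed to 3.  Every
assigned sample is correctly grouped (ARI 1.0).  Sixty samples — here one
planted population plus stragglers — remain unassigned at these
desk-scale settings: sequential detection deliberately refuses to assign
samples that never form a stable cluster, which on real data is the
desired treatment of doublets and boundary cells.  `result.node_estimates`
holds the per-node DE proportions that drove the merging, and
`rsec.newick_export(result.hierarchy)` serialises the cluster tree.

The same pipeline is available from the shell:

```sh
rsec simulate --n 200 --genes 100 --k 4 --seed 1 --out expr.csv
rsec rsec --input expr.csv --config grid.yaml --out run/ --seed 1
rsec markers --input expr.csv --labels run/merged.csv \
     --family hierarchical --dendrogram run/dendrogram.nwk \
     --top 50 --out markers.tsv
```

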