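# crossct

Cross-species single-nucleus cell-type comparison for the primary motor
cortex (and any cortical region profiled the same way): tools for deciding
which within-species transcriptomic clusters from human, marmoset and
mouse are the *same* cell type, for clustering single-cell methylomes, and
for quantifying cross-species shifts in isoform usage. The package is
aimed at computational biologists who have per-species cluster labels and
an integrated expression matrix (or methylome count matrices, or
subclass-aggregated isoform quantifications) and want the comparative
statistics, not the upstream mapping or integration pipelines.

## What it computes

**Consensus cell types from a homology tree.** Cells are first balanced
across species (the species with the most clusters in a subclass gets a
cap of 200 nuclei per cluster; the others split that theoretical maximum
evenly across their clusters), aggregated into species-pure metacells,
and organised into a Ward dendrogram on 1 − Pearson correlation of
metacell profiles. Every node is scored by its species-mixing entropy

    H = −Σᵢ pᵢ log pᵢ,

where pᵢ is the share of cells from species *i* under the node
(normalized by log n_species so H ∈ [0, 1]), and by a stability score
(mean best-Jaccard match against trees rebuilt on 100× 95% subsamples).
Pruning collapses the subtree below the deepest well-mixed node on each
root-to-leaf path (default threshold 0.95 normalized) into one homologous
group, with a within-species purity check (threshold 0.8) that splits off
species-redundant subgroups; subtrees that are never well mixed surface as
species-specific groups. Within-species clusters are then linked across
species by their overlap — the sum over pruned-tree leaves of the minimum
proportion of each cluster's nuclei co-occupying the leaf, a score in
[0, 1] — and connected components become one-to-one, one-to-many,
many-to-many or species-specific consensus types. Pairwise alignment
resolution (leaves per subclass per species pair, over subsample
replicates) is compared with ANOVA + Tukey HSD.

**Methylome clustering.** snmC-seq cells pass five QC gates (mCCC < 0.03,
mCG > 0.5, mCH < 0.2, >500k final reads, mapping rate > 0.5); 100-kb-bin
features keep mean coverage in [250, 3000] outside a blacklist. Rates are
shrunk with a per-cell beta-binomial posterior, α = m(m(1−m)/v − 1),
β = (1−m)(m(1−m)/v − 1) from the method of moments, posterior
(α + mc)/(α + β + cov) divided by the cell's global mean α/(α+β) — so
zero-coverage entries are exactly 1 and the matrix has no missing values.
After mean/coverage-binned highly-variable-feature selection and PCA per
context, CH and CG components are concatenated; Leiden runs 300× on a KNN
graph, outlier-aware DBSCAN over the run-label matrix (Hamming distance)
extracts consensus versions, and a class-balanced random forest picks the
version with the best held-out balanced accuracy, rescuing outliers with
predicted probability > 0.3. A grid search keeps the largest resolution
with outliers < 0.05, accuracy > 0.95 and ≥ 30 cells per cluster.

**Differential isoform usage.** With P = isoform TPM / gene TPM per
subclass, the shift statistic is R = (P_human − P_mouse)/(P_human +
P_mouse) ∈ [−1, 1]; |R| > 0.8 is exactly a more-than-ninefold usage
change. Standard deviations of P come from 95% confidence intervals
(sd = CI width / (2·1.96) / gene TPM), the p-value from a two-sided
normal test on P_human − P_mouse, Bonferroni-corrected per subclass over
the tested (>10 TPM in both species, P > 0.2 in at least one) isoforms.

Seeded synthetic generators (`simulate_cross_species`,
`simulate_methylation`, `simulate_isoforms`) plant known consensus types,
methylome clusters and isoform switches so every stage can be validated
against ground truth without any external data.

## Worked example

```python
from crossct import *
from sklearn.metrics import adjusted_rand_score

types = one_to_one_types(4) + [
    TypeSpec("T5", {"human": 2, "marmoset": 1, "mouse": 1}),  # one-to-many
    TypeSpec("T6", {"human": 1}),                             # species-specific
]
config = SimulationConfig(consensus_types=tuple(types), seed=1)
dataset = simulate_cross_species(config)            # 1,700 cells, 3 species

metacells = build_metacells(dataset, target_size=50, seed=1)
tree = annotate_entropy(build_tree(metacells))
partition = prune_tree(tree, dataset=dataset)
print(partition.groups[["group_id", "n_cells", "n_species", "kind", "entropy"]])
labels = partition.labels(dataset.cell_table["cell_id"])
print("ARI vs planted types:",
      adjusted_rand_score(dataset.cell_table["consensus_type"], labels))
```

prints

```
  group_id  n_cells  n_species              kind   entropy
0       G1      300          3        well_mixed  1.000000
1       G2      300          3        well_mixed  1.000000
2       G3      100          1  species_specific  0.000000
3       G4      300          3        well_mixed  1.000000
4       G5      300          3        well_mixed  1.000000
5       G6      400          3           unmixed  0.946395
ARI vs planted types: 1.0
```

The four one-to-one types emerge as well-mixed groups at maximal entropy;
the species-specific cluster (G3, one species, entropy 0) is isolated; the
one-to-many type (G6) stays a single group — its extra human cluster
doubles the human share, which lowers the node's entropy below the 0.95
threshold, so it is kept whole as an unmixed multi-species subtree. Linking
clusters by overlap (`cluster_overlap` + `assign_consensus_types`) then
labels each group's member clusters one-to-one / one-to-many /
species-specific.

A command-line interface mirrors the stages
(`crossct simulate|preprocess|tree|map|methyl|isoform`, see `--help`).

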