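# Methods

## Scope and data model

The package operates downstream of read mapping, quantification and
cross-species integration. Its inputs are (i) an integrated cells ×
features matrix with per-cell species / within-species-cluster / subclass
labels, (ii) paired methylated-count and total-coverage matrices per
cytosine context with per-cell mapping metrics, and (iii) per-subclass
isoform and gene abundance tables with 95% confidence bounds. All three
are exchanged as MTX + TSV (or plain TSV) through `crossct.io`.

## Balanced downsampling

To stop one deeply-sampled species from dominating a subclass, the
species with the largest number of within-subclass clusters is allowed
`base_cap` (default 200) nuclei per cluster; this fixes a theoretical
maximum of `base_cap × max cluster count` nuclei per species, which every
other species splits evenly across its clusters with floor division
(e.g. cluster counts 8/4/3 at cap 200 → maximum 1,600 and caps
200/400/533). Sampling is uniform without replacement and seeded;
clusters below their cap are kept whole.

## Metacells

Metacells denoise the tree input by averaging small groups of highly
similar cells. Grouping runs within each (species × cluster) stratum via
seeded k-means with k = ceil(stratum size / target_size); `target_size`
defaults to 50 cells, a compromise between noise suppression and keeping
several metacells per cluster so subsampling replicates remain
informative. Metacells therefore never mix species or clusters — every
tree leaf is species-pure (entropy 0) and the purity bookkeeping of the
pruning stage is exact. The grouping algorithm and size are deliberate
design choices: any small-within-stratum clustering would do, and k-means
is deterministic under a seed.

## Homology tree

Metacell dissimilarity is 1 − Pearson correlation of profiles; a constant
profile is a hard error naming the metacell. Agglomeration is Ward's
method implemented through the Lance–Williams update with cluster weights
equal to metacell counts; exact distance ties are broken toward the pair
containing the lowest original metacell index, making merge order fully
deterministic. The implementation is cross-checked in the test suite
against scipy's independent Ward implementation on random problems.

**Species-mixing entropy.** Each node's mixing score is the Shannon
entropy of its species composition. Published cutoffs for this style of
analysis (2.9 / 2.75 for three species, 3.0 pairwise) exceed the maximum
of the three-species Shannon entropy in any standard log base, so they
cannot parameterize the formula directly; the package therefore exposes
both the log base and an entropy scale, defaulting to *normalized*
entropy H / log(n_species) with threshold 0.95. The calibration anchor:
mixtures of roughly (0.43, 0.37, 0.20) and (0.38, 0.30, 0.32) — the kind
of composition a genuinely well-mixed node shows — score 0.958 and 0.995
normalized and pass, while a node dominated 2:1:1 by one species (0.946)
does not. Raw-scale thresholds are accepted in configuration for
compatibility but are documented as not directly interpretable.

**Stability.** Node stability is the mean, over `stability_reps` (default
100) replicates, of the best Jaccard index between the node's cell set
and any node of a tree rebuilt on a seeded 95% cell subsample (metacells
are rebuilt per replicate). "Best-matching node" is deliberately
formalized as maximum Jaccard over cell sets. Stability is reported per
node and can optionally gate well-mixedness (`min_stability`), but does
not prune by default — it is a measurement, not a criterion.

**Pruning.** A depth-first search finds, along each root-to-leaf path,
the deepest node whose entropy exceeds the threshold (the well-mixed
upper node) and collapses the subtree below it into one homologous
group. Two refinements:

* *Purity descent.* At the selected node, if some species concentrates
  beyond `purity_threshold` (default 0.8) in one immediate child **and**
  at least one immediate child still spans every species present at the
  node, the search steps one level down and each child becomes a group.
  The second condition is this package's design choice: concentration
  alone fires at essentially every clean homologous type (in a binary
  tree some child almost always contains a complete species block), which
  would shear every type along species lines. Requiring a child that
  retains the full species mixture targets exactly the situation the
  check exists for — a well-mixed node concealing a species-redundant
  subgroup such as a species-specific cluster absorbed into a genuine
  type — and leaves clean types intact. The check inspects immediate
  children only and is applied once, not recursively.
* *Unmixed subtrees.* A maximal subtree containing no well-mixed node
  becomes a species-specific group when it is species-pure — split by
  within-species cluster label, so species-specific clusters are reported
  at cluster resolution (a single-species dataset degenerates to one
  group per cluster) — and a single multi-species group otherwise (this
  is how a one-to-many type, whose duplicated species lowers the type
  node below threshold, survives as one group).

## Consensus mapping

Cluster overlap between species A and B is
Σ_L min(n_{A∩L}/n_A, n_{B∩L}/n_B) over pruned-tree leaves L, with
denominators the clusters' retained cell counts; entries lie in [0, 1]
and the score is symmetric under role swap. Clusters are linked when
overlap ≥ `min_overlap` (default 0.25 — the linking threshold is a
package choice, recorded in the output metadata) and connected components
across species become consensus types; component shape gives the
homology class, and many-to-many components are kept whole rather than
re-split so the coarsest homology consistent with all species is
retained. Pairwise alignment resolution reuses the stability machinery
(95% subsamples, default 100 replicates) to count pruned-tree leaves per
subclass and species pair; replicate counts are compared by one-way
ANOVA with Tukey HSD (statsmodels), with an all-identical-counts
degenerate case reported as "no difference", p = 1.

## Methylome pipeline

Cell QC keeps a cell only if mCCC < 0.03, mCG > 0.5, mCH < 0.2, final
reads > 500,000 and mapping rate > 0.5 — all strict comparisons, with
missing metrics rejected as "incomplete". Feature QC keeps mean total
cytosine coverage in [250, 3000] (genomic-bin scale) outside blacklist
regions (0-based half-open intervals, intervaltree overlap).

Per cell and context, the beta prior is fitted by the method of moments
from the raw rates of covered features (sample variance, ddof 1);
v ≥ m(1−m), v ≤ 0 or m ∉ (0,1) raise diagnostic errors. The posterior
(α + mc)/(α + β + cov) divided by α/(α+β) yields a complete matrix with
zero-coverage entries exactly 1; the posterior is a convex combination of
the prior mean and the raw rate whenever coverage is positive.

Highly variable features use the variance-to-mean ratio of normalized
rates (the dispersion statistic is configurable; VMR is the default),
z-scored within a 20 × 5 quantile grid of feature mean × mean coverage;
singleton bins score 0, ties break by feature index. PCA per context
scales features to zero mean / unit variance; the retained dimensionality
is the largest drop in the explained-variance-ratio curve (≥ 2),
overridable. CH and CG components are concatenated.

Consensus clustering builds a symmetrized Euclidean KNN graph (default
k = 15), runs Leiden (RBConfiguration, `n_runs` = 300 distinct seeds) and
clusters the cells × runs label matrix with DBSCAN under Hamming distance
— valid without cross-run label alignment because co-membership within a
run is label-invariant. Epsilon traverses 20 values between the 1st and
99th percentiles of pairwise Hamming distances; versions whose cluster
count falls inside the min–max range observed across runs are kept
(deduplicated). Supervised finalization holds out a stratified 10% of
non-outlier cells, 10-fold cross-validates and trains a random forest
with balanced subsample class weights on the principal components
(recursive feature elimination is omitted by design — the evaluated
quantity is balanced accuracy, which elimination does not change), keeps
the version with the best held-out balanced accuracy, and rescues
outliers whose predicted-class probability strictly exceeds 0.3.
Resolution selection returns the largest Leiden resolution whose
finalized clustering has outlier fraction < 0.05, balanced accuracy
> 0.95 and mean cluster size ≥ 30, falling back (flagged) to the
highest-accuracy candidate. Iterating the pipeline over class/type
levels is left to the caller; every invocation takes its own resolution.

## Isoform usage

P = isoform TPM / gene TPM (clipped to [0, 1]; gene TPM 0 with positive
isoform TPM marks the row invalid), sd(P) = (CI_high − CI_low)/(2·1.96)
/ gene TPM, treating quantifier 95% intervals as symmetric normal. An
isoform is tested when TPM > 10 in both species and TPM > 10 with
P > 0.2 in at least one — the P in that filter is the genic proportion,
the same symbol defined above, not a significance level. The shift
R = (P_h − P_m)/(P_h + P_m) is compared to 0 with a two-sided normal
test on P_h − P_m over the summed variance (both sds 0 with unequal P is
a degenerate p = 0 with a warning); Bonferroni multiplies by the number
of tested isoforms in the subclass, capped at 1. A switch is tested with
|R| > 0.8, the exact algebraic image of a more-than-ninefold proportion
ratio under ρ ↦ (ρ−1)/(ρ+1).

## Synthetic data: what it emulates and what it does not

`simulate_cross_species` emulates an *integrated* embedding: cell =
type centroid + species offset + cluster offset (one-to-many children)
+ Gaussian noise. Defaults (chosen once as the study conditions for the
recovery benchmarks): `type_effect` 5, `noise_sd` 1 (a 5:1
signal-to-noise ratio), `species_shift` 1 — residual species signal
strong enough that within-type subtrees segregate by species (which is
what makes the deepest-well-mixed rule stop at type level) yet five-fold
below the type signal so types separate first — `cluster_effect` 0.5,
below the species shift so same-species sibling clusters pair before
crossing species; 30 features, 100 cells per cluster. A counts mode
(negative binomial, dispersion 2 — configurable; no count model is
prescribed upstream) exercises the preprocessing path.

`simulate_methylation` draws Poisson coverage and binomial methylated
counts around per-cluster feature levels, with logit-normal cell-to-cell
variability (`cell_noise_sd` 0.5) — without it, within-cluster cells are
exchangeable point masses whose graph subsplits are perfectly stable and
learnable, an artifact real methylomes do not show; with it, oversplit
versions lose held-out accuracy and the resolution criteria discriminate
as intended. QC failures are planted at a configurable fraction with the
violated metric assigned round-robin so every filter branch is exercised.
`simulate_isoforms` draws Dirichlet genic proportions shared across
species, plants switches at (0.92, 0.08) (usage ratio 11.5), and emits
symmetric relative confidence bounds; the default gene TPM scale (200)
keeps minor switch isoforms above the 10 TPM testing floor.

None of the generators model doublets, ambient contamination, batch
structure within species, coverage–GC bias or phylogenetically correlated
expression change. Passing benchmarks therefore demonstrate the
correctness and internal consistency of the statistics — not that real
cross-species data satisfy their assumptions.

## Numerical conventions and edge cases

0·log 0 = 0 in the entropy; pure compositions return exactly 0.0. Ward
ties break to the lowest metacell index. Stability replicates that leave
fewer than two metacells are skipped with a warning (all skipped is an
error). Single-replicate resolution runs report sd 0 by convention.
DBSCAN epsilons are clamped strictly positive so a degenerate
single-run ensemble reproduces that run's partition. Clusters smaller
than the fold count raise a stratification error (skipped with a warning
when other versions remain). An overlap row for a cluster with no
retained cells is emitted as zeros with a warning. Problem sizes in the
test suite (≤ 1,700 cells, ≤ 2,000 features, ≤ 20 replicate seeds) were
chosen so planted effects are comfortably detectable at desk scale.

## Known limitations

The entropy-threshold calibration is a modelling decision forced by the
unreproducible published cutoffs; analyses sensitive to the exact
threshold should sweep it. The purity-descent refinement changes behavior
relative to an unconditional trigger precisely on species-blocked type
nodes; both behaviors are reachable through configuration
(`purity_threshold=1.0` disables descent entirely). Consensus linking at
`min_overlap` 0.25 is a choice, not an estimate. The balanced random
forest stands in for any class-balanced ensemble; absolute accuracy
values depend on it only weakly at the separations tested.
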