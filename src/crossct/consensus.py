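"""Consensus cell types from a pruned homology partition.

The pruned tree's leaves (homologous groups) act as a common reference
frame: two within-species clusters are similar to the extent that their
cells co-occupy the same leaves. The overlap score between cluster A of
one species and cluster B of another is the sum over leaves of the minimum
proportion of each cluster's retained cells falling in that leaf — 1 when
the clusters always co-cluster, 0 when they never share a leaf. Linking
cluster pairs whose overlap reaches ``min_overlap`` and taking connected
components across species yields consensus types classified as one-to-one,
one-to-many, many-to-many, or species-specific.

Pairwise alignment resolution between two species is quantified by the
number of leaves the pruned tree resolves for a subclass, averaged over
subsampled replicates, and compared across species pairs with one-way
ANOVA plus Tukey HSD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import build_metacells
from .synthetic import LabeledDataset
from .tree import HomologyPartition, PruningParams, annotate_entropy, build_tree, prune_tree

__all__ = [
    "cluster_overlap",
    "ConsensusAssignment",
    "assign_consensus_types",
    "ResolutionStats",
    "pairwise_resolution",
    "ResolutionComparison",
    "compare_resolution",
]


def cluster_overlap(
    partition: HomologyPartition,
    cell_table: pd.DataFrame,
    species_a: str,
    species_b: str,
) -> pd.DataFrame:
    """Leaf co-occupancy overlap between two species' clusters.

    ``overlap(A, B) = sum over leaves L of min(n_{A&L}/n_A, n_{B&L}/n_B)``
    with ``n_A`` the retained (partitioned) cell count of cluster A. Rows
    are ``species_a`` clusters, columns ``species_b`` clusters; entries lie
    in [0, 1]. Clusters with no retained cells yield all-zero rows/columns
    with a warning.
    """
    for sp in (species_a, species_b):
        if not (cell_table["species"] == sp).any():
            raise ValueError(f"species {sp!r} not present in cell_table")

    merged = cell_table.merge(partition.assignments, on="cell_id", how="inner")

    def proportions(sp: str) -> pd.DataFrame:
        all_clusters = pd.unique(
            cell_table.loc[cell_table["species"] == sp, "cluster"]
        )
        sub = merged[merged["species"] == sp]
        tab = pd.crosstab(sub["cluster"], sub["group_id"])
        tab = tab.reindex(index=all_clusters, fill_value=0)
        totals = tab.sum(axis=1)
        empty = totals == 0
        if empty.any():
            warnings.warn(
                f"clusters with no retained cells for {sp!r}: "
                f"{list(tab.index[empty])}; emitting zeros"
            )
        props = tab.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
        return props

    pa = proportions(species_a)
    pb = proportions(species_b)
    leaves = pa.columns.union(pb.columns)
    pa = pa.reindex(columns=leaves, fill_value=0.0).to_numpy()
    pb = pb.reindex(columns=leaves, fill_value=0.0).to_numpy()
    overlap = np.minimum(pa[:, None, :], pb[None, :, :]).sum(axis=2)
    return pd.DataFrame(
        overlap,
        index=pd.Index(
            pd.unique(cell_table.loc[cell_table["species"] == species_a, "cluster"]),
            name=species_a,
        ),
        columns=pd.Index(
            pd.unique(cell_table.loc[cell_table["species"] == species_b, "cluster"]),
            name=species_b,
        ),
    )


@dataclass
class ConsensusAssignment:
    """Cluster -> consensus type map with homology classes.

    ``table`` has one row per within-species cluster (species, cluster,
    consensus_type, homology_class); every input cluster is assigned to
    exactly one consensus type.
    """

    table: pd.DataFrame
    min_overlap: float

    @property
    def n_types(self) -> int:
        return self.table["consensus_type"].nunique()


def _homology_class(species_counts: Mapping[str, int]) -> str:
    present = [c for c in species_counts.values() if c > 0]
    if len(present) == 1:
        return "species-specific"
    if max(present) == 1:
        return "one-to-one"
    if sum(c > 1 for c in present) == 1:
        return "one-to-many"
    return "many-to-many"


def assign_consensus_types(
    overlaps: Mapping[tuple[str, str], pd.DataFrame],
    min_overlap: float = 0.25,
) -> ConsensusAssignment:
    """Connected components of the cluster-overlap graph as consensus types.

    ``overlaps`` maps (row species, column species) pairs — typically one
    reference species against each other species — to overlap matrices.
    Clusters joined by an overlap >= ``min_overlap`` form one consensus
    type; the component's per-species cluster counts determine the
    homology class; unconnected clusters become species-specific types.
    """
    parent: dict[tuple[str, str], tuple[str, str]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for (sp_a, sp_b), mat in overlaps.items():
        for a in mat.index:
            parent.setdefault((sp_a, a), (sp_a, a))
        for b in mat.columns:
            parent.setdefault((sp_b, b), (sp_b, b))
        hit = np.argwhere(mat.to_numpy() >= min_overlap)
        for i, j in hit:
            union((sp_a, mat.index[i]), (sp_b, mat.columns[j]))

    components: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for node in parent:
        components.setdefault(find(node), []).append(node)

    rows = []
    for k, (_root, members) in enumerate(
        sorted(components.items(), key=lambda kv: kv[0])
    ):
        counts: dict[str, int] = {}
        for sp, _cl in members:
            counts[sp] = counts.get(sp, 0) + 1
        hclass = _homology_class(counts)
        for sp, cl in sorted(members):
            rows.append(
                {
                    "species": sp,
                    "cluster": cl,
                    "consensus_type": f"CT{k + 1}",
                    "homology_class": hclass,
                }
            )
    return ConsensusAssignment(table=pd.DataFrame(rows), min_overlap=min_overlap)


@dataclass
class ResolutionStats:
    """Leaf counts of the pruned two-species tree over subsample replicates."""

    species_pair: tuple[str, str]
    subclass: str
    leaf_counts: np.ndarray
    reps: int
    entropy_threshold: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.leaf_counts))

    @property
    def sd(self) -> float:
        if len(self.leaf_counts) < 2:
            return 0.0
        return float(np.std(self.leaf_counts, ddof=1))


def pairwise_resolution(
    dataset: LabeledDataset,
    species_pair: tuple[str, str],
    subclass: str,
    params: PruningParams = PruningParams(),
    reps: int = 100,
    target_size: int = 50,
    seed: int = 0,
) -> ResolutionStats:
    """Alignment resolution of one species pair within a subclass.

    Restricts the dataset to the pair and subclass, then per replicate
    subsamples ``subsample_fraction`` of cells, rebuilds metacells and the
    tree, prunes with the pairwise entropy cutoff, and records the number
    of leaves (groups) in the pruned tree.
    """
    params.validate()
    sp_a, sp_b = species_pair
    table = dataset.cell_table
    for sp in species_pair:
        ok = (table["species"] == sp) & (table["subclass"] == subclass)
        if not ok.any():
            raise ValueError(f"subclass {subclass!r} absent in species {sp!r}")
    mask = table["species"].isin(species_pair) & (table["subclass"] == subclass)
    sub = dataset.subset(mask.to_numpy())

    counts = []
    n_sub = int(np.floor(params.subsample_fraction * sub.n_cells))
    for r in range(reps):
        rng = np.random.default_rng([seed, r])
        keep = np.sort(rng.choice(sub.n_cells, size=n_sub, replace=False))
        rep_data = sub.subset(keep)
        try:
            mcs = build_metacells(
                rep_data, target_size=target_size,
                seed=int(rng.integers(2**31 - 1)),
            )
            if mcs.n_metacells < 2:
                raise ValueError("fewer than 2 metacells")
            t = annotate_entropy(build_tree(mcs), params)
            part = prune_tree(t, params, dataset=rep_data)
        except ValueError as err:
            warnings.warn(f"resolution replicate {r} skipped: {err}")
            continue
        counts.append(part.n_groups)
    if not counts:
        raise ValueError("all resolution replicates were skipped")
    return ResolutionStats(
        species_pair=species_pair,
        subclass=subclass,
        leaf_counts=np.asarray(counts),
        reps=reps,
        entropy_threshold=params.entropy_threshold,
    )


@dataclass
class ResolutionComparison:
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame | None
    note: str = ""


def compare_resolution(stats_list: Sequence[ResolutionStats]) -> ResolutionComparison:
    """One-way ANOVA plus Tukey HSD on replicate leaf counts across pairs."""
    if len(stats_list) < 2:
        raise ValueError("at least two species pairs are required")
    groups = [np.asarray(s.leaf_counts, dtype=float) for s in stats_list]
    labels = ["-".join(s.species_pair) for s in stats_list]

    all_same = all(np.ptp(g) == 0 for g in groups) and (
        len({g[0] for g in groups}) == 1
    )
    if all_same:
        return ResolutionComparison(
            f_statistic=0.0, p_value=1.0, tukey=None,
            note="no difference: all leaf counts identical",
        )
    f, p = stats.f_oneway(*groups)

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(groups)
    group_labels = np.concatenate(
        [[lab] * len(g) for lab, g in zip(labels, groups)]
    )
    res = pairwise_tukeyhsd(values, group_labels)
    tukey = pd.DataFrame(
        res.summary().data[1:], columns=res.summary().data[0]
    )
    return ResolutionComparison(f_statistic=float(f), p_value=float(p), tukey=tukey)
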