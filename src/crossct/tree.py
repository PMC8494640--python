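"""Homology tree over metacells: Ward hierarchy, species-mixing entropy,
split stability, and dynamic pruning into homologous cell groups.

The tree is built from pairwise metacell dissimilarities (1 - Pearson
correlation of profiles) agglomerated with Ward's method via the
Lance-Williams update, with ties broken deterministically toward the
lowest metacell index. Every node carries its member cell count per
species; the Shannon entropy of that composition measures species mixing
(0 for a species-pure node, maximal for a uniform mixture). Pruning
searches each root-to-leaf path for the deepest node whose entropy exceeds
the threshold (the "well-mixed upper node") and collapses the subtree
below it into one homologous group; subtrees containing no well-mixed node
become species-specific groups.

The published entropy cutoffs (2.9 / 2.75 / 3.0) exceed the maximum of the
three-species Shannon entropy in both natural log (ln 3 ~ 1.099) and log2
(~1.585), so they cannot be applied literally to this formula. Both the
log base and the scale are therefore configurable, and the default is
normalized entropy H / log(n_species) with threshold 0.95 — calibrated so
that mixtures around (0.43, 0.37, 0.2) count as well mixed while a node
dominated 2:1:1 by one species does not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import MetacellSet, build_metacells
from .synthetic import LabeledDataset

__all__ = [
    "PruningParams",
    "HomologyTree",
    "TreeNode",
    "HomologyPartition",
    "species_entropy",
    "build_tree",
    "node_entropy",
    "node_purity",
    "node_stability",
    "prune_tree",
]


@dataclass(frozen=True)
class PruningParams:
    """Thresholds and conventions for entropy annotation and pruning.

    ``entropy_threshold`` is on the configured scale: the default
    normalized scale divides H by log(n_species) so the threshold lives in
    [0, 1] regardless of species count and log base. Raw-scale thresholds
    (such as the published 2.9 / 2.75 / 3.0, which exceed the formula's
    three-species range) are accepted but are not directly interpretable.
    ``stability_reps`` x ``subsample_fraction`` control the subsampled tree
    replicates used for node stability; ``min_stability`` optionally gates
    well-mixedness on stability (off by default — stability is a reported
    measurement, not a pruning criterion).
    """

    entropy_threshold: float = 0.95
    purity_threshold: float = 0.8
    stability_reps: int = 100
    subsample_fraction: float = 0.95
    log_base: str = "natural"
    entropy_scale: str = "normalized"
    min_stability: float | None = None

    def validate(self) -> None:
        if not 0 < self.purity_threshold <= 1:
            raise ValueError("purity_threshold must lie in (0, 1]")
        if self.stability_reps < 1:
            raise ValueError("stability_reps must be >= 1")
        if not 0 < self.subsample_fraction < 1:
            raise ValueError("subsample_fraction must lie in (0, 1)")
        if self.log_base not in ("natural", "2"):
            raise ValueError("log_base must be 'natural' or '2'")
        if self.entropy_scale not in ("raw", "normalized"):
            raise ValueError("entropy_scale must be 'raw' or 'normalized'")


def species_entropy(
    counts: Sequence[float],
    log_base: str = "natural",
    n_species: int | None = None,
) -> float:
    """Shannon entropy H = -sum p_i log p_i of a species composition.

    ``p_i`` is the share of cells from species ``i`` among all cells in the
    node; 0 log 0 is treated as 0. If ``n_species`` is given the entropy is
    normalized by log(n_species) so a uniform mixture scores 1.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("entropy of an empty composition is undefined")
    p = counts[counts > 0] / total
    log = np.log2 if log_base == "2" else np.log
    h = float(-(p * log(p)).sum())
    if h <= 0:
        h = 0.0  # avoid the -0.0 artifact on pure compositions
    if n_species is not None:
        if n_species < 2:
            return 0.0
        h /= float(log(n_species))
    return h


@dataclass
class TreeNode:
    id: int
    left: int | None
    right: int | None
    metacells: np.ndarray  # metacell indices under this node
    species_counts: dict[str, int]  # member cell counts per species
    size: int  # total member cells
    height: float = 0.0
    entropy: float | None = None
    stability: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class HomologyTree:
    """Binary merge tree over species-pure metacell leaves."""

    nodes: list[TreeNode]
    metacells: MetacellSet
    merge_order: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return self.metacells.n_metacells

    @property
    def root(self) -> int:
        return len(self.nodes) - 1

    @property
    def species(self) -> list[str]:
        return self.metacells.species

    def children(self, node_id: int) -> tuple[int, int]:
        node = self.nodes[node_id]
        if node.is_leaf:
            raise ValueError(f"node {node_id} is a leaf")
        return node.left, node.right

    def node_cells(self, node_id: int) -> np.ndarray:
        """Row positions (into the source dataset) of the node's cells."""
        mems = self.metacells.members
        return np.concatenate(
            [mems[m] for m in self.nodes[node_id].metacells]
        )

    def species_set(self, node_id: int) -> frozenset:
        return frozenset(
            sp for sp, n in self.nodes[node_id].species_counts.items() if n > 0
        )


def _min_leaf(members: Iterable[int]) -> int:
    return min(members)


def build_tree(metacells: MetacellSet) -> HomologyTree:
    """Ward agglomeration of 1 - Pearson correlation between profiles.

    Ties in the merge criterion are broken toward the pair whose clusters
    contain the lowest original metacell indices, making the merge order
    fully deterministic.
    """
    n = metacells.n_metacells
    if n < 2:
        raise ValueError("at least 2 metacells are required")
    profiles = metacells.profiles
    if profiles.shape[1] < 2:
        raise ValueError("at least 2 features are required")
    sd = profiles.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(
            f"metacell {flat[0]} has a constant profile; correlation undefined"
        )

    D = 1.0 - np.corrcoef(profiles)
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)

    comp = metacells.composition
    species = metacells.species
    nodes: list[TreeNode] = []
    for i in range(n):
        counts = {sp: int(comp.iloc[i][sp]) for sp in species}
        nodes.append(
            TreeNode(
                id=i,
                left=None,
                right=None,
                metacells=np.array([i]),
                species_counts=counts,
                size=int(sum(counts.values())),
            )
        )

    # Lance-Williams Ward update on the current dissimilarity matrix;
    # cluster weights are metacell counts (each metacell is one point).
    active = {i: i for i in range(n)}  # matrix slot -> node id
    weight = {i: 1.0 for i in range(n)}
    rep = {i: i for i in range(n)}  # lowest original leaf index per slot
    d = D.copy()
    merge_order: list[tuple[int, int, int]] = []
    for step in range(n - 1):
        slots = sorted(active)
        best = None
        for ai in range(len(slots)):
            for bi in range(ai + 1, len(slots)):
                a, b = slots[ai], slots[bi]
                dist = d[a, b]
                lo, hi = sorted((rep[a], rep[b]))
                key = (dist, lo, hi)
                if best is None or key < best[0]:
                    best = (key, a, b)
        (_key, a, b) = best
        na, nb = weight[a], weight[b]
        new_id = n + step
        la, lb = active[a], active[b]
        node_a, node_b = nodes[la], nodes[lb]
        counts = {
            sp: node_a.species_counts[sp] + node_b.species_counts[sp]
            for sp in species
        }
        nodes.append(
            TreeNode(
                id=new_id,
                left=la,
                right=lb,
                metacells=np.concatenate([node_a.metacells, node_b.metacells]),
                species_counts=counts,
                size=node_a.size + node_b.size,
                height=float(d[a, b]),
            )
        )
        merge_order.append((la, lb, new_id))
        # update distances into slot a; retire slot b
        dab = d[a, b]
        for c in list(active):
            if c in (a, b):
                continue
            nc = weight[c]
            tot = na + nb + nc
            val = (
                (na + nc) * d[a, c] ** 2
                + (nb + nc) * d[b, c] ** 2
                - nc * dab**2
            ) / tot
            d[a, c] = d[c, a] = np.sqrt(max(val, 0.0))
        weight[a] = na + nb
        rep[a] = min(rep[a], rep[b])
        active[a] = new_id
        del active[b], weight[b], rep[b]

    return HomologyTree(nodes=nodes, metacells=metacells, merge_order=merge_order)


def node_entropy(
    tree: HomologyTree, node_id: int, params: PruningParams = PruningParams()
) -> float:
    """Species-mixing entropy of one node under the configured convention."""
    params.validate()
    counts = list(tree.nodes[node_id].species_counts.values())
    k = len(tree.species) if params.entropy_scale == "normalized" else None
    return species_entropy(counts, log_base=params.log_base, n_species=k)


def annotate_entropy(
    tree: HomologyTree, params: PruningParams = PruningParams()
) -> HomologyTree:
    for node in tree.nodes:
        node.entropy = node_entropy(tree, node.id, params)
    return tree


def node_purity(tree: HomologyTree, node_id: int) -> dict[str, float]:
    """Within-species purity at an internal node.

    For each species present, the largest fraction of that species' cells
    falling into a single immediate child subtree; a value near 1 means the
    species concentrates in one child.
    """
    node = tree.nodes[node_id]
    if node.is_leaf:
        raise ValueError("purity is undefined for a leaf node")
    left, right = tree.nodes[node.left], tree.nodes[node.right]
    purity: dict[str, float] = {}
    for sp, total in node.species_counts.items():
        if total == 0:
            continue
        purity[sp] = max(left.species_counts[sp], right.species_counts[sp]) / total
    return purity


def node_stability(
    tree: HomologyTree,
    dataset: LabeledDataset,
    params: PruningParams = PruningParams(),
    seed: int = 0,
) -> np.ndarray:
    """Mean maximum-Jaccard agreement with subsampled replicate trees.

    Each replicate rebuilds metacells and the tree on a seeded
    ``subsample_fraction`` subsample of cells; a node's replicate score is
    the best Jaccard index between its cell set and any replicate node's
    cell set (the optimal subtree), and stability is the mean over
    replicates. Scores are written back onto the tree nodes.
    """
    params.validate()
    n_cells = dataset.n_cells
    n_sub = int(np.floor(params.subsample_fraction * n_cells))
    orig_sets = [frozenset(tree.node_cells(v.id).tolist()) for v in tree.nodes]
    scores = np.zeros((params.stability_reps, len(tree.nodes)))
    used = np.zeros(params.stability_reps, dtype=bool)
    for r in range(params.stability_reps):
        rng = np.random.default_rng([seed, r])
        keep = np.sort(rng.choice(n_cells, size=n_sub, replace=False))
        sub = dataset.subset(keep)
        try:
            mcs = build_metacells(
                sub, target_size=tree.metacells.target_size,
                seed=int(rng.integers(2**31 - 1)),
            )
            if mcs.n_metacells < 2:
                raise ValueError("fewer than 2 metacells")
            rep_tree = build_tree(mcs)
        except ValueError as err:
            warnings.warn(f"stability replicate {r} skipped: {err}")
            continue
        used[r] = True
        rep_sets = [
            frozenset(keep[rep_tree.node_cells(v.id)].tolist())
            for v in rep_tree.nodes
        ]
        for i, s in enumerate(orig_sets):
            best = 0.0
            for t in rep_sets:
                inter = len(s & t)
                if inter == 0:
                    continue
                j = inter / (len(s) + len(t) - inter)
                if j > best:
                    best = j
            scores[r, i] = best
    if not used.any():
        raise ValueError("all stability replicates were skipped")
    mean_scores = scores[used].mean(axis=0)
    for node, s in zip(tree.nodes, mean_scores):
        node.stability = float(s)
    return mean_scores


@dataclass
class HomologyPartition:
    """Homologous groups: a partition of the retained cells.

    ``assignments`` maps every retained cell to exactly one group;
    ``groups`` carries per-group provenance (source tree node, entropy,
    stability, species composition, species-specific flag).
    """

    assignments: pd.DataFrame  # cell_id, group_id
    groups: pd.DataFrame
    params: PruningParams

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def labels(self, cell_ids: Sequence[str]) -> np.ndarray:
        lut = dict(
            zip(self.assignments["cell_id"], self.assignments["group_id"])
        )
        return np.array([lut[c] for c in cell_ids])


def prune_tree(
    tree: HomologyTree,
    params: PruningParams = PruningParams(),
    dataset: LabeledDataset | None = None,
) -> HomologyPartition:
    """Collapse the tree into homologous groups by species-mixing entropy.

    Along each root-to-leaf path the deepest node whose entropy exceeds the
    threshold is the well-mixed upper node; the subtree below it is merged
    into one homologous group. If at that node some species concentrates
    beyond ``purity_threshold`` in one immediate child *and* one child
    still spans every species present (the signature of a well-mixed group
    hiding a species-redundant subgroup), the search steps one level down
    and each child is collapsed instead. Maximal subtrees containing no
    well-mixed node become species-specific groups: one group per subtree
    when it mixes species, or one group per within-species cluster when it
    is species-pure (so species-specific clusters are reported at cluster
    resolution).

    ``dataset`` supplies cell ids and within-species cluster labels; when
    omitted, groups are reported over row positions.
    """
    params.validate()
    if tree.nodes[tree.root].entropy is None:
        annotate_entropy(tree, params)

    def well_mixed(node: TreeNode) -> bool:
        if node.entropy is None or node.entropy <= params.entropy_threshold:
            return False
        if params.min_stability is not None and node.stability is not None:
            return node.stability >= params.min_stability
        return True

    n_nodes = len(tree.nodes)
    has_wm = np.zeros(n_nodes, dtype=bool)
    for node in tree.nodes:  # children precede parents by construction
        flag = well_mixed(node)
        if not node.is_leaf:
            flag = flag or has_wm[node.left] or has_wm[node.right]
        has_wm[node.id] = flag

    if dataset is not None:
        cell_ids = dataset.cell_table["cell_id"].to_numpy()
        clusters = dataset.cell_table["cluster"].to_numpy()
        cell_species = dataset.cell_table["species"].to_numpy()
    else:
        cell_ids = None
        clusters = None
        cell_species = None

    group_rows: list[dict] = []
    assign_frames: list[pd.DataFrame] = []

    def emit(node_id: int, cells: np.ndarray, kind: str) -> None:
        node = tree.nodes[node_id]
        gid = f"G{len(group_rows) + 1}"
        ids = cell_ids[cells] if cell_ids is not None else cells.astype(str)
        assign_frames.append(pd.DataFrame({"cell_id": ids, "group_id": gid}))
        if cell_species is not None:
            sp_counts = pd.Series(cell_species[cells]).value_counts().to_dict()
        else:
            sp_counts = {sp: n for sp, n in node.species_counts.items() if n > 0}
        present = {sp: n for sp, n in sp_counts.items() if n > 0}
        group_rows.append(
            {
                "group_id": gid,
                "node_id": node_id,
                "n_cells": len(cells),
                "n_species": len(present),
                "entropy": node.entropy,
                "stability": node.stability,
                "species_specific": len(present) == 1,
                "kind": kind,
                "composition": present,
            }
        )

    def emit_group(node_id: int, kind: str = "well_mixed") -> None:
        emit(node_id, tree.node_cells(node_id), kind)

    def emit_unmixed(node_id: int) -> None:
        cells = tree.node_cells(node_id)
        if len(tree.species_set(node_id)) == 1 and clusters is not None:
            # species-pure subtree: report at within-species cluster level
            for cl in pd.unique(clusters[cells]):
                emit(node_id, cells[clusters[cells] == cl], "species_specific")
        else:
            emit(node_id, cells, "unmixed")

    def walk(node_id: int) -> None:
        node = tree.nodes[node_id]
        if not has_wm[node_id]:
            emit_unmixed(node_id)
            return
        kids = [] if node.is_leaf else [node.left, node.right]
        if any(has_wm[c] for c in kids):
            for c in kids:
                if has_wm[c]:
                    walk(c)
                else:
                    emit_unmixed(c)
            return
        # node is the deepest well-mixed node on every path through it
        if not node.is_leaf:
            purity = node_purity(tree, node_id)
            node_species = tree.species_set(node_id)
            child_spans_all = any(
                tree.species_set(c) == node_species for c in kids
            )
            if (
                max(purity.values()) > params.purity_threshold
                and child_spans_all
            ):
                for c in kids:
                    emit_group(c, kind="purity_descent")
                return
        emit_group(node_id)

    walk(tree.root)
    assignments = pd.concat(assign_frames, ignore_index=True)
    groups = pd.DataFrame(group_rows)
    return HomologyPartition(assignments=assignments, groups=groups, params=params)
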