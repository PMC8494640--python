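"""Plain-text interchange: MTX matrices with TSV annotation tables,
isoform TSVs, Newick tree export, and partition/consensus tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .preprocess import MetacellSet
from .synthetic import IsoformDataset, LabeledDataset, MethylDataset
from .tree import HomologyPartition, HomologyTree

__all__ = [
    "write_expression",
    "read_expression",
    "write_methylation",
    "read_methylation",
    "write_isoforms",
    "read_isoforms",
    "write_metacells",
    "tree_to_newick",
    "write_tree",
    "write_partition",
    "read_blacklist_bed",
]


def write_expression(dataset: LabeledDataset, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(dataset.matrix))
    dataset.cell_table.to_csv(outdir / "cells.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"feature_id": [f"feature_{i}" for i in range(dataset.n_features)]}
    ).to_csv(outdir / "features.tsv", sep="\t", index=False)
    return outdir


def read_expression(indir: str | Path) -> LabeledDataset:
    indir = Path(indir)
    matrix = np.asarray(spio.mmread(indir / "matrix.mtx").todense())
    cells = pd.read_csv(indir / "cells.tsv", sep="\t")
    return LabeledDataset(matrix=matrix, cell_table=cells)


def write_methylation(mdata: MethylDataset, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ctx in mdata.contexts:
        spio.mmwrite(outdir / f"mc_{ctx}.mtx", sparse.csr_matrix(mdata.mc[ctx]))
        spio.mmwrite(outdir / f"cov_{ctx}.mtx", sparse.csr_matrix(mdata.cov[ctx]))
    mdata.qc.to_csv(outdir / "qc.tsv", sep="\t", index=False)
    mdata.cell_table.to_csv(outdir / "cells.tsv", sep="\t", index=False)
    n_features = next(iter(mdata.mc.values())).shape[1]
    pd.DataFrame(
        {"feature_id": [f"bin_{i}" for i in range(n_features)]}
    ).to_csv(outdir / "features.tsv", sep="\t", index=False)
    return outdir


def read_methylation(indir: str | Path) -> MethylDataset:
    indir = Path(indir)
    mc: dict[str, np.ndarray] = {}
    cov: dict[str, np.ndarray] = {}
    for path in sorted(indir.glob("mc_*.mtx")):
        ctx = path.stem.removeprefix("mc_")
        mc[ctx] = np.asarray(spio.mmread(path).todense()).astype(np.int64)
        cov[ctx] = np.asarray(
            spio.mmread(indir / f"cov_{ctx}.mtx").todense()
        ).astype(np.int64)
    qc = pd.read_csv(indir / "qc.tsv", sep="\t")
    cells = pd.read_csv(indir / "cells.tsv", sep="\t")
    return MethylDataset(mc=mc, cov=cov, qc=qc, cell_table=cells)


def write_isoforms(dataset: IsoformDataset, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.table.to_csv(outdir / "isoforms.tsv", sep="\t", index=False)
    dataset.truth.to_csv(outdir / "isoform_truth.tsv", sep="\t", index=False)
    return outdir


def read_isoforms(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_metacells(metacells: MetacellSet, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metacells.table.to_csv(outdir / "metacells.tsv", sep="\t", index=False)
    spio.mmwrite(
        outdir / "metacell_profiles.mtx", sparse.csr_matrix(metacells.profiles)
    )
    return outdir


def tree_to_newick(tree: HomologyTree) -> str:
    """Newick string with bracketed node comments (size/entropy/stability)."""

    def comment(node) -> str:
        parts = [f"size={node.size}"]
        if node.entropy is not None:
            parts.append(f"entropy={node.entropy:.4f}")
        if node.stability is not None:
            parts.append(f"stability={node.stability:.4f}")
        return "[&" + ",".join(parts) + "]"

    def render(node_id: int) -> str:
        node = tree.nodes[node_id]
        if node.is_leaf:
            return f"mc{node_id}{comment(node)}:{0.0:.6f}"
        left = render(node.left)
        right = render(node.right)
        return f"({left},{right}){comment(node)}:{node.height:.6f}"

    return render(tree.root) + ";"


def write_tree(tree: HomologyTree, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "tree.nwk").write_text(tree_to_newick(tree) + "\n")
    rows = [
        {
            "node_id": n.id,
            "left": n.left if n.left is not None else -1,
            "right": n.right if n.right is not None else -1,
            "size": n.size,
            "entropy": n.entropy,
            "stability": n.stability,
            **{f"n_{sp}": c for sp, c in n.species_counts.items()},
        }
        for n in tree.nodes
    ]
    pd.DataFrame(rows).to_csv(outdir / "nodes.tsv", sep="\t", index=False)
    return outdir


def write_partition(partition: HomologyPartition, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    partition.assignments.to_csv(outdir / "groups.tsv", sep="\t", index=False)
    groups = partition.groups.copy()
    groups["composition"] = groups["composition"].map(
        lambda d: ";".join(f"{k}:{v}" for k, v in sorted(d.items()))
    )
    groups.to_csv(outdir / "group_info.tsv", sep="\t", index=False)
    return outdir


def read_blacklist_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read 0-based half-open intervals from a BED file."""
    regions = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        chrom, start, end = line.split("\t")[:3]
        regions.append((chrom, int(start), int(end)))
    return regions
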