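"""Balanced cross-species downsampling and metacell aggregation.

Downsampling equalises the number of nuclei each species contributes to a
subclass before integration-style analyses: the species with the most
within-subclass clusters is allowed ``base_cap`` nuclei per cluster, which
fixes a theoretical maximum (``base_cap x max cluster count``) that every
other species splits evenly (floor division) across its own clusters.

Metacells are small groups of highly similar cells whose averaged profiles
denoise the input of the homology tree. Grouping runs within each
(species x within-species cluster) stratum via seeded k-means with
``k = ceil(stratum size / target_size)``, so a metacell never mixes species
or clusters and the species entropy of every tree leaf is zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .synthetic import LabeledDataset

__all__ = ["DownsampleScheme", "MetacellSet", "balanced_downsample", "build_metacells"]


@dataclass(frozen=True)
class DownsampleScheme:
    subclass: str
    base_cap: int
    cluster_counts: Mapping[str, int]
    caps: Mapping[str, int]
    theoretical_max: int


def balanced_downsample(
    dataset: LabeledDataset,
    subclass: str,
    base_cap: int = 200,
    seed: int = 0,
) -> tuple[LabeledDataset, DownsampleScheme]:
    """Per-cluster caps balancing species contributions within a subclass.

    The species with the largest within-subclass cluster count receives
    ``base_cap`` per cluster; every species' cap is
    ``floor(theoretical_max / its cluster count)`` (identical for the
    largest species). Cells are sampled uniformly without replacement per
    cluster; clusters smaller than their cap are kept whole.
    """
    if base_cap < 1:
        raise ValueError("base_cap must be >= 1")
    table = dataset.cell_table
    in_subclass = table["subclass"] == subclass
    if not in_subclass.any():
        raise ValueError(f"subclass {subclass!r} not present in dataset")
    sub = table[in_subclass]

    cluster_counts = {
        sp: sub.loc[sub["species"] == sp, "cluster"].nunique()
        for sp in pd.unique(sub["species"])
    }
    theoretical_max = base_cap * max(cluster_counts.values())
    caps = {sp: theoretical_max // k for sp, k in cluster_counts.items()}

    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for (sp, _cl), grp in sub.groupby(["species", "cluster"], sort=True):
        idx = grp.index.to_numpy()
        cap = caps[sp]
        if len(idx) > cap:
            idx = rng.choice(idx, size=cap, replace=False)
        keep.append(idx)
    keep_idx = np.sort(np.concatenate(keep))
    positions = table.index.get_indexer(keep_idx)

    scheme = DownsampleScheme(
        subclass=subclass,
        base_cap=base_cap,
        cluster_counts=cluster_counts,
        caps=caps,
        theoretical_max=theoretical_max,
    )
    return dataset.subset(positions), scheme


@dataclass
class MetacellSet:
    """Aggregated profiles with species composition and cell membership.

    ``table`` has one row per metacell (metacell_id, species, cluster,
    n_cells); ``profiles`` row ``m`` is the mean feature vector of the
    member cells listed in ``members[m]`` (row positions into the source
    dataset); ``composition`` counts member cells per species.
    """

    profiles: np.ndarray
    table: pd.DataFrame
    members: list[np.ndarray]
    composition: pd.DataFrame
    species: list[str]
    target_size: int

    @property
    def n_metacells(self) -> int:
        return self.profiles.shape[0]

    def cell_ids(self, dataset: LabeledDataset, metacell: int) -> np.ndarray:
        return dataset.cell_table["cell_id"].to_numpy()[self.members[metacell]]


def build_metacells(
    dataset: LabeledDataset, target_size: int = 50, seed: int = 0
) -> MetacellSet:
    """Stratified k-means metacells of approximately ``target_size`` cells."""
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    if dataset.n_cells == 0:
        raise ValueError("dataset is empty")

    rng = np.random.default_rng(seed)
    table = dataset.cell_table
    profiles: list[np.ndarray] = []
    members: list[np.ndarray] = []
    rows: list[dict] = []
    for (sp, cl), grp in table.groupby(["species", "cluster"], sort=True):
        pos = table.index.get_indexer(grp.index)
        X = dataset.matrix[pos]
        n = len(pos)
        k = min(ceil(n / target_size), n)
        if k == 1:
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(
                n_clusters=k,
                random_state=int(rng.integers(2**31 - 1)),
                n_init=10,
            )
            labels = km.fit_predict(X)
        for lab in range(k):
            sel = pos[labels == lab]
            if len(sel) == 0:  # k-means may leave a cluster empty on ties
                continue
            profiles.append(dataset.matrix[sel].mean(axis=0))
            members.append(sel)
            rows.append({"species": sp, "cluster": cl, "n_cells": len(sel)})

    meta = pd.DataFrame(rows)
    meta.insert(0, "metacell_id", np.arange(len(meta)))
    species = list(pd.unique(table["species"]))
    comp = pd.DataFrame(0, index=meta["metacell_id"], columns=species)
    for m, row in meta.iterrows():
        comp.loc[m, row["species"]] = row["n_cells"]
    return MetacellSet(
        profiles=np.vstack(profiles),
        table=meta,
        members=members,
        composition=comp,
        species=species,
        target_size=target_size,
    )
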