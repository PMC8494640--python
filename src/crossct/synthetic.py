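"""Seeded generators for multi-species datasets with planted ground truth.

Three generators mirror the three data modalities the analysis stages
consume:

* :func:`simulate_cross_species` — an integrated cells x features matrix
  (embedding or counts) with planted consensus cell types spanning one or
  more species, driving the homology-tree and consensus-mapping stages.
* :func:`simulate_methylation` — paired methylated-count / total-coverage
  matrices per cytosine context with planted cluster structure and per-cell
  QC metrics, driving the methylome stage.
* :func:`simulate_isoforms` — per-subclass isoform/gene TPM tables with
  confidence intervals and planted usage switches, driving the
  differential-isoform-usage stage.

All generators are fully determined by their config (which includes the
seed): identical configs reproduce identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TypeSpec",
    "SimulationConfig",
    "LabeledDataset",
    "MethylSimConfig",
    "MethylDataset",
    "IsoformSimConfig",
    "IsoformDataset",
    "simulate_cross_species",
    "simulate_methylation",
    "simulate_isoforms",
]


# ---------------------------------------------------------------------------
# Expression / embedding simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TypeSpec:
    """Topology of one planted consensus type.

    ``clusters`` maps each species carrying the type to its number of
    within-species child clusters: one child per species gives a one-to-one
    type, ``k > 1`` children a one-to-many type, and omitting a species a
    species-specific type.
    """

    name: str
    clusters: Mapping[str, int]
    subclass: str = "all"

    def validate(self, species: Sequence[str]) -> None:
        if len(self.clusters) == 0:
            raise ValueError(f"consensus type {self.name!r} has no species")
        for sp, k in self.clusters.items():
            if sp not in species:
                raise ValueError(
                    f"consensus type {self.name!r} references unknown species {sp!r}"
                )
            if k < 1:
                raise ValueError(
                    f"consensus type {self.name!r} has zero clusters for {sp!r}"
                )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the cross-species expression generator.

    Defaults emulate an integrated (batch-corrected) embedding: the
    type signal (``type_effect``) dominates, a residual species signal
    (``species_shift``) five-fold weaker structures the subtree below each
    type, and unit Gaussian noise sits on top.
    """

    species: Sequence[str] = ("human", "marmoset", "mouse")
    consensus_types: Sequence[TypeSpec] = ()
    cells_per_cluster: int = 100
    n_features: int = 30
    type_effect: float = 5.0
    species_shift: float = 1.0
    cluster_effect: float = 0.5
    noise_sd: float = 1.0
    output_mode: str = "embedding"
    nb_dispersion: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.cells_per_cluster < 1:
            raise ValueError("cells_per_cluster must be >= 1")
        if self.n_features < 2:
            raise ValueError("n_features must be >= 2")
        if len(self.consensus_types) == 0:
            raise ValueError("at least one consensus type is required")
        if self.output_mode not in ("embedding", "counts"):
            raise ValueError("output_mode must be 'embedding' or 'counts'")
        for val, name in [
            (self.type_effect, "type_effect"),
            (self.species_shift, "species_shift"),
            (self.cluster_effect, "cluster_effect"),
            (self.noise_sd, "noise_sd"),
        ]:
            if val < 0:
                raise ValueError(f"{name} must be nonnegative")
        names = [t.name for t in self.consensus_types]
        if len(set(names)) != len(names):
            raise ValueError("consensus type names must be unique")
        for t in self.consensus_types:
            t.validate(self.species)


def one_to_one_types(
    n_types: int, species: Sequence[str] = ("human", "marmoset", "mouse"),
    subclass: str = "all",
) -> list[TypeSpec]:
    """Convenience: ``n_types`` one-to-one types across all ``species``."""
    return [
        TypeSpec(f"T{i + 1}", {sp: 1 for sp in species}, subclass=subclass)
        for i in range(n_types)
    ]


@dataclass
class LabeledDataset:
    """Cells x features matrix plus the per-cell annotation table.

    ``cell_table`` rows correspond one-to-one with matrix rows and carry
    ``cell_id``, ``species``, ``cluster`` (unique within species, not
    across), ``subclass`` and, for simulated data, the planted
    ``consensus_type``.
    """

    matrix: np.ndarray
    cell_table: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.cell_table) != self.matrix.shape[0]:
            raise ValueError("cell_table rows must match matrix rows")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def species(self) -> list[str]:
        return list(pd.unique(self.cell_table["species"]))

    def subset(self, mask: np.ndarray) -> "LabeledDataset":
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return LabeledDataset(
            self.matrix[idx], self.cell_table.iloc[idx].reset_index(drop=True)
        )


def simulate_cross_species(config: SimulationConfig) -> LabeledDataset:
    """Draw cells per species x cluster around planted type centroids.

    Each cell's feature vector is ``type centroid + species offset
    [+ child-cluster offset for one-to-many types] + Gaussian noise`` in
    embedding mode; in counts mode that vector is the log-mean of a
    negative-binomial draw (fixed dispersion ``nb_dispersion``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    F = config.n_features

    species_offsets = {
        sp: config.species_shift * rng.standard_normal(F) for sp in config.species
    }

    blocks: list[np.ndarray] = []
    rows: list[dict] = []
    for tspec in config.consensus_types:
        centroid = config.type_effect * rng.standard_normal(F)
        for sp in config.species:
            if sp not in tspec.clusters:
                continue
            k = tspec.clusters[sp]
            for child in range(k):
                child_offset = (
                    config.cluster_effect * rng.standard_normal(F)
                    if k > 1
                    else np.zeros(F)
                )
                mean = centroid + species_offsets[sp] + child_offset
                n = config.cells_per_cluster
                noise = config.noise_sd * rng.standard_normal((n, F))
                blocks.append(mean + noise)
                cluster = (
                    f"{sp}_{tspec.name}" if k == 1 else f"{sp}_{tspec.name}_{child + 1}"
                )
                rows.extend(
                    {
                        "species": sp,
                        "cluster": cluster,
                        "subclass": tspec.subclass,
                        "consensus_type": tspec.name,
                    }
                    for _ in range(n)
                )

    matrix = np.vstack(blocks)
    if config.output_mode == "counts":
        # gamma-Poisson mixture = negative binomial with size nb_dispersion
        log_mu = np.clip(matrix, None, 12.0)
        mu = np.exp(log_mu)
        lam = rng.gamma(config.nb_dispersion, mu / config.nb_dispersion)
        matrix = rng.poisson(lam).astype(np.int64)

    cell_table = pd.DataFrame(rows)
    cell_table.insert(0, "cell_id", [f"cell_{i}" for i in range(len(cell_table))])
    return LabeledDataset(matrix, cell_table)


# ---------------------------------------------------------------------------
# Methylome simulation
# ---------------------------------------------------------------------------

# per-cell QC metric columns and, for planted failures, one violating value
# per metric (assigned round-robin so every filter branch is exercised)
_QC_COLUMNS = ("mccc_rate", "mcg_rate", "mch_rate", "final_reads", "mapping_rate")
_QC_VIOLATIONS = {
    "mccc_rate": 0.05,
    "mcg_rate": 0.4,
    "mch_rate": 0.3,
    "final_reads": 400_000,
    "mapping_rate": 0.4,
}


@dataclass(frozen=True)
class MethylSimConfig:
    """Planted-cluster methylome generator settings.

    ``levels[context]`` is an ``n_clusters x n_features`` array of true
    methylation levels in [0, 1]; coverage is Poisson with per-feature mean
    ``coverage_mean`` and methylated counts are binomial given coverage.
    """

    n_cells_per_cluster: int
    n_features: int
    levels: Mapping[str, np.ndarray]
    coverage_mean: float = 10.0
    cell_noise_sd: float = 0.5
    qc_fail_fraction: float = 0.0
    seed: int = 0

    @property
    def contexts(self) -> tuple[str, ...]:
        return tuple(self.levels.keys())

    @property
    def n_clusters(self) -> int:
        return next(iter(self.levels.values())).shape[0]

    def validate(self) -> None:
        if self.n_cells_per_cluster < 1:
            raise ValueError("n_cells_per_cluster must be >= 1")
        if not self.levels:
            raise ValueError("at least one context is required")
        for ctx, lv in self.levels.items():
            lv = np.asarray(lv)
            if lv.shape[1] != self.n_features:
                raise ValueError(f"levels[{ctx!r}] must have n_features columns")
            if lv.min() < 0 or lv.max() > 1:
                raise ValueError(f"levels[{ctx!r}] must lie in [0, 1]")
        if not 0 <= self.qc_fail_fraction <= 1:
            raise ValueError("qc_fail_fraction must lie in [0, 1]")
        if np.any(np.asarray(self.coverage_mean) < 0):
            raise ValueError("coverage_mean must be nonnegative")
        if self.cell_noise_sd < 0:
            raise ValueError("cell_noise_sd must be nonnegative")

    @classmethod
    def random(
        cls,
        n_clusters: int,
        n_features: int,
        n_cells_per_cluster: int,
        contexts: Sequence[str] = ("CG",),
        low: float = 0.1,
        high: float = 0.9,
        coverage_mean: float = 10.0,
        qc_fail_fraction: float = 0.0,
        seed: int = 0,
    ) -> "MethylSimConfig":
        """Cluster levels drawn uniformly from ``{low, high}`` per feature."""
        rng = np.random.default_rng(seed)
        levels = {
            ctx: rng.choice([low, high], size=(n_clusters, n_features))
            for ctx in contexts
        }
        return cls(
            n_cells_per_cluster=n_cells_per_cluster,
            n_features=n_features,
            levels=levels,
            coverage_mean=coverage_mean,
            qc_fail_fraction=qc_fail_fraction,
            seed=seed,
        )


@dataclass
class MethylDataset:
    """Paired mc/cov count matrices per context with QC and planted labels."""

    mc: dict[str, np.ndarray]
    cov: dict[str, np.ndarray]
    qc: pd.DataFrame
    cell_table: pd.DataFrame

    @property
    def contexts(self) -> tuple[str, ...]:
        return tuple(self.mc.keys())


def simulate_methylation(config: MethylSimConfig) -> MethylDataset:
    """Poisson coverage, binomial methylated counts, round-robin QC failures."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_cells = config.n_clusters * config.n_cells_per_cluster
    clusters = np.repeat(np.arange(config.n_clusters), config.n_cells_per_cluster)

    mc: dict[str, np.ndarray] = {}
    cov: dict[str, np.ndarray] = {}
    mean = np.broadcast_to(
        np.asarray(config.coverage_mean, dtype=float), (config.n_features,)
    )
    for ctx in config.contexts:
        lv = np.asarray(config.levels[ctx], dtype=float)[clusters]
        if config.cell_noise_sd > 0:
            # biological cell-to-cell variability: logit-scale jitter of the
            # cluster level; exact 0/1 levels stay exact
            interior = (lv > 0) & (lv < 1)
            jitter = config.cell_noise_sd * rng.standard_normal(lv.shape)
            logit = np.zeros_like(lv)
            logit[interior] = np.log(lv[interior] / (1 - lv[interior]))
            lv = np.where(
                interior, 1.0 / (1.0 + np.exp(-(logit + jitter))), lv
            )
        c = rng.poisson(np.broadcast_to(mean, (n_cells, config.n_features)))
        m = rng.binomial(c, lv)
        cov[ctx] = c
        mc[ctx] = m

    qc = pd.DataFrame(
        {
            "mccc_rate": rng.uniform(0.005, 0.02, n_cells),
            "mcg_rate": rng.uniform(0.6, 0.85, n_cells),
            "mch_rate": rng.uniform(0.02, 0.1, n_cells),
            "final_reads": rng.integers(600_000, 3_000_000, n_cells),
            "mapping_rate": rng.uniform(0.6, 0.95, n_cells),
        }
    )
    n_fail = int(round(config.qc_fail_fraction * n_cells))
    if n_fail:
        fail_idx = np.sort(rng.choice(n_cells, size=n_fail, replace=False))
        for i, cell in enumerate(fail_idx):
            metric = _QC_COLUMNS[i % len(_QC_COLUMNS)]
            qc.loc[cell, metric] = _QC_VIOLATIONS[metric]

    cell_ids = [f"mcell_{i}" for i in range(n_cells)]
    qc.insert(0, "cell_id", cell_ids)
    cell_table = pd.DataFrame(
        {"cell_id": cell_ids, "cluster": [f"M{c}" for c in clusters]}
    )
    return MethylDataset(mc=mc, cov=cov, qc=qc, cell_table=cell_table)


# ---------------------------------------------------------------------------
# Isoform simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IsoformSimConfig:
    """Per-subclass isoform abundance generator with planted usage switches.

    Planted switches set the first isoform of a gene to
    ``switch_proportions`` (first species) versus its reverse (second
    species); the default (0.92, 0.08) gives a usage ratio of 11.5, safely
    beyond the ninefold-switch boundary. Remaining isoforms share the rest
    of the gene evenly. ``ci_rel_halfwidth`` sets symmetric 95% confidence
    bounds at ``tpm * (1 +/- halfwidth)``.
    """

    n_genes: int = 100
    isoforms_per_gene: int = 2
    species: tuple[str, str] = ("human", "mouse")
    subclasses: Sequence[str] = ("subclass_1",)
    gene_tpm_scale: float = 200.0
    ci_rel_halfwidth: float = 0.1
    noise_sd: float = 0.0
    n_switches: int = 0
    switch_proportions: tuple[float, float] = (0.92, 0.08)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.isoforms_per_gene < 1:
            raise ValueError("n_genes and isoforms_per_gene must be >= 1")
        if self.n_switches > self.n_genes:
            raise ValueError("n_switches cannot exceed n_genes")
        if self.n_switches and self.isoforms_per_gene < 2:
            raise ValueError("switches require genes with >= 2 isoforms")
        a, b = self.switch_proportions
        if not (0 < b < a < 1):
            raise ValueError("switch_proportions must satisfy 0 < minor < major < 1")
        if self.noise_sd < 0 or self.ci_rel_halfwidth < 0:
            raise ValueError("noise_sd and ci_rel_halfwidth must be nonnegative")


@dataclass
class IsoformDataset:
    """Long-format isoform abundance table plus planted truth."""

    table: pd.DataFrame
    truth: pd.DataFrame


def simulate_isoforms(config: IsoformSimConfig) -> IsoformDataset:
    """Emit isoform TPM = gene TPM x true proportion x multiplicative noise."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    sp_a, sp_b = config.species
    k = config.isoforms_per_gene

    switch_genes = set(
        rng.choice(config.n_genes, size=config.n_switches, replace=False).tolist()
    )

    rows: list[dict] = []
    truth_rows: list[dict] = []
    for g in range(config.n_genes):
        gene_id = f"gene_{g}"
        if k == 1:
            base = np.array([1.0])
        else:
            base = rng.dirichlet(np.ones(k) * 5.0)
        props = {sp_a: base.copy(), sp_b: base.copy()}
        if g in switch_genes:
            hi, lo = config.switch_proportions
            for sp, major in ((sp_a, hi), (sp_b, lo)):
                rest = props[sp][1:]
                rest = rest / rest.sum() * (1.0 - major) if k > 1 else rest
                props[sp] = np.concatenate([[major], rest])
        for j in range(k):
            iso_id = f"iso_{g}_{j}"
            pa, pb = props[sp_a][j], props[sp_b][j]
            denom = pa + pb
            r_true = (pa - pb) / denom if denom > 0 else 0.0
            truth_rows.append(
                {
                    "isoform_id": iso_id,
                    "gene_id": gene_id,
                    f"P_{sp_a}": pa,
                    f"P_{sp_b}": pb,
                    "R": r_true,
                    # a planted switch moves every isoform of the gene;
                    # the flag marks those whose true usage ratio exceeds 9
                    "switch": abs(r_true) > 0.8,
                }
            )
        for subclass in config.subclasses:
            for sp in (sp_a, sp_b):
                gene_tpm = config.gene_tpm_scale * rng.lognormal(0.0, 0.25)
                iso_tpm = gene_tpm * props[sp]
                if config.noise_sd > 0:
                    iso_tpm = iso_tpm * np.exp(
                        config.noise_sd * rng.standard_normal(k)
                    )
                gene_total = iso_tpm.sum()
                for j in range(k):
                    t = iso_tpm[j]
                    hw = config.ci_rel_halfwidth * t
                    rows.append(
                        {
                            "isoform_id": f"iso_{g}_{j}",
                            "gene_id": f"gene_{g}",
                            "species": sp,
                            "subclass": subclass,
                            "tpm": t,
                            "tpm_ci_low": t - hw,
                            "tpm_ci_high": t + hw,
                            "gene_tpm": gene_total,
                        }
                    )

    return IsoformDataset(table=pd.DataFrame(rows), truth=pd.DataFrame(truth_rows))
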