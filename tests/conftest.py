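import numpy as np
import pandas as pd
import pytest

from crossct import (
    LabeledDataset,
    MethylSimConfig,
    SimulationConfig,
    TypeSpec,
    one_to_one_types,
    simulate_cross_species,
    simulate_methylation,
)


def recovery_types() -> tuple[TypeSpec, ...]:
    """Six planted types: four one-to-one, one one-to-many, one species-specific."""
    return tuple(
        one_to_one_types(4)
        + [
            TypeSpec("T5", {"human": 2, "marmoset": 1, "mouse": 1}),
            TypeSpec("T6", {"human": 1}),
        ]
    )


@pytest.fixture(scope="session")
def recovery_dataset() -> LabeledDataset:
    """3 species, 6 planted types (default study conditions), seed 1."""
    return simulate_cross_species(
        SimulationConfig(consensus_types=recovery_types(), seed=1)
    )


@pytest.fixture(scope="session")
def methyl_dataset():
    """4 planted methylome clusters at genomic-bin coverage, both contexts."""
    config = MethylSimConfig.random(
        n_clusters=4,
        n_features=800,
        n_cells_per_cluster=75,
        contexts=("CG", "CH"),
        coverage_mean=300.0,
        seed=7,
    )
    return simulate_methylation(config)


def hand_partition(cluster_leaves: dict[str, dict[str, int]]) -> tuple:
    """Build a HomologyPartition + cell table from explicit leaf occupancies.

    ``cluster_leaves[(species, cluster)] = {leaf: n_cells}`` laid out as
    ``{"species|cluster": {leaf: n}}`` for readable test input.
    """
    from crossct.tree import HomologyPartition, PruningParams

    assign_rows, cell_rows = [], []
    i = 0
    for key, leaves in cluster_leaves.items():
        species, cluster = key.split("|")
        for leaf, n in leaves.items():
            for _ in range(n):
                cid = f"c{i}"
                i += 1
                assign_rows.append({"cell_id": cid, "group_id": leaf})
                cell_rows.append(
                    {"cell_id": cid, "species": species, "cluster": cluster}
                )
    partition = HomologyPartition(
        assignments=pd.DataFrame(assign_rows),
        groups=pd.DataFrame(),
        params=PruningParams(),
    )
    return partition, pd.DataFrame(cell_rows)
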