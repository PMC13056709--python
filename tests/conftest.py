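import numpy as np
import pandas as pd
import pytest

from txfidelity import (
    CountMatrix,
    SimConfig,
    cell_table_from_truth,
    generate_experiment,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A fast-but-structured experiment: 4 types, 400 genes, 500+500 cells."""
    return SimConfig(
        n_genes=400,
        n_cells_day0=500,
        n_cells_day14=500,
        n_markers_per_type=25,
        drift_sd=0.3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    day0, day14, truth = generate_experiment(small_config)
    return day0, day14, truth


@pytest.fixture(scope="session")
def small_cells(small_experiment) -> pd.DataFrame:
    day0, day14, truth = small_experiment
    cells = cell_table_from_truth(day0, day14, truth)
    return cells.rename(columns={"true_label": "label"})


@pytest.fixture(scope="session")
def small_counts(small_experiment) -> CountMatrix:
    day0, day14, _ = small_experiment
    return CountMatrix.concat_cells([day0, day14])


def make_counts(dense, gene_ids=None, cell_ids=None) -> CountMatrix:
    """Helper: CountMatrix from a dense list-of-lists."""
    dense = np.asarray(dense)
    genes = gene_ids or [f"g{i+1}" for i in range(dense.shape[0])]
    cells = cell_ids or [f"c{j+1}" for j in range(dense.shape[1])]
    return CountMatrix(dense, np.array(genes, object), np.array(cells, object))
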