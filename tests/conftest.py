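import numpy as np
import pandas as pd
import pytest

from voxtome import (
    CountMatrix,
    SyntheticConfig,
    VoxelGrid,
    generate_fixture,
    normalize_per_million,
)


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """4 genes x 3 voxels with hand-checkable numbers."""
    counts = np.array(
        [
            [10, 0, 5],
            [90, 1, 5],
            [0, 0, 10],
            [0, 3, 0],
        ]
    )
    return CountMatrix(["gA", "gB", "gC", "gD"], ["v1", "v2", "v3"], counts)


@pytest.fixture
def tiny_grid() -> VoxelGrid:
    table = pd.DataFrame(
        {
            "voxel_id": ["v1", "v2", "v3"],
            "section_id": ["S1", "S1", "S1"],
            "row": [0, 0, 1],
            "col": [0, 1, 0],
        }
    )
    return VoxelGrid(table)


@pytest.fixture(scope="session")
def small_fixture():
    """A desk-scale synthetic dataset shared across tests (seed 7).

    Smaller than the default study conditions so unit tests stay fast; the
    acceptance suite exercises the full default configuration.
    """
    config = SyntheticConfig(seed=7, n_genes=1200, markers_per_program=80)
    counts, grid, truth = generate_fixture(config)
    return counts, grid, truth


@pytest.fixture(scope="session")
def small_expression(small_fixture):
    counts, grid, truth = small_fixture
    return normalize_per_million(counts), grid, truth
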