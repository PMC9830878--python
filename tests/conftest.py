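import numpy as np
import pytest
import scipy.sparse as sp

from xylolink import SimConfig, simulate_two_species
from xylolink.io import CellMatrix


@pytest.fixture(scope="session")
def dataset():
    """Default-condition synthetic two-species dataset (seed 1), shared
    across the suite to keep runtime down."""
    return simulate_two_species(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """Smaller dataset for the heavier end-to-end checks."""
    return simulate_two_species(SimConfig(seed=3, n_cells_per_cluster=40))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_cell_matrix(counts, species="ptr", prefix=""):
    counts = np.asarray(counts)
    n, g = counts.shape
    return CellMatrix(
        sp.csr_matrix(counts),
        [f"{prefix}c{i}" for i in range(n)],
        [f"{prefix}g{j}" for j in range(g)],
        species=species,
    )
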