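import numpy as np
import pytest

from mnsf.core_model import SampleData
from mnsf.simulate import design_preset, simulate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """Two small simulated samples (8x8 grids, 30 genes) plus ground truth."""
    design = design_preset(
        "fig1a", grid_shape=((8, 8), (8, 8)), n_genes=30, seed=11
    )
    return simulate_dataset(design)


@pytest.fixture()
def single_sample():
    rng = np.random.default_rng(21)
    n = 25
    coords = np.column_stack(
        [np.tile(np.arange(5), 5), np.repeat(np.arange(5), 5)]
    ).astype(float)
    counts = rng.poisson(3.0, (n, 12))
    counts[0, :] = np.maximum(counts[0, :], 1)  # no all-zero spots
    return SampleData(counts=counts, coords=coords, sample_id="tiny")
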