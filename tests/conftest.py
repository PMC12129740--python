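import numpy as np
import pytest

from mtlnet.grids import BoldRun, VolumeGrid
from mtlnet.synthgen import CohortConfig, generate_cohort, generate_run


@pytest.fixture(scope="session")
def small_grid():
    return VolumeGrid((20, 20, 12), (3.0, 3.0, 3.0))


@pytest.fixture(scope="session")
def clean_run(small_grid):
    """A nuisance-free synthetic run with strong planted loadings."""
    return generate_run({"AT": 0.6, "PM": 0.6}, grid=small_grid,
                        n_volumes=200, seed=7, nuisance_scale=0.0)


@pytest.fixture(scope="session")
def noisy_run(small_grid):
    """A synthetic run with the full nuisance structure."""
    return generate_run({"AT": 0.6, "PM": 0.6}, grid=small_grid,
                        n_volumes=200, seed=7, nuisance_scale=1.0)


@pytest.fixture(scope="session")
def default_cohort():
    table, truth = generate_cohort(CohortConfig(), seed=11)
    return table, truth


def make_run_from_array(data, tr_s=2.382, grid=None):
    data = np.asarray(data, dtype=float)
    grid = grid or VolumeGrid(data.shape[:3], (3.0, 3.0, 3.0))
    return BoldRun(data=data, grid=grid, tr_s=tr_s)
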