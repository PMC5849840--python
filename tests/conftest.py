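import numpy as np
import pytest

from olvpredict.grid_io import StructureMask, VoxelGrid
from olvpredict.synthetic import SyntheticCohortParams, generate_cohort, generate_patient


@pytest.fixture
def unit_grid():
    """10 x 10 x 1 grid, 1 mm spacing, voxel centers at 0.5 ... 9.5 mm."""
    return VoxelGrid((10, 10, 1), (1.0, 1.0, 1.0), (0.5, 0.5, 0.0))


@pytest.fixture
def cube_grid():
    return VoxelGrid((20, 20, 10), (1.0, 1.0, 2.0), (0.0, 0.0, 0.0))


def random_mask(grid: VoxelGrid, rng, p=0.08, name="m") -> StructureMask:
    return StructureMask(grid, rng.random(grid.shape) < p, name)


@pytest.fixture(scope="session")
def small_cohort():
    """Shared 30-plan synthetic cohort at default study conditions."""
    params = SyntheticCohortParams(n_patients=30, seed=7)
    bundles, cohort, truth = generate_cohort(params, return_bundles=False)
    return params, cohort, truth


@pytest.fixture(scope="session")
def one_plan():
    """One generated plan with its bundle, truth and records."""
    params = SyntheticCohortParams(n_patients=1, seed=11)
    rng = np.random.default_rng(params.seed)
    bundle, truths, records = generate_patient(params, rng, plan_id="P000")
    return params, bundle, truths, records
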