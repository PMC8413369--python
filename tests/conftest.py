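import numpy as np
import pytest

from fnkit import VoxelGrid, FunctionalVolume, Mask, ProbabilityMap, PriorsStore


@pytest.fixture
def unit_grid():
    """4x4x4 grid with 1 mm voxels and identity affine."""
    return VoxelGrid((4, 4, 4), np.eye(4))


@pytest.fixture
def mm2_grid():
    """10x10x10 grid with 2 mm voxels."""
    return VoxelGrid((10, 10, 10), np.diag([2.0, 2.0, 2.0, 1.0]))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_volume(grid, n_frames, rng, baseline=0.0):
    data = baseline + rng.normal(0.0, 1.0, grid.shape + (n_frames,))
    return FunctionalVolume(grid, data, tr=1.0)


def delta_priors(grid, mask):
    """Priors where each seed's map is the indicator of the seed itself."""
    entries = {}
    for v in mask.sorted_voxels():
        data = np.zeros(grid.shape)
        data[v] = 1.0
        entries[v] = ProbabilityMap(grid, data)
    return PriorsStore(grid, "voxel", entries)


def random_sparse_priors(grid, mask, rng, density=0.1):
    """Random non-negative sparse priors over the mask's seeds."""
    entries = {}
    for v in mask.sorted_voxels():
        data = rng.uniform(0.0, 1.0, grid.shape)
        data[rng.uniform(size=grid.shape) > density] = 0.0
        entries[v] = ProbabilityMap(grid, data)
    return PriorsStore(grid, "voxel", entries)
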