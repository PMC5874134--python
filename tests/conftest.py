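import numpy as np
import pytest
from hypothesis import settings

from roiconsist import Parcellation, SyntheticSpec, VoxelTimeSeriesSet

settings.register_profile("repeatable", derandomize=True, database=None)
settings.load_profile("repeatable")


def make_vts(data, grid_shape=None):
    """Wrap a (n_voxels, T) matrix laying voxels along the x axis."""
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if grid_shape is None:
        grid_shape = (n, 1, 1)
    coords = np.array([[i, 0, 0] for i in range(n)])
    return VoxelTimeSeriesSet(data=data, coords=coords, grid_shape=grid_shape)


def make_parcellation(labels_1d):
    """Parcellation matching make_vts's along-x voxel layout."""
    arr = np.asarray(labels_1d, dtype=np.int64).reshape(-1, 1, 1)
    return Parcellation(labels=arr)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_roi_spec():
    """Two correlated ROIs with known population statistics."""
    return SyntheticSpec(
        roi_sizes=(20, 30),
        n_timepoints=400,
        shared_fraction=(0.4, 0.25),
        global_fraction=0.1,
        latent_correlation=np.array([[1.0, 0.5], [0.5, 1.0]]),
        seed=7,
        grid_shape=(6, 6, 6),
    )
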