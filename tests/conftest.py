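import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from epiunwarp.geometry import FieldMap, ImageVolume, OppositePair
from epiunwarp.operators import diff_pe


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_smooth_pair(shape=(12, 10, 8), voxel_sizes=(1.0, 1.2, 0.9), seed=0):
    """A small random smooth opposite pair (not model-consistent; for
    operator and derivative checks only)."""
    rng = np.random.default_rng(seed)
    dp = gaussian_filter(rng.random(shape), 1.5)
    dm = gaussian_filter(rng.random(shape), 1.5)
    return OppositePair(ImageVolume(dp, voxel_sizes), ImageVolume(dm, voxel_sizes))


def random_feasible_field(shape=(12, 10, 8), voxel_sizes=(1.0, 1.2, 0.9),
                          max_slope=0.3, seed=1):
    """Smooth random staggered field with max |db/dpe| = max_slope."""
    rng = np.random.default_rng(seed)
    b = gaussian_filter(rng.standard_normal(shape[:2] + (shape[2] + 1,)), 2.0)
    b *= max_slope * voxel_sizes[2] / np.abs(diff_pe(b, voxel_sizes[2])).max()
    return FieldMap(b, voxel_sizes)


@pytest.fixture
def small_pair():
    return random_smooth_pair()


@pytest.fixture
def small_field():
    return random_feasible_field()
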