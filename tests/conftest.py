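import numpy as np
import pytest

from braindiff.synth import CohortSpec, ellipsoid_mask, make_atlas
from braindiff.types import VolumeMap


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_spec():
    """Seconds-scale cohort: 14^3 grid, 4 regions, 40 time points."""
    return CohortSpec(
        n_male=6,
        n_female=6,
        grid_shape=(14, 14, 14),
        n_regions=4,
        n_timepoints=40,
        seed=7,
    )


@pytest.fixture
def tiny_mask(tiny_spec):
    return ellipsoid_mask(tiny_spec.grid_shape)


@pytest.fixture
def tiny_atlas(tiny_spec, tiny_mask):
    return make_atlas(tiny_mask, tiny_spec.n_regions, seed=tiny_spec.seed)


def volume_from(values, mask=None, voxel_size_mm=3.0):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    return VolumeMap(values, mask, voxel_size_mm)


@pytest.fixture
def make_volume():
    return volume_from
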