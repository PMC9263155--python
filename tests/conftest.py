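import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from necrovol.geometry import ApplicatorAxis, OrientedSlice, VoxelGrid
from necrovol.phantom import PhantomSpec, VesselSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20220707)


@pytest.fixture
def axis():
    return ApplicatorAxis((32.0, 32.0))


@pytest.fixture
def small_grid():
    return VoxelGrid(np.zeros((64, 64, 64), dtype=np.uint8), (1.0, 1.0, 1.0))


@pytest.fixture
def small_spec():
    """Noiseless homogeneous phantom on a 64³ mm grid."""
    return PhantomSpec(
        grid_shape=(64, 64, 64),
        final_semi_axes=(13.0, 13.0, 20.0),
        thresholds=55.0,
        noise_sd=0.0,
        background_noise_sd=0.0,
    )


@pytest.fixture
def noisy_spec():
    """Phantom with the default ±1 °C noise and inhomogeneous thresholds."""
    return PhantomSpec(
        grid_shape=(64, 64, 64),
        final_semi_axes=(13.0, 13.0, 20.0),
        noise_sd=1.0,
        seed=3,
    )


@pytest.fixture
def vessel_spec():
    """Perfusion phantom: perpendicular tube clipping the necrosis boundary."""
    return PhantomSpec(
        grid_shape=(64, 64, 64),
        final_semi_axes=(13.0, 13.0, 20.0),
        vessel=VesselSpec(offset_xy=(9.0, 0.0), direction=(0.0, 1.0, 0.0)),
        noise_sd=1.0,
        seed=5,
    )


def make_mask_slice(angle_deg, mask, timestamp=0.0, u0=None, spacing=(1.0, 1.0)):
    return OrientedSlice(
        angle_deg=angle_deg,
        pixels=np.asarray(mask, dtype=np.uint8),
        in_plane_spacing=spacing,
        timestamp=timestamp,
        u0=u0,
    )
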