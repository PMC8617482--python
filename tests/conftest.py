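import numpy as np
import pytest

from qdmpipe import ParticleModel, SensorConfig
from qdmpipe.magnetostatics import AppliedField


@pytest.fixture()
def sensor():
    return SensorConfig()


@pytest.fixture()
def particle():
    """Representative iron organelle: 365 nm sphere, chi_v 0.053, packing 0.7."""
    return ParticleModel(center=(0.0, 0.0, 250e-9), diameter=365e-9, chi_v=0.053)


@pytest.fixture()
def applied_100g(sensor):
    return AppliedField.from_gauss(100.0, sensor.nv_axis)


# compact simulation settings used throughout: 20 binned pixels (~4.3 um)
# around the particle, 6x supersampling (36 nm raster)
SMALL_EXTENT = (4.32e-6, 4.32e-6)
SMALL_OVERSAMPLE = 6


@pytest.fixture()
def small_extent():
    return SMALL_EXTENT


def rng(seed=0):
    return np.random.default_rng(seed)
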