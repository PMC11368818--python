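import numpy as np
import pytest

from microvista.geometry import Spherocylinder
from microvista.psf import OpticsConfig, theoretical_psf


@pytest.fixture(scope="session")
def optics_515():
    return OpticsConfig(wavelength_um=0.515, na=1.45, pixel_size_um=0.02,
                        z_step_um=0.05)


@pytest.fixture(scope="session")
def small_tpsf():
    """A compact theoretical kernel shared across tests (33x81x81)."""
    return theoretical_psf(
        OpticsConfig(wavelength_um=0.55, na=1.4), (33, 81, 81),
        voxel_xy_um=0.04, voxel_z_um=0.1,
    )


@pytest.fixture
def typical_rod():
    return Spherocylinder(length_um=5.0, radius_um=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
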