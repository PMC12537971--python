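import numpy as np
import pytest

from axisim.optics import OpticalConfig, MirrorConfig, detection_psf


@pytest.fixture(scope="session")
def small_optics() -> OpticalConfig:
    """Small grid for fast speckle/PSF tests."""
    return OpticalConfig(grid_shape=(32, 48, 48))


@pytest.fixture(scope="session")
def small_det_psf(small_optics):
    return detection_psf(small_optics)


@pytest.fixture(scope="session")
def mirror() -> MirrorConfig:
    return MirrorConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
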