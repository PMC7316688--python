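import numpy as np
import pytest

from specalib import (
    CameraModel,
    ChromophoreTable,
    WavelengthGrid,
    band_illuminant,
    reference_illuminants,
)


@pytest.fixture(scope="session")
def grid():
    return WavelengthGrid.default()


@pytest.fixture(scope="session")
def camera():
    return CameraModel()


@pytest.fixture(scope="session")
def illuminants(grid):
    return reference_illuminants(grid)


@pytest.fixture(scope="session")
def band_truths(grid, camera, illuminants):
    """L1-normalized band-integrated illuminants: the calibration ground truth."""
    return {
        name: band_illuminant(spd.values, grid, camera).values
        for name, spd in illuminants.items()
    }


@pytest.fixture(scope="session")
def chromophores():
    return ChromophoreTable.default()


@pytest.fixture(scope="session")
def synthetic_chromophores():
    return ChromophoreTable.synthetic()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
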