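import numpy as np
import pytest

from vasoquant.imaging_io import RasterImage
from vasoquant.segmentation import VesselMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def bar_mask(shape=(60, 80), rows=slice(28, 33), cols=slice(10, 70)) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[rows, cols] = True
    return m


@pytest.fixture
def bar_vessel_mask():
    return VesselMask(mask=bar_mask(), pixel_size_um=5.0, method="truth")


@pytest.fixture
def random_raw_image(rng):
    return RasterImage(pixels=rng.random((32, 32)) * 100, pixel_size_um=20.0, stage="raw")
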