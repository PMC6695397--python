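import numpy as np
import pytest

from palmarea.grid import Raster
from palmarea.synth import (
    OPTICAL_BANDS,
    ClassSignature,
    default_signatures,
    generate_class_map,
)


@pytest.fixture(scope="session")
def signatures():
    return default_signatures()


@pytest.fixture(scope="session")
def noiseless_signatures():
    return default_signatures(optical_sd=0.0, sar_sd=(0.0, 0.0))


@pytest.fixture()
def small_truth():
    """A 64x64 six-class truth map with every class present."""
    return generate_class_map(64, 64, (0.15, 0.15, 0.30, 0.20, 0.12, 0.08),
                              patch_scale=6.0, seed=42, block=2)


@pytest.fixture()
def flat_raster():
    def make(value=0.0, shape=(8, 8), res=10.0, crs="EPSG:32647"):
        h, w = shape
        return Raster(np.full(shape, value, dtype=float),
                      (res, 0.0, 0.0, 0.0, -res, h * res), crs=crs)

    return make
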