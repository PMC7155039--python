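import datetime as dt

import numpy as np
import pytest

import endolakes as el
from endolakes.core import QA_VALID


@pytest.fixture(scope="session")
def library():
    return el.make_library(1)


@pytest.fixture(scope="session")
def snowmelt_bundle():
    """Noiseless, cloud-free snowmelt bundle (full 35-year record)."""
    return el.simulate_series(el.snowmelt_params(11))


@pytest.fixture(scope="session")
def monsoonal_bundle():
    return el.simulate_series(el.monsoonal_params(11))


def make_image(bands, qa=None, date=None, geometry=None):
    """Build a SpectralImage from a dict of 2-D arrays (all valid by default)."""
    bands = {k: np.asarray(v, dtype=float) for k, v in bands.items()}
    shape = next(iter(bands.values())).shape
    if qa is None:
        qa = np.full(shape, QA_VALID, dtype=np.uint8)
    return el.SpectralImage(
        bands=bands, qa=qa, date=date or dt.date(2000, 7, 1),
        geometry=geometry or el.GridGeometry(),
    )


@pytest.fixture
def uniform_image():
    """4x4 image, constant bands, all valid."""
    shape = (4, 4)
    return make_image(
        {
            "blue": np.full(shape, 0.10),
            "green": np.full(shape, 0.20),
            "red": np.full(shape, 0.15),
            "nir": np.full(shape, 0.30),
            "swir1": np.full(shape, 0.25),
            "swir2": np.full(shape, 0.20),
        }
    )
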