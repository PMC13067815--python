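import numpy as np
import pytest

from harescape.solar_clock import SiteLocation
from harescape import synthetic_data as syn

WISCONSIN = SiteLocation("wisconsin", 45.0, -91.0, -6.0)
ISLE_ROYALE = SiteLocation("isle_royale", 48.0, -89.0, -5.0)
YUKON = SiteLocation("yukon", 61.0, -138.0, -8.0)


@pytest.fixture(scope="session")
def wisconsin():
    return WISCONSIN


@pytest.fixture(scope="session")
def sites():
    return {"wisconsin": WISCONSIN, "isle_royale": ISLE_ROYALE,
            "yukon": YUKON}


@pytest.fixture(scope="session")
def small_stack():
    return syn.gen_landscape(12345, (64, 64))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
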