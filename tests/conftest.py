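import numpy as np
import pytest

from gazenum.stimuli import ScreenGeometry, make_canonical, make_item_battery


@pytest.fixture(scope="session")
def geometry() -> ScreenGeometry:
    return ScreenGeometry()


@pytest.fixture(scope="session")
def dice5(geometry):
    return make_canonical(5, geometry)


@pytest.fixture(scope="session")
def battery():
    return make_item_battery(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
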