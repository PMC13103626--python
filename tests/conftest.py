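import numpy as np
import pytest

from beehex.spectra import default_grid
from beehex.synth import default_config
from beehex.vision import green_leaf_background, make_receptor_templates, solar_irradiance


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def templates():
    return make_receptor_templates()


@pytest.fixture(scope="session")
def illuminant(grid):
    return solar_irradiance(grid)


@pytest.fixture(scope="session")
def background(grid):
    return green_leaf_background(grid)


@pytest.fixture()
def config():
    return default_config(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1)
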