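import numpy as np
import pytest

from elbawood.config import default_config
from elbawood.synthetic import elba_catalogue


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def elba_sites():
    return elba_catalogue()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
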