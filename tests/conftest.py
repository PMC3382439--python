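import numpy as np
import pytest

import evoguide as eg


@pytest.fixture(scope="session")
def default_envs():
    return eg.default_environments()


@pytest.fixture(scope="session")
def params():
    return eg.CellParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
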