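import numpy as np
import pytest

from neurodic import make_hh, make_stg


@pytest.fixture(scope="session")
def stg():
    return make_stg()


@pytest.fixture(scope="session")
def hh():
    return make_hh()


@pytest.fixture()
def rng():
    return np.random.default_rng(20211)
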