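import numpy as np
import pytest

from idpensemble import fixtures as fx
from idpensemble import so3


@pytest.fixture(scope="session")
def igso3_table():
    """Shared IGSO3 table (one build per test session)."""
    return so3.default_table()


@pytest.fixture(scope="session")
def helix20():
    return fx.ideal_helix(20, sequence="A" * 20)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
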