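import numpy as np
import pytest

from wrkykit import fixtures


@pytest.fixture(scope="session")
def panel():
    return fixtures.default_panel()


@pytest.fixture(scope="session")
def table1():
    return fixtures.load_table1()


@pytest.fixture(scope="session")
def table2():
    return fixtures.load_table2()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
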