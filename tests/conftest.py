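import numpy as np
import pytest

from apopath.panel import load_packaged_panel, load_table1_fixture


@pytest.fixture(scope="session")
def panel():
    return load_packaged_panel()


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
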