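import numpy as np
import pytest

from nrminer.config import RunConfig
from nrminer.datasets import build_reference_panel, load_junction_catalog, load_pbox_catalog


@pytest.fixture(scope="session")
def config():
    return RunConfig()

@pytest.fixture(scope="session")
def catalog():
    return load_pbox_catalog()


@pytest.fixture(scope="session")
def panel():
    return build_reference_panel()


@pytest.fixture(scope="session")
def junctions():
    return load_junction_catalog()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
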