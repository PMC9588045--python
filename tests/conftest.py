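import numpy as np
import pytest

from lamina.design import make_block_design


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def design_3t():
    return make_block_design("3T-BOLD", seed=0)


@pytest.fixture(scope="session")
def design_7t():
    return make_block_design("7T-BOLD", seed=0)


@pytest.fixture(scope="session")
def design_vaso():
    return make_block_design("7T-VASO", seed=0)
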