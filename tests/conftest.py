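import numpy as np
import pytest

from hypogeo import DesignConfig, generate_design


@pytest.fixture(scope="session")
def small_design():
    """A 12-grid design: 48 samples, cheap enough for per-test reuse."""
    config = DesignConfig(n_grids=12, seed=101)
    return config, generate_design(config)


@pytest.fixture(scope="session")
def full_design():
    """The default 162-grid / 648-sample survey design."""
    config = DesignConfig(seed=202)
    return config, generate_design(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
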