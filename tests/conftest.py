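import numpy as np
import pytest

from isocurl.synthetic import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cfg():
    """A compact error-free configuration used by recovery tests."""
    return SimConfig(seed=7, n_genes=25, error_rate=0.0)
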