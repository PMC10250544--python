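import numpy as np
import pytest

from nichekit.synthetic import LandscapeSpec, make_landscape


@pytest.fixture(scope="session")
def small_stack():
    """40x40, 3-layer autocorrelated landscape shared across tests."""
    return make_landscape(LandscapeSpec(40, 40, 1.0, 3, 4.0, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
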