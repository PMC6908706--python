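import numpy as np
import pytest

import entrainkit as ek


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    """A reproducible 6-bout coupled dyad at generator defaults."""
    return ek.simulate_dyad(config=ek.SimConfig(n_bouts=6, seed=101))


@pytest.fixture
def default_dataset():
    """The defaults study: 28 bouts at the generator's default parameters."""
    return ek.simulate_dyad(config=ek.SimConfig(n_bouts=28, seed=202))
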