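import numpy as np
import pytest

import barrelmap as bm


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def field():
    return bm.make_whisker_field(5, 5, 1.0)


@pytest.fixture
def small_arch():
    """A miniature sheet (25x25 neurons) that keeps every invariant testable."""
    return bm.Architecture(supra_size=5)


@pytest.fixture
def small_state(small_arch):
    return bm.init_network(small_arch, np.random.default_rng(42))
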