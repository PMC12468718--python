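import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_uint8():
    """Factory for seeded random 8-bit images."""
    def make(h, w, seed=0):
        return np.random.default_rng(seed).integers(0, 256, size=(h, w)).astype(np.uint8)

    return make
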