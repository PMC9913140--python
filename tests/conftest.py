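import numpy as np
import pytest


class ForcedRng:
    """Generator stand-in whose uniform draws return a fixed value."""

    def __init__(self, value: float, integer: int = 0):
        self.value = value
        self.integer = integer

    def random(self, size=None):
        if size is None:
            return self.value
        return np.full(size, self.value)

    def integers(self, *args, **kwargs):
        return self.integer


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def forced_rng():
    return ForcedRng
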