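import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


class FakeUniformRng:
    """Generator stub returning a queued sequence of uniform draws."""

    def __init__(self, values):
        self._values = np.asarray(values, dtype=float).ravel()
        self._i = 0

    def random(self, size=None):
        n = int(np.prod(size)) if size is not None else 1
        out = self._values[self._i : self._i + n]
        self._i += n
        if size is None:
            return float(out[0])
        return out.reshape(size)


@pytest.fixture
def fake_rng():
    return FakeUniformRng
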