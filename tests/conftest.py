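import numpy as np
import pytest


def rand_mask(rng: np.random.Generator, shape, p: float = 0.3) -> np.ndarray:
    return rng.random(shape) < p


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
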