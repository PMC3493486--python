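import numpy as np
import pytest

from ctcsim import build_condition, generate_batch, hann_window


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def async_batches():
    """Small windowed train/test pair, asynchronous condition, shared by
    fit-based tests (sized for speed, not accuracy)."""
    cond = build_condition("asynchronous")
    train = hann_window(generate_batch(cond, 4.0, 600, 101))
    test = hann_window(generate_batch(cond, 4.0, 600, 102))
    return cond, train, test
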