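import numpy as np
import pytest

from bootair import BootPairSignal, ProcessedSignal


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_pair(rng):
    """A random signed two-channel signal at 54 Hz."""
    n = 500
    return BootPairSignal(
        sample_rate_hz=54.0,
        t0_s=0.0,
        left_acc_y=rng.normal(0.0, 10.0, n),
        right_acc_y=rng.normal(0.0, 10.0, n),
    )


def make_fused(values, rate=54.0, t0=0.0):
    return ProcessedSignal(sample_rate_hz=rate, t0_s=t0, values=values, stage="fused")


def make_smoothed(values, window=3, rate=54.0, t0=0.0):
    return ProcessedSignal(
        sample_rate_hz=rate, t0_s=t0, values=values, stage="smoothed", window_samples=window
    )
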