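import numpy as np
import pytest

from kinemetrics import minjerk
from kinemetrics.preprocess import AccelRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def minjerk_pulse_recording(
    distance=0.5, duration=1.0, rate_hz=100.0, pad_s=2.0, axis=0
):
    """A recording containing a single minimum-jerk acceleration pulse."""
    n_pad = int(pad_s * rate_hz)
    t = np.arange(int(duration * rate_hz) + 1) / rate_hz
    a = minjerk.acceleration(t, distance, duration)
    samples = np.zeros((2 * n_pad + len(a), 3))
    samples[n_pad : n_pad + len(a), axis] = a
    return AccelRecording(samples=samples, rate_hz=rate_hz), n_pad, len(a)


@pytest.fixture
def pulse_recording():
    return minjerk_pulse_recording()
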