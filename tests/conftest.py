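import numpy as np
import pytest
from hypothesis import settings

from fallsense import RawRecording, UniformClip
from fallsense.signal_io import CLIP_SAMPLES, RATE

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def make_clip(rng):
    """Factory for random clips: standard-normal samples around a rest posture."""

    def _make(seed=None, scale=1.0, offset=(9.8, 0.0, 0.0)):
        r = np.random.default_rng(seed) if seed is not None else rng
        samples = np.asarray(offset) + scale * r.normal(size=(CLIP_SAMPLES, 3))
        return UniformClip(samples, center_time=5.0)

    return _make


@pytest.fixture
def rest_clip(rng):
    """Phone at rest on an upright subject: x ≈ 9.8, y ≈ z ≈ 0, small noise."""
    samples = np.array([9.8, 0.0, 0.0]) + rng.normal(0, 0.05, size=(CLIP_SAMPLES, 3))
    return UniformClip(samples, center_time=5.0)


@pytest.fixture
def uniform_recording():
    """A quiet 60 s uniform 20 Hz recording."""

    def _make(duration=60.0, value=(9.8, 0.0, 0.0)):
        n = int(duration * RATE) + 1
        t = np.arange(n) / RATE
        samples = np.tile(np.asarray(value, dtype=float), (n, 1))
        return RawRecording(t, samples)

    return _make
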