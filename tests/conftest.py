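import numpy as np
import pytest

from twaves.axes import AxisStack
from twaves.synth import NoiseSpec, WaveSpec, make_noise, make_plane_wave


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def forward_segment():
    """Noiseless 7 x 500 forward plane wave at 10 Hz (1 kHz sampling)."""
    return make_plane_wave(WaveSpec(10.0, np.pi / 7), 7, 500, 1000.0)


def make_stack(data, fs=1000.0, tmin=0.0, name="midline"):
    data = np.asarray(data, dtype=float)
    n = data.shape[-1]
    times = tmin + np.arange(n) / fs
    return AxisStack(name, data, fs, times)


@pytest.fixture
def noisy_forward_trials(rng):
    """200 single-trial 7 x 500 stacks: forward wave in 1/f noise."""
    n_trials, n_samples, fs = 200, 500, 1000.0
    out = np.empty((n_trials, 7, n_samples))
    for i in range(n_trials):
        phase0 = rng.uniform(0, 2 * np.pi)
        wave = make_plane_wave(WaveSpec(10.0, np.pi / 7, 1.0), 7, n_samples, fs,
                               phase0=phase0)
        noise = make_noise(NoiseSpec(1.0, 1.0), 7, n_samples, fs, rng)
        out[i] = wave + noise
    return out
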