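import numpy as np
import pytest

from ampdyn import MotionTrace, TimeSeriesImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_sinusoid_image(freqs_hz, amps, tr_s=2.0, n_timepoints=160, phase=0.0,
                        grid_shape=(2, 2, 1), baseline=0.0):
    """A tiny image where every voxel carries the same sum of sinusoids."""
    t = np.arange(n_timepoints) * tr_s
    sig = baseline + sum(
        a * np.sin(2 * np.pi * f * t + phase) for f, a in zip(freqs_hz, amps)
    )
    data = np.broadcast_to(sig, grid_shape + (n_timepoints,)).copy()
    return TimeSeriesImage(data, (3.0, 3.0, 3.0), tr_s)


def make_noise_image(rng, grid_shape=(4, 4, 3), n_timepoints=120, tr_s=2.0, sd=1.0):
    data = sd * rng.standard_normal(grid_shape + (n_timepoints,))
    return TimeSeriesImage(data, (3.0, 3.0, 3.0), tr_s)


def zero_motion(n_timepoints):
    return MotionTrace(np.zeros((n_timepoints, 6)))


@pytest.fixture
def sinusoid_image():
    return make_sinusoid_image


@pytest.fixture
def noise_image():
    return make_noise_image
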