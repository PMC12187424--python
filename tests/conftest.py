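import numpy as np
import pytest

from jvpradar import (
    DisplacementTrajectory,
    RadarConfig,
    SceneSpec,
    simulate_frames,
)


@pytest.fixture(scope="session")
def config():
    return RadarConfig()


@pytest.fixture
def noise_free_scene():
    return SceneSpec(noise_snr_db=None)


@pytest.fixture
def make_sine_cube(config):
    """Simulate a cube for a sinusoidally vibrating target."""

    def _make(amplitude=100e-6, freq=1.5, duration=10.0, scene=None, seed=0):
        scene = scene or SceneSpec(noise_snr_db=None)
        n = int(round(duration * config.frame_rate))
        t = np.arange(n) / config.frame_rate
        traj = DisplacementTrajectory(config.frame_rate,
                                      amplitude * np.sin(2 * np.pi * freq * t))
        return simulate_frames(config, traj, scene, seed=seed), traj

    return _make


def bin_centered_range(config, m):
    """Target range whose beat frequency falls exactly on fast-time bin m."""
    df = config.adc_rate / config.n_samples_per_chirp
    from jvpradar import SPEED_OF_LIGHT
    return m * df * SPEED_OF_LIGHT / (2.0 * config.chirp_slope)
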