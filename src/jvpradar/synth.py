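"""Synthetic displacement trajectories and FMCW echo simulation.

The generators here stand in for hardware: a jugular-venous-pulse (JVP)
surface motion, the two-tone speaker-plate validation signal, a finger
photoplethysmogram (PPG), and the FMCW receiver that observes a moving
skin patch through a real-valued (I-only) mixer across a half-wavelength
antenna pair.

The JVP trajectory is built per cardiac cycle from signed Gaussian bumps
— positive a, c and v waves, negative x and y descents — and then
band-limited to harmonics below 4 Hz, reflecting the physiological
observation that essentially all JVP waveform content lies below 4 Hz.
An arterial sinusoid at the cardiac fundamental, a respiratory sinusoid
and white measurement noise are superposed on top of the venous motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .core import SPEED_OF_LIGHT, DisplacementTrajectory, RadarConfig, RadarDataCube
from .errors import InvalidArgumentError

__all__ = [
    "JVPWaveformSpec",
    "SpeakerSignalSpec",
    "SceneSpec",
    "synth_jvp_trajectory",
    "synth_speaker_trajectory",
    "synth_ppg",
    "simulate_frames",
]

#: Band edge below which JVP waveform content is kept (Hz).
JVP_BAND_EDGE_HZ = 4.0

#: PPG device sampling rate (Hz).
PPG_RATE_HZ = 273.1


@dataclass(frozen=True)
class JVPWaveformSpec:
    """Morphology and superposed components of the synthetic jugular pulse.

    Venous amplitudes are surface displacements in metres; wave centres
    and widths are fractions of the cardiac cycle.  ``posture_factor``
    scales the venous components only, emulating the posture dependence
    of jugular distension (supine > reclined > upright).
    """

    cardiac_rate: float = 1.13
    wave_amplitudes: tuple = (150e-6, 60e-6, 120e-6)   # a, c, v
    wave_centers: tuple = (0.10, 0.25, 0.60)           # a, c, v
    wave_widths: tuple = (0.05, 0.04, 0.07)            # a, c, v
    descent_depths: tuple = (100e-6, 130e-6)           # x, y
    descent_centers: tuple = (0.18, 0.75)              # x, y
    descent_widths: tuple = (0.05, 0.08)               # x, y
    arterial_amplitude: float = 80e-6
    respiratory_rate: float = 0.25
    respiratory_amplitude: float = 200e-6
    noise_sd: float = 5e-6
    posture_factor: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.cardiac_rate < JVP_BAND_EDGE_HZ):
            raise InvalidArgumentError("cardiac_rate must lie in (0, 4) Hz")
        for amp in (*self.wave_amplitudes, *self.descent_depths,
                    self.arterial_amplitude, self.respiratory_amplitude):
            if amp < 0:
                raise InvalidArgumentError("amplitudes must be non-negative")
        a, c, v = self.wave_centers
        if not (a < c < v):
            raise InvalidArgumentError("wave centers must be ordered a < c < v")
        if self.noise_sd < 0 or self.posture_factor < 0:
            raise InvalidArgumentError("noise_sd and posture_factor must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "JVPWaveformSpec":
        d = {k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()}
        return cls(**d)


@dataclass(frozen=True)
class SpeakerSignalSpec:
    """Two-tone plate displacement s(t) = a1 cos(2π f1 t) + a2 cos(2π f2 t)."""

    a1: float = 50e-6
    a2: float = 50e-6
    f1: float = 50.0
    f2: float = 54.0

    def __post_init__(self) -> None:
        if self.f1 == self.f2:
            raise InvalidArgumentError("f1 and f2 must differ")
        if self.f1 <= 0 or self.f2 <= 0:
            raise InvalidArgumentError("tone frequencies must be positive")


@dataclass(frozen=True)
class SceneSpec:
    """Geometry and noise of the simulated measurement scene.

    The default 5 cm standoff keeps the skin echo clear of the DC bin
    (one range bin spans about 28 mm at the full 5.5 GHz sweep); a very
    close target would merge with the DC component of the real-valued IF
    signal.  ``noise_snr_db=None`` means noise-free.  ``weak_channel_gain``
    scales the echo amplitude on antennas beyond the primary pair
    (indices >= 2), providing a low-SNR channel for antenna-selection
    tests.
    """

    base_range: float = 0.05
    doa: float = 0.0                      # degrees
    reflection_amplitude: float = 1.0
    noise_snr_db: float | None = 30.0
    weak_channel_gain: float = 0.25

    def __post_init__(self) -> None:
        if self.base_range <= 0:
            raise InvalidArgumentError("base_range must be positive")
        if not (-90.0 < self.doa < 90.0):
            raise InvalidArgumentError("doa must lie strictly inside (-90, 90) degrees")
        if self.reflection_amplitude <= 0:
            raise InvalidArgumentError("reflection_amplitude must be positive")
        if not (0 <= self.weak_channel_gain):
            raise InvalidArgumentError("weak_channel_gain must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        return cls(**d)


# --------------------------------------------------------------------------
# trajectory generators
# --------------------------------------------------------------------------

def _venous_cycle_coefficients(spec: JVPWaveformSpec, n_harmonics: int,
                               oversample: int = 4096) -> np.ndarray:
    """Complex Fourier coefficients (k = 0..n_harmonics) of one venous cycle.

    The cycle is a sum of signed periodic Gaussian bumps evaluated on a
    dense phase grid; coefficients above ``n_harmonics`` are discarded,
    which band-limits the waveform exactly.
    """
    u = np.arange(oversample) / oversample
    cycle = np.zeros(oversample)

    def bump(center, width, amp, sign):
        # wrap-around distance on the unit circle of cycle phase
        d = u - center
        d -= np.round(d)
        return sign * amp * np.exp(-0.5 * (d / width) ** 2)

    for amp, ctr, wid in zip(spec.wave_amplitudes, spec.wave_centers, spec.wave_widths):
        cycle += bump(ctr, wid, amp, +1.0)
    for dep, ctr, wid in zip(spec.descent_depths, spec.descent_centers, spec.descent_widths):
        cycle += bump(ctr, wid, dep, -1.0)
    cycle *= spec.posture_factor

    coeffs = np.fft.rfft(cycle) / oversample
    return coeffs[: n_harmonics + 1]


def venous_waveform(spec: JVPWaveformSpec, t: np.ndarray) -> np.ndarray:
    """Band-limited periodic venous displacement evaluated at times ``t``."""
    n_harm = int(np.floor((JVP_BAND_EDGE_HZ - 1e-12) / spec.cardiac_rate))
    coeffs = _venous_cycle_coefficients(spec, n_harm)
    phase = spec.cardiac_rate * t
    out = np.full_like(np.asarray(t, dtype=float), coeffs[0].real)
    for k in range(1, len(coeffs)):
        out += 2.0 * (coeffs[k].real * np.cos(2 * np.pi * k * phase)
                      - coeffs[k].imag * np.sin(2 * np.pi * k * phase))
    return out


def synth_jvp_trajectory(spec: JVPWaveformSpec, duration: float, rate: float,
                         seed: int = 0) -> DisplacementTrajectory:
    """Synthesize a jugular-pulse skin-displacement trajectory.

    Parameters
    ----------
    spec : JVPWaveformSpec
        Morphology and component amplitudes.
    duration : float
        Record length in seconds.
    rate : float
        Sample rate in Hz (the radar frame rate when feeding the simulator);
        must exceed twice the cardiac rate.
    seed : int
        Seed for the additive white-noise component.
    """
    if duration <= 0 or rate <= 0:
        raise InvalidArgumentError("duration and rate must be positive")
    if rate <= 2 * spec.cardiac_rate:
        raise InvalidArgumentError("rate must exceed twice the cardiac rate")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    rng = np.random.default_rng(seed)

    values = venous_waveform(spec, t)
    values += spec.arterial_amplitude * np.sin(2 * np.pi * spec.cardiac_rate * t)
    values += spec.respiratory_amplitude * np.sin(2 * np.pi * spec.respiratory_rate * t)
    if spec.noise_sd > 0:
        values += spec.noise_sd * rng.standard_normal(n)
    return DisplacementTrajectory(rate, values, "synthetic JVP skin displacement")


def synth_speaker_trajectory(spec: SpeakerSignalSpec, duration: float,
                             rate: float) -> DisplacementTrajectory:
    """Two-tone speaker-plate displacement used for sensitivity validation."""
    if duration <= 0 or rate <= 0:
        raise InvalidArgumentError("duration and rate must be positive")
    if rate <= 2 * max(spec.f1, spec.f2):
        raise InvalidArgumentError("rate must exceed twice the highest tone")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    values = spec.a1 * np.cos(2 * np.pi * spec.f1 * t) + spec.a2 * np.cos(2 * np.pi * spec.f2 * t)
    return DisplacementTrajectory(rate, values, "two-tone speaker plate")


def synth_ppg(cardiac_rate: float, duration: float, rate: float = PPG_RATE_HZ,
              seed: int = 0, noise_sd: float = 0.02) -> DisplacementTrajectory:
    """Synthesize a finger-PPG pulse train (arbitrary amplitude units).

    Each cycle is a systolic Gaussian peak followed by a smaller dicrotic
    bump.  Phases are placed so the JVP a wave precedes the systolic peak
    and the v wave sits near the dicrotic notch, matching the canonical
    JVP/PPG alignment within the cardiac cycle.
    """
    if duration <= 0 or rate <= 0 or cardiac_rate <= 0:
        raise InvalidArgumentError("duration, rate and cardiac_rate must be positive")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    u = cardiac_rate * t
    u -= np.floor(u)

    def bump(center, width, amp):
        d = u - center
        d -= np.round(d)
        return amp * np.exp(-0.5 * (d / width) ** 2)

    values = bump(0.18, 0.09, 1.0) + bump(0.55, 0.11, 0.30)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + noise_sd * rng.standard_normal(n)
    return DisplacementTrajectory(rate, values, "synthetic finger PPG")


# --------------------------------------------------------------------------
# FMCW echo simulation
# --------------------------------------------------------------------------

def simulate_frames(config: RadarConfig, trajectory: DisplacementTrajectory,
                    scene: SceneSpec, seed: int = 0,
                    n_frames: int | None = None) -> RadarDataCube:
    """Simulate the raw data cube an I-only FMCW receiver would record.

    For frame ``t``, antenna ``a`` and fast-time sample ``n`` the IF value is

        A_a · cos(2π f_b n / f_adc + 4π R(t)/λ + φ_a) + noise,

    with target range ``R(t) = base_range + trajectory(t)``, beat frequency
    ``f_b = 2 R(t) (B/T_c)/c`` and inter-antenna phase
    ``φ_a = −2π · spacing · a · sin(doa)`` (delay convention matching the
    steering vector used by the beamformer).  The receiver has no
    quadrature mixer, so the stored samples are real; complex I/Q data
    arises only through the fast-time FFT downstream.  All chirps within a
    frame observe the same range (displacement is sampled at the frame
    rate) and differ only in their noise.  The cube is scaled into the
    normalized ADC range [-1, 1].
    """
    if trajectory.sample_rate != config.frame_rate:
        raise InvalidArgumentError(
            f"trajectory rate {trajectory.sample_rate} Hz must equal the frame rate "
            f"{config.frame_rate} Hz"
        )
    if n_frames is None:
        n_frames = len(trajectory.values)
    if n_frames > len(trajectory.values):
        raise InvalidArgumentError(
            f"trajectory has {len(trajectory.values)} samples; {n_frames} frames requested"
        )

    lam = config.wavelength
    r = scene.base_range + trajectory.values[:n_frames]          # (F,)
    f_beat = 2.0 * r * config.chirp_slope / SPEED_OF_LIGHT       # (F,)
    n_fast = np.arange(config.n_samples_per_chirp)

    # fast-time argument common to all antennas/chirps: (F, S)
    arg = (2 * np.pi * f_beat[:, None] * n_fast[None, :] / config.adc_rate
           + 4 * np.pi * r[:, None] / lam)

    amps = np.full(config.n_rx, scene.reflection_amplitude)
    amps[2:] *= scene.weak_channel_gain
    phis = (-2 * np.pi * config.rx_spacing_wavelengths
            * np.arange(config.n_rx) * np.sin(np.radians(scene.doa)))

    # (F, A, S) -> broadcast over chirps
    sig = amps[None, :, None] * np.cos(arg[:, None, :] + phis[None, :, None])
    cube = np.repeat(sig[:, :, None, :], config.n_chirps_per_frame, axis=2)

    if scene.noise_snr_db is not None:
        rng = np.random.default_rng(seed)
        sigma = (scene.reflection_amplitude / np.sqrt(2.0)
                 / 10.0 ** (scene.noise_snr_db / 20.0))
        cube = cube + sigma * rng.standard_normal(cube.shape)

    peak = np.max(np.abs(cube))
    if peak > 0:
        cube = cube / peak
    return RadarDataCube(cube, config)
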