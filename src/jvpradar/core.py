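"""Core data containers shared across the pipeline.

An FMCW radar transmits linear frequency chirps; the received echo is
mixed down to an intermediate-frequency (IF) signal whose beat frequency
encodes target range and whose phase tracks sub-wavelength target motion.
Samples within a chirp are "fast time" (range axis); successive frames
are "slow time" (motion axis, sampled at the frame rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import InvalidArgumentError, ShapeError

SPEED_OF_LIGHT = 299_792_458.0  # m/s

# Upper edge of the device's ISM band in Hz.
_DEVICE_BAND_TOP = 63.5e9


@dataclass(frozen=True)
class RadarConfig:
    """Chirp/frame geometry and RF band of the FMCW sensor.

    Defaults follow the configuration found optimal for jugular-pulse
    visibility on a 58-63.5 GHz sensor: 128 samples/chirp at 1 MHz ADC
    rate, 8 chirps/frame, 250 Hz frame rate, full 5.5 GHz sweep.
    """

    n_rx: int = 3
    n_chirps_per_frame: int = 8
    n_samples_per_chirp: int = 128
    adc_rate: float = 1.0e6
    chirp_duration: float = 132.987e-6
    frame_rate: float = 250.0
    band_start: float = 58e9
    bandwidth: float = 5.5e9
    rx_spacing_wavelengths: float = 0.5

    def __post_init__(self) -> None:
        if self.n_rx < 1 or self.n_chirps_per_frame < 1 or self.n_samples_per_chirp < 2:
            raise InvalidArgumentError("antenna/chirp/sample counts must be positive")
        if self.n_samples_per_chirp / self.adc_rate > self.chirp_duration * (1 + 1e-9):
            raise InvalidArgumentError(
                "n_samples_per_chirp / adc_rate exceeds chirp_duration: "
                "samples do not fit inside one chirp"
            )
        if self.n_chirps_per_frame * self.chirp_duration > 1.0 / self.frame_rate:
            raise InvalidArgumentError("chirps do not fit inside one frame period")
        if self.bandwidth <= 0:
            raise InvalidArgumentError("bandwidth must be positive")
        if self.band_start + self.bandwidth > _DEVICE_BAND_TOP + 1e-3:
            raise InvalidArgumentError(
                f"band_start + bandwidth exceeds the device band top ({_DEVICE_BAND_TOP:g} Hz)"
            )
        if self.rx_spacing_wavelengths <= 0:
            raise InvalidArgumentError("rx_spacing_wavelengths must be positive")

    # ---- derived quantities -------------------------------------------------

    @property
    def carrier_frequency(self) -> float:
        """Band-centre frequency used for phase-to-displacement scaling (Hz)."""
        return self.band_start + self.bandwidth / 2.0

    @property
    def wavelength(self) -> float:
        """Carrier wavelength at band centre (m)."""
        return SPEED_OF_LIGHT / self.carrier_frequency

    @property
    def chirp_slope(self) -> float:
        """Sweep rate bandwidth / chirp_duration (Hz/s)."""
        return self.bandwidth / self.chirp_duration

    def beat_frequency(self, target_range: float) -> float:
        """IF beat frequency for a target at the given range (Hz):
        f_b = 2 R B / (c T_c)."""
        return 2.0 * target_range * self.chirp_slope / SPEED_OF_LIGHT

    def range_to_bin(self, target_range: float) -> float:
        """Fractional fast-time FFT bin index for a target range."""
        return self.beat_frequency(target_range) * self.n_samples_per_chirp / self.adc_rate

    @property
    def range_bin_spacing(self) -> float:
        """Range separation between adjacent fast-time FFT bins (m).

        Slightly wider than c/(2B) because only the first
        n_samples_per_chirp/adc_rate of each sweep is sampled.
        """
        df = self.adc_rate / self.n_samples_per_chirp
        return df * SPEED_OF_LIGHT / (2.0 * self.chirp_slope)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RadarConfig":
        return cls(**d)


@dataclass
class RadarDataCube:
    """Raw real-valued ADC samples indexed (frame, antenna, chirp, sample)."""

    values: np.ndarray
    config: RadarConfig

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 4:
            raise ShapeError(f"cube must be 4-D (frame, antenna, chirp, sample); got {v.ndim}-D")
        expected = (self.config.n_rx, self.config.n_chirps_per_frame, self.config.n_samples_per_chirp)
        if v.shape[1:] != expected:
            raise ShapeError(
                f"cube trailing shape {v.shape[1:]} does not match config "
                f"(n_rx, n_chirps, n_samples) = {expected}"
            )
        if not np.all(np.isfinite(v)):
            raise InvalidArgumentError("cube contains non-finite values")
        if np.max(np.abs(v), initial=0.0) > 1.0 + 1e-9:
            raise InvalidArgumentError("cube values exceed the normalized ADC range [-1, 1]")
        self.values = v

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class DisplacementTrajectory:
    """A target-surface displacement time series in metres at a fixed rate."""

    sample_rate: float
    values: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if self.sample_rate <= 0:
            raise InvalidArgumentError("sample_rate must be positive")
        if v.ndim != 1:
            raise InvalidArgumentError("trajectory values must be 1-D")
        if not np.all(np.isfinite(v)):
            raise InvalidArgumentError("trajectory contains non-finite values")
        self.values = v

    @property
    def duration(self) -> float:
        return len(self.values) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.sample_rate


@dataclass
class IQSeries:
    """Complex slow-time stream per antenna at a single range bin.

    ``values`` has shape (n_antennas, n_frames); ``sample_rate`` equals
    the radar frame rate; ``source_bin`` records the fast-time bin the
    stream was taken from (never the DC bin).
    """

    values: np.ndarray
    sample_rate: float
    source_bin: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=complex)
        if v.ndim == 1:
            v = v[None, :]
        if v.ndim != 2:
            raise InvalidArgumentError("IQ values must be (antenna, frame)")
        if self.source_bin < 1:
            raise InvalidArgumentError("source_bin must be >= 1 (DC bin excluded)")
        self.values = v

    @property
    def n_antennas(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class PhaseSeries:
    """Unwrapped instantaneous phase of the beamformed I/Q stream (rad)."""

    values: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class DisplacementSignal:
    """Skin displacement per frame (m), zero mean after reconstruction."""

    values: np.ndarray
    sample_rate: float
    wavelength: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise InvalidArgumentError("displacement contains non-finite values")
        self.values = v

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.sample_rate
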