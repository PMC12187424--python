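"""Range processing: raw cube → per-antenna slow-time I/Q at the skin bin.

The fast-time FFT of each real-valued chirp yields a complex range
profile; the first spectral spike above the noise floor is taken as the
skin echo (the closest reflector), and that bin's complex value per
frame forms the slow-time I/Q stream whose phase tracks skin motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import IQSeries, RadarConfig, RadarDataCube
from .errors import (
    ConfigurationError,
    DetectionError,
    InvalidArgumentError,
    ShapeError,
)

__all__ = [
    "RangeProfile",
    "AntennaSelection",
    "reshape_raw",
    "range_fft",
    "select_target_bin",
    "extract_iq",
    "select_antennas",
]

#: Displacement band used for the antenna SNR criterion (Hz).
DISPLACEMENT_BAND_HZ = (0.75, 4.0)


@dataclass
class RangeProfile:
    """Complex fast-time spectra indexed (frame, antenna, bin), bins 0..Ns/2."""

    values: np.ndarray
    config: RadarConfig
    chirp_averaged: bool

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=complex)
        expected_bins = self.config.n_samples_per_chirp // 2 + 1
        if v.ndim != 3 or v.shape[1] != self.config.n_rx or v.shape[2] != expected_bins:
            raise ShapeError(
                f"range profile must be (frames, {self.config.n_rx}, {expected_bins}); "
                f"got {v.shape}"
            )
        self.values = v

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[2]


@dataclass
class AntennaSelection:
    """The two antennas chosen for beamforming and all per-antenna SNRs (dB)."""

    pair: tuple
    snr_db: np.ndarray

    def __post_init__(self) -> None:
        i, j = self.pair
        if i == j:
            raise InvalidArgumentError("selected antennas must be distinct")


def reshape_raw(flat_samples: np.ndarray, config: RadarConfig) -> RadarDataCube:
    """Reshape a flat normalized ADC vector into a (frame, antenna, chirp,
    sample) cube without altering any value."""
    v = np.asarray(flat_samples, dtype=float).ravel()
    per_frame = config.n_rx * config.n_chirps_per_frame * config.n_samples_per_chirp
    if len(v) == 0 or len(v) % per_frame != 0:
        raise ShapeError(
            f"raw vector length {len(v)} is not a multiple of "
            f"n_rx × n_chirps × n_samples = {config.n_rx} × "
            f"{config.n_chirps_per_frame} × {config.n_samples_per_chirp} = {per_frame}"
        )
    n_frames = len(v) // per_frame
    cube = v.reshape(n_frames, config.n_rx, config.n_chirps_per_frame,
                     config.n_samples_per_chirp)
    return RadarDataCube(cube, config)


def range_fft(cube: RadarDataCube, window: str | None = None,
              average_chirps: bool = False) -> RangeProfile:
    """Fast-time FFT of every chirp, with per-chirp mean removal.

    The per-chirp mean is removed before the transform to suppress the DC
    spike that otherwise masks close targets.  When ``average_chirps`` is
    true the complex spectra are averaged across each frame's chirps
    (noise reduction); otherwise the first chirp's spectrum is kept,
    which preserves fine slow-time detail of the pulse waveform.
    """
    x = cube.values - cube.values.mean(axis=-1, keepdims=True)
    if window is not None:
        try:
            w = sps.get_window(window, cube.config.n_samples_per_chirp, fftbins=True)
        except ValueError as e:
            raise ConfigurationError(f"unknown window name {window!r}") from e
        x = x * w
    spectra = np.fft.rfft(x, axis=-1)                     # (F, A, C, bins)
    if average_chirps:
        prof = spectra.mean(axis=2)
    else:
        prof = spectra[:, :, 0, :]
    return RangeProfile(prof, cube.config, chirp_averaged=average_chirps)


def select_target_bin(profile: RangeProfile, prominence_factor: float = 3.0) -> int:
    """Pick the skin echo: the first (lowest-index) local maximum above the
    noise floor of the frame- and antenna-averaged magnitude spectrum.

    The first spike, not the strongest, is chosen — the closest reflector
    is the skin; later bins belong to other obstacles.  The DC bin is
    never returned.  The prominence floor is ``prominence_factor`` times
    the median magnitude over bins >= 1.
    """
    if profile.n_bins < 3:
        raise InvalidArgumentError("range profile needs at least 3 bins")
    mag = np.abs(profile.values).mean(axis=(0, 1))
    floor = prominence_factor * np.median(mag[1:])
    for k in range(1, profile.n_bins - 1):
        if mag[k] > mag[k - 1] and mag[k] >= mag[k + 1] and mag[k] > floor:
            return k
    raise DetectionError(
        "no qualifying first spike found in the range spectrum; "
        "check receiver gain and radar-skin distance"
    )


def extract_iq(profile: RangeProfile, target_bin: int) -> IQSeries:
    """Slow-time complex stream: the selected bin's value per frame per antenna.

    Inverse-transforming a one-bin-masked spectrum yields a pure fast-time
    exponential whose complex amplitude is exactly that bin value, so the
    bin value itself is the slow-time sample; no information is lost.
    """
    if not (1 <= target_bin < profile.n_bins):
        raise InvalidArgumentError(
            f"bin {target_bin} outside valid range 1..{profile.n_bins - 1}"
        )
    vals = profile.values[:, :, target_bin].T          # (antenna, frame)
    return IQSeries(vals, profile.config.frame_rate, target_bin)


def _phase_band_snr_db(iq_channel: np.ndarray, fs: float,
                       band: tuple = DISPLACEMENT_BAND_HZ) -> float:
    """SNR of one antenna's phase-difference signal: displacement-band power
    over out-of-band power, in dB."""
    mag = np.abs(iq_channel)
    if np.any(mag == 0):
        return -np.inf
    dphi = np.diff(np.unwrap(np.angle(iq_channel)))
    if len(dphi) < 8:
        raise InvalidArgumentError("too few frames for an SNR estimate")
    f, pxx = sps.periodogram(dphi, fs=fs)
    in_band = (f >= band[0]) & (f <= band[1])
    out_band = (f > 0) & ~in_band
    p_in = float(np.sum(pxx[in_band]))
    p_out = float(np.sum(pxx[out_band]))
    eps = np.finfo(float).tiny
    return 10.0 * np.log10((p_in + eps) / (p_out + eps))


def select_antennas(iq: IQSeries, tie_tolerance_db: float = 6.0) -> AntennaSelection:
    """Choose the antenna pair feeding the beamformer by the SNR criterion.

    A low-SNR channel degrades the beamformer, so channels are ranked by
    displacement-band SNR.  Channels within ``tie_tolerance_db`` of the
    best are treated as interchangeable (the estimate has a few dB of
    variance even on clean channels); among interchangeable channels the
    lowest-index adjacent pair is preferred, because the steering model
    assumes the pair is half-wavelength spaced.  When no adjacent pair
    qualifies (e.g. a dead middle channel) the two highest-SNR channels
    are returned.
    """
    if iq.n_antennas < 2:
        raise InvalidArgumentError("antenna selection needs at least 2 channels")
    snrs = np.array([_phase_band_snr_db(iq.values[a], iq.sample_rate)
                     for a in range(iq.n_antennas)])
    eligible = set(np.flatnonzero(snrs >= np.max(snrs) - tie_tolerance_db))
    for i in range(iq.n_antennas - 1):
        if i in eligible and i + 1 in eligible:
            return AntennaSelection((i, i + 1), snrs)
    order = np.argsort(-snrs, kind="stable")
    pair = tuple(sorted(int(a) for a in order[:2]))
    return AntennaSelection(pair, snrs)
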