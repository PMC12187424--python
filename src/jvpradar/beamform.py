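"""Eigen-beamforming for a two-antenna half-wavelength receive pair.

Because the slow-time I/Q stream comes from a single range bin it is an
almost noise-free, fully coherent observation: its sample covariance
R̂ = X Xᴴ / N is rank one and ill-conditioned, so inverse-based adaptive
beamformers are unusable.  Eigen-beamforming instead combines the
channels along the dominant eigenvector of R̂ — no inversion anywhere —
and scans a direction-of-arrival (DoA) power spectrum by projecting
steering vectors onto that one-dimensional signal subspace:

    A(α)      = [1, exp(−iπ sin α)]          (half-wavelength spacing)
    A_proj(α) = e₁ (e₁ᴴ A(α))
    PSD(α)    = A_proj(α)ᴴ R̂ A_proj(α)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import IQSeries
from .errors import DegenerateInputError, InvalidArgumentError

__all__ = [
    "CovarianceMatrix",
    "BeamformerState",
    "DoASpectrum",
    "covariance",
    "sliding_covariance",
    "steering_vector",
    "dominant_eigendecomposition",
    "project_steering",
    "psd_scan",
    "beamform_series",
]


@dataclass
class CovarianceMatrix:
    """2×2 Hermitian sample covariance with the snapshot count it used."""

    matrix: np.ndarray
    snapshot_count: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=complex)
        if m.shape != (2, 2):
            raise InvalidArgumentError("covariance must be 2x2")
        self.matrix = m


@dataclass
class BeamformerState:
    """Dominant eigenstructure of the covariance: the combining weights."""

    eigenvector: np.ndarray      # unit norm, phase-fixed
    eigenvalue: float
    eigenvalue_ratio: float      # largest / smallest, >= 1 (inf if singular)


@dataclass
class DoASpectrum:
    """Beamformer output power versus scan angle."""

    angles_deg: np.ndarray
    psd: np.ndarray
    peak_angle_deg: float


def covariance(x: np.ndarray) -> CovarianceMatrix:
    """Sample covariance R̂ = X Xᴴ / N over N snapshots of a 2-channel block.

    Hermitian symmetry is enforced by averaging with the conjugate
    transpose; for a single snapshot the result is exactly rank one.
    """
    x = np.asarray(x, dtype=complex)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != 2 or x.shape[1] < 1:
        raise InvalidArgumentError("covariance expects a (2, N) block with N >= 1")
    n = x.shape[1]
    r = x @ x.conj().T / n
    r = 0.5 * (r + r.conj().T)
    return CovarianceMatrix(r, n)


def sliding_covariance(x: np.ndarray, window: int = 256, hop: int = 128) -> CovarianceMatrix:
    """Average of sample covariances over sliding slow-time windows.

    A ~1 s window (256 samples at 250 Hz) with 50% hop tracks slow scene
    drift while keeping each estimate well populated.  Records shorter
    than one window fall back to a single full-record covariance.
    """
    x = np.asarray(x, dtype=complex)
    if x.shape[0] != 2:
        raise InvalidArgumentError("expected a (2, N) block")
    n = x.shape[1]
    if n <= window:
        return covariance(x)
    starts = range(0, n - window + 1, hop)
    mats = [covariance(x[:, s:s + window]).matrix for s in starts]
    return CovarianceMatrix(np.mean(mats, axis=0), n)


def steering_vector(alpha: float) -> np.ndarray:
    """A(α) = [1, exp(−iπ sin α)] for a half-wavelength pair; α in radians."""
    if not (abs(alpha) <= np.pi / 2):
        raise InvalidArgumentError("steering angle must lie in [-pi/2, pi/2]")
    return np.array([1.0, np.exp(-1j * np.pi * np.sin(alpha))])


def dominant_eigendecomposition(r: CovarianceMatrix) -> BeamformerState:
    """Unit eigenvector of the largest eigenvalue, with a deterministic
    global phase (first non-negligible component made real positive)."""
    m = r.matrix
    scale = np.max(np.abs(m))
    if scale == 0:
        raise DegenerateInputError("covariance matrix is zero")
    w, v = np.linalg.eigh(m)
    lam_min, lam_max = float(w[0]), float(w[-1])
    e1 = v[:, -1]
    k = int(np.argmax(np.abs(e1) > 1e-12 * np.max(np.abs(e1))))
    e1 = e1 * np.exp(-1j * np.angle(e1[k]))
    e1 = e1 / np.linalg.norm(e1)
    ratio = np.inf if lam_min <= lam_max * 1e-15 else lam_max / lam_min
    return BeamformerState(e1, lam_max, ratio)


def project_steering(a: np.ndarray, state: BeamformerState) -> np.ndarray:
    """Project a steering vector onto the dominant eigenvector's span:
    A_proj = e₁ (e₁ᴴ A)."""
    e1 = state.eigenvector
    return e1 * (e1.conj() @ np.asarray(a, dtype=complex))


def psd_scan(r: CovarianceMatrix, grid_deg: np.ndarray | None = None) -> DoASpectrum:
    """Beamformer output power PSD(α) = A_projᴴ R̂ A_proj over a scan grid.

    The result is real and non-negative for any Hermitian PSD covariance;
    the peak takes the lowest angle on ties.
    """
    if grid_deg is None:
        grid_deg = np.arange(-90.0, 91.0, 1.0)
    grid_deg = np.asarray(grid_deg, dtype=float)
    if grid_deg.size == 0:
        raise InvalidArgumentError("scan grid is empty")
    if np.any(np.abs(grid_deg) > 90.0):
        raise InvalidArgumentError("scan angles must lie within [-90, 90] degrees")
    state = dominant_eigendecomposition(r)
    psd = np.empty_like(grid_deg)
    for i, adeg in enumerate(grid_deg):
        aproj = project_steering(steering_vector(np.radians(adeg)), state)
        psd[i] = float(np.real(aproj.conj() @ r.matrix @ aproj))
    peak = float(grid_deg[int(np.argmax(psd))])
    return DoASpectrum(grid_deg, psd, peak)


def beamform_series(iq_pair: np.ndarray, state: BeamformerState) -> np.ndarray:
    """Coherent combination along the dominant eigenvector: y(t) = e₁ᴴ x(t)."""
    x = np.asarray(iq_pair, dtype=complex)
    if x.ndim != 2 or x.shape[0] != 2:
        raise InvalidArgumentError("expected a (2, N) pair of equal-length streams")
    return state.eigenvector.conj() @ x


def beamform_iq(iq: IQSeries, pair: tuple, window: int = 256,
                hop: int = 128) -> tuple[np.ndarray, BeamformerState, CovarianceMatrix]:
    """Convenience: covariance → eigenstate → combined stream for a pair."""
    block = iq.values[list(pair), :]
    r = sliding_covariance(block, window=window, hop=hop)
    state = dominant_eigendecomposition(r)
    return beamform_series(block, state), state, r
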