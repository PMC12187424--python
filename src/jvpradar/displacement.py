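"""I/Q constellation correction and phase-to-displacement conversion.

A target oscillating by a fraction of a wavelength traces an arc in the
I/Q plane.  DC offsets (mixer leakage, static clutter) displace that arc
from the origin and distort the extracted phase, so the arc's circle is
estimated by Taubin's algebraic circular regression (solved via SVD,
more accurate than the plain Kåsa least-squares fit) and the I/Q stream
is recentred on the fitted centre.  The unwrapped phase of the corrected
stream then converts to skin displacement through

    d = θ · λ / (4π),

the factor 4π (= 2 · 2π/λ) accounting for the round trip of the wave.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DisplacementSignal, PhaseSeries
from .errors import DegenerateInputError, InvalidArgumentError, PhaseUndefinedError

__all__ = [
    "CircleFit",
    "fit_circle_taubin",
    "recenter_iq",
    "correct_iq_offset",
    "instantaneous_phase",
    "phase_to_displacement",
]


@dataclass
class CircleFit:
    """Fitted circle: centre (x, y), radius and RMS radial residual."""

    center: tuple
    radius: float
    residual: float

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise DegenerateInputError("fitted radius must be positive")


def _as_points(points: np.ndarray) -> np.ndarray:
    p = np.asarray(points)
    if np.iscomplexobj(p):
        p = np.column_stack([p.real, p.imag])
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise InvalidArgumentError("points must be complex 1-D or (N, 2) real")
    return p


def fit_circle_taubin(points: np.ndarray) -> CircleFit:
    """Taubin algebraic circle fit, SVD implementation.

    Minimises the Taubin-normalised algebraic distance of
    a(x²+y²) + bx + cy + d = 0.  After centring the data, the reduced
    coordinate z = x²+y² is rescaled by its mean and the smallest right
    singular vector of the (z̃, x, y) design matrix gives the circle
    parameters.  Exact on noise-free circles of any radius; on noisy data
    its bias is lower than the plain least-squares (Kåsa) fit.
    """
    p = _as_points(points)
    # deduplicate for the degeneracy checks; the fit itself uses all points
    uniq = np.unique(p, axis=0)
    if uniq.shape[0] < 3:
        raise DegenerateInputError("circle fit needs at least 3 distinct points")
    mx, my = p[:, 0].mean(), p[:, 1].mean()
    x = p[:, 0] - mx
    y = p[:, 1] - my
    z = x * x + y * y
    zm = z.mean()
    if zm <= 0:
        raise DegenerateInputError("all points coincide")
    z0 = (z - zm) / (2.0 * np.sqrt(zm))
    design = np.column_stack([z0, x, y])
    _, s, vt = np.linalg.svd(design, full_matrices=False)
    if s[0] > 0 and s[-1] / s[0] < 1e-12 and abs(vt[-1, 0]) < 1e-9:
        # best algebraic solution is a line through the data
        raise DegenerateInputError("points are collinear; no circle is defined")
    a_, b_, c_ = vt[-1]
    a = a_ / (2.0 * np.sqrt(zm))
    d = -zm * a
    if abs(a) < 1e-14:
        raise DegenerateInputError("points are collinear; no circle is defined")
    cx = -b_ / (2.0 * a)
    cy = -c_ / (2.0 * a)
    radius = float(np.sqrt(cx * cx + cy * cy - d / a))
    center = (float(cx + mx), float(cy + my))
    radial = np.hypot(p[:, 0] - center[0], p[:, 1] - center[1])
    residual = float(np.sqrt(np.mean((radial - radius) ** 2)))
    return CircleFit(center, radius, residual)


def recenter_iq(iq: np.ndarray, fit: CircleFit) -> np.ndarray:
    """Translate the I/Q stream so the fitted circle centre sits at the origin."""
    iq = np.asarray(iq, dtype=complex)
    return iq - (fit.center[0] + 1j * fit.center[1])


def correct_iq_offset(iq: np.ndarray, block: int = 256) -> np.ndarray:
    """Per-block Taubin fit and recentring of a slow-time I/Q stream.

    Non-overlapping blocks of ``block`` samples track slow drift of the
    DC offset; a trailing partial block is merged into its predecessor so
    every fit sees enough points.
    """
    iq = np.asarray(iq, dtype=complex)
    n = len(iq)
    if n < 3:
        raise DegenerateInputError("need at least 3 samples to correct the I/Q offset")
    if n <= block + block // 2:
        return recenter_iq(iq, fit_circle_taubin(iq))
    edges = list(range(0, n, block))
    if n - edges[-1] < block // 2:
        edges.pop()
    out = np.empty_like(iq)
    for i, s in enumerate(edges):
        e = edges[i + 1] if i + 1 < len(edges) else n
        out[s:e] = recenter_iq(iq[s:e], fit_circle_taubin(iq[s:e]))
    return out


def instantaneous_phase(iq: np.ndarray, sample_rate: float) -> PhaseSeries:
    """Four-quadrant instantaneous phase, unwrapped over slow time.

    Unwrapping restores the phase's continuous growth by adding ±2π where
    successive wrapped differences exceed π.  A zero-magnitude sample has
    no phase and aborts with the offending frame index — interpolating
    over it could fabricate pulses.
    """
    iq = np.asarray(iq, dtype=complex)
    mag = np.abs(iq)
    if np.any(mag == 0):
        raise PhaseUndefinedError(int(np.argmax(mag == 0)))
    theta = np.unwrap(np.angle(iq))
    return PhaseSeries(theta, sample_rate)


def phase_to_displacement(phase: PhaseSeries, wavelength: float) -> DisplacementSignal:
    """Convert unwrapped phase to a zero-mean skin-displacement trace.

    Successive phase differences are scaled by λ/(4π) — only the fast
    phase variation carries pulse information, the linear range-offset
    trend does not — then cumulatively summed and mean-removed.
    """
    if wavelength <= 0:
        raise InvalidArgumentError("wavelength must be positive")
    theta = phase.values
    increments = np.diff(theta) * wavelength / (4.0 * np.pi)
    disp = np.concatenate([[0.0], np.cumsum(increments)])
    disp = disp - disp.mean()
    return DisplacementSignal(disp, phase.sample_rate, wavelength)
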