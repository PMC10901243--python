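"""Stokes-Mueller algebra for linear polarization elements.

Conventions used throughout the package
---------------------------------------
* All angles are in **degrees**. Axial quantities (fast axes, transmission
  axes, fiber orientations) live on the half-open interval ``[0, 180)`` and
  are measured counterclockwise from the horizontal x-axis of the image
  plane.
* Stokes vectors are ``(I, Q, U, V)`` with ``Q > 0`` meaning horizontal
  linear polarization. With this choice a quarter-wave retarder at fast
  axis theta has fourth row ``(0, sin 2θ, −cos 2θ, 0)``.
* Mueller elements are referred to with 1-based indices ``m11 .. m44`` in
  all documentation and reports; arrays are 0-based internally.

All constructors broadcast over array-valued angle arguments and return
arrays of shape ``(..., 4, 4)``, which is what the phantom generator and
the per-pixel image pipeline rely on.
"""

from __future__ import annotations

from functools import reduce

import numpy as np

__all__ = [
    "wrap_axial",
    "rotation_matrix",
    "linear_retarder",
    "linear_diattenuator",
    "depolarizer_diag",
    "compose_layers",
    "stokes",
    "degree_of_polarization",
    "degree_of_linear_polarization",
    "is_physical_stokes",
    "normalize_m11",
    "element_bounds_ok",
]

_STOKES_TOL = 1e-9


def _as_finite(angle, name: str = "angle") -> np.ndarray:
    a = np.asarray(angle, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} must be finite, got {angle!r}")
    return a


def wrap_axial(angle):
    """Reduce an axial angle (degrees) to the fundamental domain [0, 180)."""
    return np.mod(_as_finite(angle), 180.0)


def rotation_matrix(angle):
    """Mueller rotation matrix R(angle) for a frame rotation by ``angle`` degrees.

    Satisfies ``R(a) @ R(b) == R(a + b)`` and acts on the (Q, U) block with
    double-angle arguments; an element with axis ``t`` is
    ``R(t) @ element(axis=0) @ R(-t)``.
    """
    a = _as_finite(angle)
    phi = np.deg2rad(2.0 * a)
    c, s = np.cos(phi), np.sin(phi)
    out = np.zeros(np.shape(c) + (4, 4))
    out[..., 0, 0] = 1.0
    out[..., 3, 3] = 1.0
    out[..., 1, 1] = c
    out[..., 1, 2] = -s
    out[..., 2, 1] = s
    out[..., 2, 2] = c
    return out


def linear_retarder(delta, axis):
    """Mueller matrix of a linear retarder.

    Parameters
    ----------
    delta : float or array
        Retardance magnitude in degrees, in [0, 180].
    axis : float or array
        Fast-axis orientation in degrees (axial).

    Notes
    -----
    Equal to ``R(axis) @ retarder(delta, 0) @ R(-axis)``; a quarter-wave
    plate (``delta=90``) reproduces the canonical matrix with
    ``m42 = sin 2θ`` and ``m43 = −cos 2θ``.
    """
    d = _as_finite(delta, "delta")
    if np.any(d < 0.0) or np.any(d > 180.0):
        raise ValueError(f"retardance must lie in [0, 180] deg, got {delta!r}")
    t = _as_finite(axis, "axis")
    d, t = np.broadcast_arrays(d, t)
    cd, sd = np.cos(np.deg2rad(d)), np.sin(np.deg2rad(d))
    C, S = np.cos(np.deg2rad(2.0 * t)), np.sin(np.deg2rad(2.0 * t))
    out = np.zeros(np.shape(C) + (4, 4))
    out[..., 0, 0] = 1.0
    out[..., 1, 1] = C * C + S * S * cd
    out[..., 1, 2] = C * S * (1.0 - cd)
    out[..., 1, 3] = -S * sd
    out[..., 2, 1] = C * S * (1.0 - cd)
    out[..., 2, 2] = S * S + C * C * cd
    out[..., 2, 3] = C * sd
    out[..., 3, 1] = S * sd
    out[..., 3, 2] = -C * sd
    out[..., 3, 3] = cd
    return out


def linear_diattenuator(D, axis):
    """m11-normalized linear diattenuator with diattenuation ``D`` in [0, 1].

    ``axis`` is the azimuth of maximum transmittance (degrees). ``D=1`` at
    ``axis=0`` gives an ideal horizontal polarizer (up to the m11 scale,
    which is folded into the normalization).
    """
    Dv = _as_finite(D, "D")
    if np.any(Dv < 0.0) or np.any(Dv > 1.0):
        raise ValueError(f"diattenuation must lie in [0, 1], got {D!r}")
    t = _as_finite(axis, "axis")
    Dv, t = np.broadcast_arrays(Dv, t)
    c, s = np.cos(np.deg2rad(2.0 * t)), np.sin(np.deg2rad(2.0 * t))
    q = np.sqrt(1.0 - Dv * Dv)
    out = np.zeros(np.shape(c) + (4, 4))
    out[..., 0, 0] = 1.0
    out[..., 0, 1] = Dv * c
    out[..., 0, 2] = Dv * s
    out[..., 1, 0] = Dv * c
    out[..., 2, 0] = Dv * s
    # mD = q I + (1 - q) dhat dhat^T with dhat = (c, s, 0)
    out[..., 1, 1] = q + (1.0 - q) * c * c
    out[..., 1, 2] = (1.0 - q) * c * s
    out[..., 2, 1] = (1.0 - q) * c * s
    out[..., 2, 2] = q + (1.0 - q) * s * s
    out[..., 3, 3] = q
    return out


def depolarizer_diag(d1, d2, d3):
    """Diagonal depolarizer ``diag(1, d1, d2, d3)`` with each coefficient in [0, 1].

    Its depolarization power is ``1 - (d1 + d2 + d3) / 3``.
    """
    coeffs = [_as_finite(d, f"d{i + 1}") for i, d in enumerate((d1, d2, d3))]
    for i, d in enumerate(coeffs):
        if np.any(d < 0.0) or np.any(d > 1.0):
            raise ValueError(f"depolarizer coefficient d{i + 1} must lie in [0, 1]")
    b = np.broadcast_arrays(*coeffs)
    out = np.zeros(np.shape(b[0]) + (4, 4))
    out[..., 0, 0] = 1.0
    for i in range(3):
        out[..., i + 1, i + 1] = b[i]
    return out


def compose_layers(layers) -> np.ndarray:
    """Compose Mueller matrices of layers given in light-propagation order.

    The first-encountered layer is first in the list; the composite is the
    matrix product with the last-encountered layer leftmost,
    ``M = M_n @ ... @ M_1``.
    """
    mats = [np.asarray(m, dtype=float) for m in layers]
    if not mats:
        raise ValueError("compose_layers requires at least one layer")
    return reduce(lambda acc, m: m @ acc, mats)


def stokes(I, Q=0.0, U=0.0, V=0.0) -> np.ndarray:
    """Build a Stokes vector (I, Q, U, V) as a float array."""
    s = np.array([I, Q, U, V], dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("Stokes components must be finite")
    return s


def degree_of_polarization(s) -> float:
    s = np.asarray(s, dtype=float)
    return float(np.sqrt(s[1] ** 2 + s[2] ** 2 + s[3] ** 2) / s[0])


def degree_of_linear_polarization(s) -> float:
    s = np.asarray(s, dtype=float)
    return float(np.hypot(s[1], s[2]) / s[0])


def is_physical_stokes(s, tol: float = _STOKES_TOL) -> bool:
    """Check I >= 0 and Q^2 + U^2 + V^2 <= I^2 within tolerance."""
    s = np.asarray(s, dtype=float)
    return bool(s[0] >= -tol and s[1] ** 2 + s[2] ** 2 + s[3] ** 2 <= s[0] ** 2 + tol)


def normalize_m11(M) -> np.ndarray:
    """Return M / m11 (per matrix for stacked input). Requires m11 > 0."""
    M = np.asarray(M, dtype=float)
    m11 = M[..., 0, 0]
    if np.any(m11 <= 0):
        raise ValueError("m11 must be positive for a physically meaningful element")
    return M / m11[..., None, None]


def element_bounds_ok(M, tol: float = 1e-9) -> bool:
    """True when every element satisfies |mij| <= m11 (+tol)."""
    M = np.asarray(M, dtype=float)
    m11 = M[..., 0, 0]
    return bool(np.all(np.abs(M) <= (m11 + tol)[..., None, None]))
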