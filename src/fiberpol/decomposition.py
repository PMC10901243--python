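"""Lu-Chipman polar decomposition and per-pixel anisotropy parameters.

A measured Mueller matrix is factored as ``M = M_delta @ M_R @ M_D``
(depolarizer, pure retarder, diattenuator). From the factors the pipeline
derives the per-pixel maps this package is about:

* ``theta`` — fast-axis orientation of the linear retardance, from the
  retardance vector of the retarder factor, ``theta = 1/2 atan2(r2, r1)``;
* ``delta_lr`` — linear retardance magnitude in degrees;
* ``Delta`` — depolarization power ``1 - |tr(m_delta)| / 3``;
* ``alphaP`` — diattenuation azimuth ``1/2 atan2(m31, m21)`` read directly
  from the (first-column) elements of the normalized matrix;
* ``alphaQ`` — birefringence azimuth ``1/2 atan2(m42, -m43)`` read directly
  from the matrix elements (equal to theta for a pure linear retarder, but
  unstable when depolarization couples linear and circular components);
* ``D`` — diattenuation magnitude.

All half-angle ratios use the two-argument arctangent and are reduced to
[0, 180), which removes the quadrant ambiguity a single-argument arctan
leaves open. Degenerate pixels (vanishing retardance, vanishing
diattenuation vector, near-perfect diattenuator, singular depolarizer) are
masked with reason codes rather than propagated as NaN surprises.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mueller import normalize_m11, wrap_axial

__all__ = [
    "MMPDFactors",
    "ParamMaps",
    "lu_chipman",
    "retardance_theta",
    "linear_retardance",
    "depolarization_power",
    "alpha_p",
    "alpha_q",
    "decompose_image",
    "MASK_THETA",
    "MASK_ALPHA_P",
    "MASK_ALPHA_Q",
    "MASK_DIATT_DEGENERATE",
    "MASK_SINGULAR_DEPOL",
]

# mask reason bits for ParamMaps.mask
MASK_THETA = 1  # retarder orientation undefined (sin(delta) ~ 0)
MASK_ALPHA_P = 2  # diattenuation orientation undefined (m21, m31 ~ 0)
MASK_ALPHA_Q = 4  # alphaQ undefined (m42, m43 ~ 0)
MASK_DIATT_DEGENERATE = 8  # D ~ 1, diattenuator not invertible
MASK_SINGULAR_DEPOL = 16  # det(m_delta) ~ 0, retarder factor undefined

_EPS_DEGENERATE_D = 1e-9
_EPS_SINGULAR = 1e-12
_ORTHO_TOL = 1e-9


@dataclass
class MMPDFactors:
    """The three m11-normalized polar-decomposition factors of one matrix."""

    M_delta: np.ndarray
    M_R: np.ndarray
    M_D: np.ndarray

    def recompose(self) -> np.ndarray:
        return self.M_delta @ self.M_R @ self.M_D


@dataclass
class ParamMaps:
    """Per-pixel anisotropy parameter maps with a reason-coded mask.

    Angular maps hold NaN where the corresponding mask bit is set; scalar
    maps (``Delta``, ``D``, ``delta_lr``) stay finite wherever the
    decomposition itself succeeded.
    """

    theta: np.ndarray
    delta_lr: np.ndarray
    Delta: np.ndarray
    alphaP: np.ndarray
    alphaQ: np.ndarray
    D: np.ndarray
    mask: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.mask is None:
            self.mask = np.zeros(np.shape(self.theta), dtype=np.uint8)

    @property
    def shape(self):
        return np.shape(self.theta)

    def valid(self, which: int) -> np.ndarray:
        """Boolean map of pixels where none of the given mask bits are set."""
        return (self.mask & which) == 0


def _factor_batch(M: np.ndarray):
    """Batched Lu-Chipman factorization of matrices of shape (..., 4, 4).

    Returns (M_delta, M_R, M_D, degenerate_D, singular_delta).
    """
    N = normalize_m11(M)
    shape = N.shape[:-2]
    I3 = np.eye(3)

    Dvec = N[..., 0, 1:]
    D = np.linalg.norm(Dvec, axis=-1)
    degenerate = D >= 1.0 - _EPS_DEGENERATE_D
    # degenerate diattenuators are flagged and replaced by the identity so the
    # batched factorization stays well-posed for the remaining pixels
    N = np.where(degenerate[..., None, None], np.eye(4), N)
    Dvec = N[..., 0, 1:]
    Dsafe = np.where(degenerate, 0.0, D)
    dnorm = np.where(Dsafe > 0, Dsafe, 1.0)
    dhat = np.where(degenerate[..., None], 0.0, Dvec) / dnorm[..., None]
    q = np.sqrt(1.0 - Dsafe**2)
    mD = q[..., None, None] * I3 + (1.0 - q)[..., None, None] * (
        dhat[..., :, None] * dhat[..., None, :]
    )
    MD = np.zeros(shape + (4, 4))
    MD[..., 0, 0] = 1.0
    MD[..., 0, 1:] = np.where(degenerate[..., None], 0.0, Dvec)
    MD[..., 1:, 0] = MD[..., 0, 1:]
    MD[..., 1:, 1:] = mD

    Mp = N @ np.linalg.inv(MD)
    mp = Mp[..., 1:, 1:]

    mmT = mp @ np.swapaxes(mp, -1, -2)
    lam2 = np.linalg.eigvalsh(mmT)  # ascending
    lam = np.sqrt(np.clip(lam2, 0.0, None))
    s1 = lam.sum(axis=-1)
    s2 = lam[..., 0] * lam[..., 1] + lam[..., 0] * lam[..., 2] + lam[..., 1] * lam[..., 2]
    s3 = lam[..., 0] * lam[..., 1] * lam[..., 2]
    sign = np.where(np.linalg.det(mp) < 0, -1.0, 1.0)
    # two vanishing singular values make (m'm'^T + s2 I) itself singular:
    # the depolarizer factor is then rank-deficient and the retarder undefined
    rank_deficient = lam[..., 1] < _EPS_SINGULAR ** (1.0 / 3.0)
    lhs = mmT + s2[..., None, None] * I3
    lhs = np.where(rank_deficient[..., None, None], I3, lhs)
    rhs = s1[..., None, None] * mmT + s3[..., None, None] * I3
    mdelta = sign[..., None, None] * np.linalg.solve(lhs, rhs)

    singular = rank_deficient | (np.abs(np.linalg.det(mdelta)) < _EPS_SINGULAR)
    mdelta_safe = np.where(singular[..., None, None], I3, mdelta)
    mR = np.linalg.solve(mdelta_safe, mp)

    # re-orthogonalize the retarder rotation when numerical inversion left a defect
    defect = np.abs(mR @ np.swapaxes(mR, -1, -2) - I3).max(axis=(-1, -2))
    bad = defect > _ORTHO_TOL
    if np.any(bad):
        U, _, Vt = np.linalg.svd(mR[bad])
        det = np.linalg.det(U @ Vt)
        U[..., :, 2] *= np.where(det < 0, -1.0, 1.0)[..., None]
        mR[bad] = U @ Vt

    m3 = N[..., 1:, 1:]
    P = N[..., 1:, 0]
    denom = np.maximum(1.0 - Dsafe**2, _EPS_SINGULAR)
    Pdelta = (P - np.einsum("...ij,...j->...i", m3, Dvec)) / denom[..., None]

    Mdelta = np.zeros(shape + (4, 4))
    Mdelta[..., 0, 0] = 1.0
    Mdelta[..., 1:, 0] = Pdelta
    Mdelta[..., 1:, 1:] = mdelta
    MR = np.zeros(shape + (4, 4))
    MR[..., 0, 0] = 1.0
    MR[..., 1:, 1:] = mR
    return Mdelta, MR, MD, degenerate, singular


def lu_chipman(M: np.ndarray) -> MMPDFactors:
    """Polar decomposition ``M = M_delta @ M_R @ M_D`` of a single matrix.

    Raises
    ------
    ValueError
        If m11 <= 0, the diattenuation magnitude reaches 1 (degenerate
        diattenuator), or the depolarizer submatrix is singular (retarder
        undefined).
    """
    M = np.asarray(M, dtype=float)
    if M.shape != (4, 4):
        raise ValueError("lu_chipman expects a single 4x4 matrix")
    Mdelta, MR, MD, degenerate, singular = _factor_batch(M)
    if bool(degenerate):
        raise ValueError("degenerate diattenuator: D >= 1, M_D is not invertible")
    if bool(singular):
        raise ValueError("singular depolarizer submatrix: retarder factor undefined")
    return MMPDFactors(M_delta=Mdelta, M_R=MR, M_D=MD)


def _submatrix(M_R: np.ndarray) -> np.ndarray:
    M_R = np.asarray(M_R, dtype=float)
    return M_R[..., 1:, 1:]


def retardance_theta(M_R: np.ndarray) -> np.ndarray | float:
    """Fast-axis orientation (deg) of a retarder factor via the retardance vector.

    ``r_i`` is proportional to ``sum_jk eps_ijk mR(j, k)``;
    ``theta = 1/2 atan2(r2, r1)`` reduced to [0, 180). NaN where the total
    retardance is 0 or 180 deg (``sin(delta) ~ 0``), where the orientation
    is undefined.
    """
    mR = _submatrix(M_R)
    r1 = mR[..., 1, 2] - mR[..., 2, 1]
    r2 = mR[..., 2, 0] - mR[..., 0, 2]
    r3 = mR[..., 0, 1] - mR[..., 1, 0]
    # |r| = 2 sin(delta_total); undefined orientation when it vanishes
    sin_delta = 0.5 * np.sqrt(r1**2 + r2**2 + r3**2)
    theta = wrap_axial(0.5 * np.degrees(np.arctan2(r2, r1)))
    theta = np.where(sin_delta < 1e-9, np.nan, theta)
    return float(theta) if np.ndim(theta) == 0 else theta


def linear_retardance(M_R: np.ndarray) -> np.ndarray | float:
    """Linear retardance magnitude (deg) of a retarder factor, in [0, 180]."""
    mR = _submatrix(M_R)
    arg = (
        np.sqrt(
            (mR[..., 0, 0] + mR[..., 1, 1]) ** 2
            + (mR[..., 1, 0] - mR[..., 0, 1]) ** 2
        )
        - 1.0
    )
    if np.any(np.abs(arg) > 1.0 + 1e-9):
        raise ValueError("linear retardance argument outside [-1, 1] beyond tolerance")
    delta = np.degrees(np.arccos(np.clip(arg, -1.0, 1.0)))
    return float(delta) if np.ndim(delta) == 0 else delta


def depolarization_power(M_delta: np.ndarray) -> np.ndarray | float:
    """Depolarization power ``Delta = 1 - |tr(m_delta)| / 3`` in [0, 1]."""
    m = _submatrix(M_delta)
    tr = np.trace(m, axis1=-2, axis2=-1)
    out = 1.0 - np.abs(tr) / 3.0
    return float(out) if np.ndim(out) == 0 else out


def alpha_p(M: np.ndarray, floor: float = 1e-6) -> np.ndarray | float:
    """Diattenuation azimuth ``1/2 atan2(m31, m21)`` in degrees on [0, 180).

    NaN (masked) where ``sqrt(m21^2 + m31^2)`` falls below ``floor`` times
    m11, i.e. where the diattenuation orientation is undefined.
    """
    N = normalize_m11(np.asarray(M, dtype=float))
    m21 = N[..., 1, 0]
    m31 = N[..., 2, 0]
    mag = np.hypot(m21, m31)
    out = wrap_axial(0.5 * np.degrees(np.arctan2(m31, m21)))
    out = np.where(mag < floor, np.nan, out)
    return float(out) if np.ndim(out) == 0 else out


def alpha_q(M: np.ndarray, floor: float = 1e-6) -> np.ndarray | float:
    """Birefringence azimuth ``1/2 atan2(m42, -m43)`` in degrees on [0, 180).

    Equals the fast axis for a pure linear retarder. NaN where
    ``sqrt(m42^2 + m43^2)`` falls below ``floor`` times m11.
    """
    N = normalize_m11(np.asarray(M, dtype=float))
    m42 = N[..., 3, 1]
    m43 = N[..., 3, 2]
    mag = np.hypot(m42, m43)
    out = wrap_axial(0.5 * np.degrees(np.arctan2(m42, -m43)))
    out = np.where(mag < floor, np.nan, out)
    return float(out) if np.ndim(out) == 0 else out


def decompose_image(
    M: np.ndarray,
    alpha_floor: float = 1e-6,
    retarder_floor: float = 1e-9,
) -> ParamMaps:
    """Pixelwise polar decomposition and parameter extraction for an image.

    Parameters
    ----------
    M : array, shape (H, W, 4, 4)
        Mueller image (any positive m11 scale).
    alpha_floor : float
        Mask threshold on the element-vector magnitudes behind alphaP and
        alphaQ, relative to m11.
    retarder_floor : float
        Mask threshold on ``sin(total retardance)`` below which the fast
        axis is undefined.

    Returns
    -------
    ParamMaps
        Six maps plus a uint8 mask of reason bits. Pixels failing a
        precondition are masked (angular maps hold NaN there), never
        silently NaN-propagated.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 4 or M.shape[-2:] != (4, 4):
        raise ValueError("decompose_image expects shape (H, W, 4, 4)")
    N = normalize_m11(M)
    Mdelta, MR, MD, degenerate, singular = _factor_batch(N)

    mask = np.zeros(M.shape[:2], dtype=np.uint8)
    mask[degenerate] |= MASK_DIATT_DEGENERATE
    mask[singular] |= MASK_SINGULAR_DEPOL

    mR = MR[..., 1:, 1:]
    r1 = mR[..., 1, 2] - mR[..., 2, 1]
    r2 = mR[..., 2, 0] - mR[..., 0, 2]
    r3 = mR[..., 0, 1] - mR[..., 1, 0]
    sin_delta = 0.5 * np.sqrt(r1**2 + r2**2 + r3**2)
    theta = wrap_axial(0.5 * np.degrees(np.arctan2(r2, r1)))
    theta_bad = (sin_delta < retarder_floor) | singular | degenerate
    mask[theta_bad & ~singular & ~degenerate] |= MASK_THETA
    theta = np.where(theta_bad, np.nan, theta)

    delta_lr = linear_retardance(MR)
    Delta = depolarization_power(Mdelta)
    D = np.linalg.norm(N[..., 0, 1:], axis=-1)

    m21, m31 = N[..., 1, 0], N[..., 2, 0]
    p_bad = np.hypot(m21, m31) < alpha_floor
    mask[p_bad] |= MASK_ALPHA_P
    aP = wrap_axial(0.5 * np.degrees(np.arctan2(m31, m21)))
    aP = np.where(p_bad, np.nan, aP)

    m42, m43 = N[..., 3, 1], N[..., 3, 2]
    q_bad = np.hypot(m42, m43) < alpha_floor
    mask[q_bad] |= MASK_ALPHA_Q
    aQ = wrap_axial(0.5 * np.degrees(np.arctan2(m42, -m43)))
    aQ = np.where(q_bad, np.nan, aQ)

    return ParamMaps(
        theta=theta, delta_lr=delta_lr, Delta=Delta, alphaP=aP, alphaQ=aQ, D=D,
        mask=mask,
    )
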