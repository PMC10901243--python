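"""Dual-rotating quarter-wave-plate acquisition simulator and reconstruction.

The simulated instrument follows the classic dual-rotating-retarder layout:
a fixed polarizer P1 and quarter-wave plate R1 form the polarization state
generator (PSG); the analyzer is quarter-wave plate R2 followed by a fixed
polarizer P2 (PSA). Both wave plates rotate synchronously over 30 frames,
R1 in 6 deg steps and R2 in 30 deg steps (a 1:5 ratio), and each frame
records one scalar intensity image. The per-pixel Mueller matrix is
recovered from the 30 intensities by least squares on the 30x16 design
matrix, which on this evenly stepped protocol is mathematically equivalent
to the Fourier-coefficient inversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mueller import linear_diattenuator, linear_retarder, normalize_m11, stokes

__all__ = [
    "AcquisitionProtocol",
    "ProtocolRankError",
    "psg_state",
    "psa_row",
    "design_matrix",
    "simulate_stack",
    "reconstruct_mueller",
    "air_calibration_error",
]


class ProtocolRankError(ValueError):
    """The acquisition protocol does not determine all 16 Mueller elements."""

    def __init__(self, rank: int):
        self.rank = rank
        super().__init__(
            f"design matrix has rank {rank} < 16; the protocol cannot recover "
            "a full Mueller matrix"
        )


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Geometry of the rotating-retarder measurement.

    Defaults are the 30-frame protocol with PSG retarder step 6 deg/frame,
    PSA retarder step 30 deg/frame, quarter-wave retardances and both
    polarizers at 0 deg.
    """

    n_frames: int = 30
    psg_step: float = 6.0
    psa_step: float = 30.0
    psg_retardance: float = 90.0
    psa_retardance: float = 90.0
    psg_polarizer_axis: float = 0.0
    psa_polarizer_axis: float = 0.0

    def __post_init__(self):
        if self.n_frames < 16:
            raise ValueError("n_frames must be >= 16 for invertibility")
        if self.psg_step <= 0 or self.psa_step <= 0:
            raise ValueError("retarder steps must be positive")

    def to_dict(self) -> dict:
        return {
            "n_frames": self.n_frames,
            "psg_step": self.psg_step,
            "psa_step": self.psa_step,
            "psg_retardance": self.psg_retardance,
            "psa_retardance": self.psa_retardance,
            "psg_polarizer_axis": self.psg_polarizer_axis,
            "psa_polarizer_axis": self.psa_polarizer_axis,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        return cls(**d)


_DEFAULT = AcquisitionProtocol()


def _check_index(frame_index: int, protocol: AcquisitionProtocol):
    if not 0 <= frame_index < protocol.n_frames:
        raise ValueError(
            f"frame index {frame_index} out of range [0, {protocol.n_frames})"
        )


def psg_state(frame_index: int, protocol: AcquisitionProtocol = _DEFAULT) -> np.ndarray:
    """Stokes vector produced by the generator at one rotation step.

    Unit unpolarized light through P1 then R1 at ``frame_index * psg_step``
    degrees; the result is fully polarized.
    """
    _check_index(frame_index, protocol)
    pol = linear_diattenuator(1.0, protocol.psg_polarizer_axis)
    qwp = linear_retarder(protocol.psg_retardance, frame_index * protocol.psg_step)
    return qwp @ pol @ stokes(1.0)


def psa_row(frame_index: int, protocol: AcquisitionProtocol = _DEFAULT) -> np.ndarray:
    """Analyzer row vector for one rotation step.

    First row of ``P2 @ R2(frame_index * psa_step)``; the detected intensity
    for a sample ``M`` at frame k is ``psa_row(k) @ M @ psg_state(k)``.
    """
    _check_index(frame_index, protocol)
    pol = linear_diattenuator(1.0, protocol.psa_polarizer_axis)
    qwp = linear_retarder(protocol.psa_retardance, frame_index * protocol.psa_step)
    return (pol @ qwp)[0]


def design_matrix(protocol: AcquisitionProtocol = _DEFAULT) -> np.ndarray:
    """(n_frames, 16) matrix mapping the flattened Mueller matrix to intensities.

    Row k is the outer product ``psa_row(k) (x) psg_state(k)`` flattened in
    row-major m11..m44 order.
    """
    rows = [
        np.outer(psa_row(k, protocol), psg_state(k, protocol)).ravel()
        for k in range(protocol.n_frames)
    ]
    return np.asarray(rows)


def simulate_stack(
    sample: np.ndarray,
    protocol: AcquisitionProtocol = _DEFAULT,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Simulate the intensity stack for a Mueller image.

    Parameters
    ----------
    sample : array, shape (H, W, 4, 4)
        Per-pixel sample Mueller matrices.
    noise_sd : float
        Relative standard deviation of zero-mean multiplicative Gaussian
        intensity noise; 0 gives the exact analytic frames. Noisy
        intensities are clipped at zero.
    seed : int, optional
        Seed for the noise generator; a fixed seed gives bit-identical
        stacks.

    Returns
    -------
    array, shape (n_frames, H, W)
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    M = np.asarray(sample, dtype=float)
    if M.ndim != 4 or M.shape[-2:] != (4, 4):
        raise ValueError("sample must have shape (H, W, 4, 4)")
    analyzers = np.asarray([psa_row(k, protocol) for k in range(protocol.n_frames)])
    states = np.asarray([psg_state(k, protocol) for k in range(protocol.n_frames)])
    frames = np.einsum("ka,hwab,kb->khw", analyzers, M, states)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = frames * (1.0 + rng.normal(0.0, noise_sd, frames.shape))
        np.clip(frames, 0.0, None, out=frames)
    return frames


def reconstruct_mueller(
    stack: np.ndarray, protocol: AcquisitionProtocol = _DEFAULT
) -> np.ndarray:
    """Per-pixel least-squares Mueller matrix from an intensity stack.

    Raises :class:`ProtocolRankError` when the protocol's design matrix has
    rank below 16. A noise-free simulate/reconstruct round trip recovers
    the sample to better than 1e-9 per element.
    """
    frames = np.asarray(stack, dtype=float)
    if frames.ndim != 3:
        raise ValueError("stack must have shape (n_frames, H, W)")
    if frames.shape[0] != protocol.n_frames:
        raise ValueError(
            f"stack has {frames.shape[0]} frames, protocol expects {protocol.n_frames}"
        )
    A = design_matrix(protocol)
    rank = int(np.linalg.matrix_rank(A))
    if rank < 16:
        raise ProtocolRankError(rank)
    pinv = np.linalg.pinv(A)
    elements = np.einsum("ek,khw->hwe", pinv, frames)
    return elements.reshape(frames.shape[1], frames.shape[2], 4, 4)


def air_calibration_error(M: np.ndarray) -> float:
    """Maximum per-element deviation from the identity over an m11-normalized image.

    An empty (air) sample has the identity Mueller matrix, so this is the
    numerical-calibration figure of merit: ``max |mij - delta_ij|`` over all
    pixels and elements.
    """
    N = normalize_m11(np.asarray(M, dtype=float))
    return float(np.max(np.abs(N - np.eye(4))))
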