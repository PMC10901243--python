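"""Axial (180-degree-periodic) orientation statistics.

Fast axes and diattenuation azimuths are axial quantities: a and a+180 are
the same physical orientation. This module bins such angles into a
frequency distribution histogram (FDH) on [0, 180), finds its circular
peaks, measures each peak's angular full width at half maximum (beta), and
classifies a bimodal fast-axis distribution into an intrinsic-birefringence
peak (theta_b, perpendicular to the fiber long axis) and a
form-birefringence peak (theta_c, parallel to the fiber), using the
diattenuation azimuth alphaP — itself perpendicular to the fiber — as the
reference. The share gamma = peak(theta_b) / (peak(theta_b) + peak(theta_c))
tracks the relative strength of intrinsic vs. form birefringence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks

from .mueller import wrap_axial

__all__ = [
    "AxialHistogram",
    "Peak",
    "PeakSet",
    "BimodalSummary",
    "ClassificationRefused",
    "axial_distance",
    "build_fdh",
    "smooth_fdh",
    "circular_mean",
    "find_peaks",
    "beta",
    "classify_peaks",
    "gamma",
    "plot_fdh_polar",
]


class ClassificationRefused(ValueError):
    """Peak classification refused (multimodal alphaP, >2 theta peaks, or tie)."""

    def __init__(self, message: str, theta_modality: int, alpha_modality: int):
        self.theta_modality = theta_modality
        self.alpha_modality = alpha_modality
        super().__init__(
            f"{message} (theta modality {theta_modality}, alphaP modality "
            f"{alpha_modality})"
        )


def axial_distance(a, b):
    """Distance between two axial angles in degrees, in [0, 90]."""
    d = np.mod(np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)), 180.0)
    out = np.minimum(d, 180.0 - d)
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class AxialHistogram:
    """Binned probability distribution of an axial angle over [0, 180)."""

    bin_width: float
    bin_centers: np.ndarray
    mass: np.ndarray
    n_samples: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"bin_center_deg": self.bin_centers, "mass": self.mass}
        )


@dataclass
class Peak:
    angle: float
    density: float
    beta: float


@dataclass
class PeakSet:
    """Detected FDH peaks, sorted by density descending."""

    peaks: list[Peak] = field(default_factory=list)

    def __len__(self):
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def __getitem__(self, i):
        return self.peaks[i]

    @property
    def modality(self) -> int:
        return len(self.peaks)


@dataclass
class BimodalSummary:
    """Classified bimodal fast-axis statistics.

    ``theta_b`` is the intrinsic-birefringence peak (perpendicular to the
    fiber long axis), ``theta_c`` the form-birefringence peak (parallel to
    it); either may be None when the distribution is unimodal. ``gamma`` is
    the share of theta_b in the combined peak mass.
    """

    theta_b: float | None
    theta_c: float | None
    peak_b: float
    peak_c: float
    beta_b: float | None
    beta_c: float | None
    gamma: float
    fiber_axis: float
    modality: int

    def to_dict(self) -> dict:
        return {
            "theta_b_deg": self.theta_b,
            "theta_c_deg": self.theta_c,
            "peak_b": self.peak_b,
            "peak_c": self.peak_c,
            "beta_b_deg": self.beta_b,
            "beta_c_deg": self.beta_c,
            "gamma": self.gamma,
            "fiber_axis_deg": self.fiber_axis,
            "modality": self.modality,
        }


def build_fdh(angles, bin_width: float = 1.0) -> AxialHistogram:
    """Bin axial angles (degrees) into a normalized FDH on [0, 180).

    NaN entries (masked pixels) are dropped first. ``bin_width`` must
    divide 180.
    """
    n_bins_f = 180.0 / float(bin_width)
    n_bins = int(round(n_bins_f))
    if n_bins < 1 or abs(n_bins_f - n_bins) > 1e-9:
        raise ValueError(f"bin width {bin_width} must divide 180 deg")
    a = np.asarray(angles, dtype=float).ravel()
    a = a[np.isfinite(a)]
    if a.size == 0:
        raise ValueError("no valid angles to histogram (empty input after masking)")
    edges = np.linspace(0.0, 180.0, n_bins + 1)
    counts, _ = np.histogram(wrap_axial(a), bins=edges)
    return AxialHistogram(
        bin_width=float(bin_width),
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        mass=counts / a.size,
        n_samples=int(a.size),
    )


def smooth_fdh(fdh: AxialHistogram, window: int = 3) -> AxialHistogram:
    """Circular moving-average smoothing (off by default everywhere)."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    kernel = np.ones(window) / window
    padded = np.concatenate([fdh.mass[-(window // 2):], fdh.mass, fdh.mass[: window // 2]])
    smoothed = np.convolve(padded, kernel, mode="valid")
    return AxialHistogram(fdh.bin_width, fdh.bin_centers, smoothed, fdh.n_samples)


def circular_mean(fdh: AxialHistogram) -> float:
    """Axial circular mean of the histogram, in degrees on [0, 180)."""
    phi = np.deg2rad(2.0 * fdh.bin_centers)
    c = np.sum(fdh.mass * np.cos(phi))
    s = np.sum(fdh.mass * np.sin(phi))
    return float(wrap_axial(0.5 * np.degrees(np.arctan2(s, c))))


def beta(fdh: AxialHistogram, peak_angle: float) -> float:
    """Angular FWHM (degrees) of the FDH peak nearest ``peak_angle``.

    Walks circularly left and right from the peak bin to the first
    crossings of half the peak mass, interpolating linearly between bins;
    the result is the angular span between the two crossings. Returns NaN
    when a crossing is not found within 90 deg on a side.
    """
    n = fdh.mass.size
    i0 = int(np.argmin(axial_distance(fdh.bin_centers, peak_angle)))
    h = fdh.mass[i0]
    if h <= 0:
        return float("nan")
    half = 0.5 * h
    max_steps = n // 2

    def _walk(direction: int) -> float | None:
        prev = h
        for step in range(1, max_steps + 1):
            cur = fdh.mass[(i0 + direction * step) % n]
            if cur <= half:
                frac = (prev - half) / (prev - cur) if prev > cur else 1.0
                return (step - 1 + frac) * fdh.bin_width
            prev = cur
        return None

    left = _walk(-1)
    right = _walk(+1)
    if left is None or right is None:
        return float("nan")
    return left + right


def find_peaks(
    fdh: AxialHistogram,
    max_peaks: int = 4,
    min_separation: float = 20.0,
    min_prominence_frac: float = 0.1,
) -> PeakSet:
    """Wraparound-aware local maxima of the FDH, greedily selected by density.

    Candidate peaks must have circular prominence of at least
    ``min_prominence_frac`` times the maximum bin mass; selected peaks are
    pairwise at least ``min_separation`` deg apart (axially) and at most
    ``max_peaks`` are returned, annotated with their beta widths. A flat
    histogram yields an empty PeakSet (modality 0).
    """
    mass = fdh.mass
    n = mass.size
    if n == 0 or np.ptp(mass) == 0:
        return PeakSet([])
    prominence = min_prominence_frac * mass.max()
    tiled = np.tile(mass, 3)
    idx, _ = _scipy_find_peaks(tiled, prominence=prominence)
    idx = np.unique(idx[(idx >= n) & (idx < 2 * n)] - n)
    if idx.size == 0:
        return PeakSet([])
    order = idx[np.argsort(mass[idx])[::-1]]
    selected: list[int] = []
    for i in order:
        angle_i = fdh.bin_centers[i]
        if all(
            axial_distance(angle_i, fdh.bin_centers[j]) >= min_separation
            for j in selected
        ):
            selected.append(int(i))
        if len(selected) == max_peaks:
            break
    peaks = [
        Peak(
            angle=float(fdh.bin_centers[i]),
            density=float(mass[i]),
            beta=beta(fdh, float(fdh.bin_centers[i])),
        )
        for i in selected
    ]
    return PeakSet(peaks)


def gamma(peak_b: float, peak_c: float) -> float:
    """Share of the intrinsic-birefringence peak: peak_b / (peak_b + peak_c)."""
    if peak_b < 0 or peak_c < 0:
        raise ValueError("peak masses must be non-negative")
    total = peak_b + peak_c
    if total == 0:
        raise ValueError("gamma undefined: both peak masses are zero")
    return peak_b / total


def classify_peaks(
    theta_peaks: PeakSet,
    alphaP_fdh: AxialHistogram,
    tie_tol: float = 1e-9,
    **peak_kwargs,
) -> BimodalSummary:
    """Classify fast-axis peaks into theta_b / theta_c using the alphaP FDH.

    The fiber long axis is estimated as the alphaP peak + 90 deg (the
    diattenuation azimuth of aligned cylinders is perpendicular to the
    fiber). The theta peak closer to the fiber axis is the
    form-birefringence peak theta_c; the other (if present) is the
    intrinsic-birefringence peak theta_b. A lone theta peak is assigned by
    a 45 deg distance threshold, giving gamma exactly 0 or 1.

    Raises
    ------
    ClassificationRefused
        When alphaP is not unimodal, when theta has more than two peaks
        (the serial-parallel multi-petal case), or when both theta peaks
        are equidistant from the fiber axis.
    """
    alpha_peaks = find_peaks(alphaP_fdh, **peak_kwargs)
    n_theta = theta_peaks.modality
    n_alpha = alpha_peaks.modality
    if n_alpha != 1:
        raise ClassificationRefused(
            "alphaP distribution is not unimodal", n_theta, n_alpha
        )
    if n_theta == 0:
        raise ClassificationRefused("no theta peaks detected", n_theta, n_alpha)
    if n_theta > 2:
        raise ClassificationRefused(
            "theta distribution is multi-petal", n_theta, n_alpha
        )
    fiber_axis = float(wrap_axial(alpha_peaks[0].angle + 90.0))

    if n_theta == 1:
        p = theta_peaks[0]
        d = axial_distance(p.angle, fiber_axis)
        if abs(d - 45.0) <= tie_tol:
            raise ClassificationRefused(
                "lone theta peak equidistant from fiber axis", n_theta, n_alpha
            )
        if d < 45.0:
            return BimodalSummary(
                theta_b=None, theta_c=p.angle, peak_b=0.0, peak_c=p.density,
                beta_b=None, beta_c=p.beta, gamma=0.0, fiber_axis=fiber_axis,
                modality=1,
            )
        return BimodalSummary(
            theta_b=p.angle, theta_c=None, peak_b=p.density, peak_c=0.0,
            beta_b=p.beta, beta_c=None, gamma=1.0, fiber_axis=fiber_axis,
            modality=1,
        )

    p0, p1 = theta_peaks[0], theta_peaks[1]
    d0 = axial_distance(p0.angle, fiber_axis)
    d1 = axial_distance(p1.angle, fiber_axis)
    if abs(d0 - d1) <= tie_tol:
        raise ClassificationRefused(
            "theta peaks equidistant from fiber axis", n_theta, n_alpha
        )
    pc, pb = (p0, p1) if d0 < d1 else (p1, p0)
    return BimodalSummary(
        theta_b=pb.angle, theta_c=pc.angle, peak_b=pb.density, peak_c=pc.density,
        beta_b=pb.beta, beta_c=pc.beta, gamma=gamma(pb.density, pc.density),
        fiber_axis=fiber_axis, modality=2,
    )


def plot_fdh_polar(fdh: AxialHistogram, ax=None, **kwargs):
    """Minimal polar FDH plot helper (untested convenience surface)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    phi = np.deg2rad(np.concatenate([fdh.bin_centers, fdh.bin_centers + 180.0]))
    r = np.concatenate([fdh.mass, fdh.mass])
    ax.plot(phi, r, **kwargs)
    return ax
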