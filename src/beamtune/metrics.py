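"""Curve metrics: R80, Bragg-peak widths, and lateral FWHM.

All metrics follow the commissioning convention: locate the level crossing
of a fraction of the curve maximum by linear interpolation between the two
bracketing samples.  R80 is the *distal* crossing of 80 % of the peak
maximum (the operational beam range); BPW50/BPW80 are the widths between the
proximal and distal crossings at 50 %/80 % of the maximum; the FWHM of a
lateral profile is the distance between the two half-maximum flank
crossings.

Crossing selection under bin noise: the distal crossing is the outermost one
(robust for a falloff that may wiggle through the level), while flank
crossings for the FWHM and the proximal Bragg-peak crossing are the
innermost ones (nearest the peak).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ExtractionError
from .optics import FWHM_PER_SIGMA

#: Default lateral-profile bin [mm] (scintillator-screen resolution).
DEFAULT_PROFILE_BIN_MM = 0.5


@dataclass(frozen=True)
class LateralProfile:
    """1-D lateral dose profile: strictly increasing offsets, intensity >= 0."""

    offsets: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.offsets, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "offsets", x)
        object.__setattr__(self, "intensity", y)
        if x.ndim != 1 or x.shape != y.shape:
            raise DomainError("offsets and intensity must be 1-D of equal length")
        if x.size < 7:
            raise DomainError(f"profile needs >= 7 samples, got {x.size}")
        if np.any(np.diff(x) <= 0):
            raise DomainError("offsets must be strictly increasing")
        if np.any(y < 0):
            raise DomainError("intensity must be >= 0")


@dataclass(frozen=True)
class IdcMetrics:
    """Extracted descriptors of one depth-dose curve."""

    r80: float
    bpw50: float
    bpw80: float
    peak_depth: float
    peak_value: float

    def __post_init__(self) -> None:
        if not self.bpw50 > self.bpw80 > 0:
            raise DomainError("expected bpw50 > bpw80 > 0")
        if not self.r80 > self.peak_depth:
            raise DomainError("expected r80 beyond the peak")


def _as_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape or x.size < 2:
        raise DomainError("need 1-D x and y of equal length >= 2")
    if np.any(np.diff(x) <= 0):
        raise DomainError("abscissa must be strictly increasing")
    if y.max() <= y.min():
        raise ExtractionError("flat curve: no peak to measure")
    return x, y


def _interp(x0, y0, x1, y1, level) -> float:
    return x0 + (level - y0) / (y1 - y0) * (x1 - x0)


def _distal_crossing(x, y, peak_idx, level, outermost=True) -> float:
    """Downward crossing of ``level`` beyond the peak."""
    hits = []
    for i in range(peak_idx, x.size - 1):
        if y[i] >= level > y[i + 1]:
            hits.append(_interp(x[i], y[i], x[i + 1], y[i + 1], level))
    if not hits:
        raise ExtractionError(
            f"no distal crossing of {level:g}: curve does not fall off"
        )
    return hits[-1] if outermost else hits[0]


def _proximal_crossing(x, y, peak_idx, level) -> float:
    """Innermost upward crossing of ``level`` before the peak."""
    for i in range(peak_idx - 1, -1, -1):
        if y[i] < level <= y[i + 1]:
            return _interp(x[i], y[i], x[i + 1], y[i + 1], level)
    raise ExtractionError(f"no proximal crossing of {level:g} before the peak")


def _curve_arrays(curve_or_x, y=None) -> tuple[np.ndarray, np.ndarray]:
    if y is None:
        return _as_xy(curve_or_x.depths, curve_or_x.dose)
    return _as_xy(curve_or_x, y)


def r80(curve_or_depths, dose=None) -> float:
    """Depth [mm] of the distal 80 %-of-maximum point of a depth-dose curve.

    Accepts a :class:`~beamtune.depth_dose.DepthDoseCurve` or raw
    ``(depths, dose)`` arrays.  Invariant under positive rescaling of the
    dose.  Raises :class:`ExtractionError` when the curve has no distal
    falloff through the level.
    """
    x, yv = _curve_arrays(curve_or_depths, dose)
    peak_idx = int(np.argmax(yv))
    return _distal_crossing(x, yv, peak_idx, 0.8 * yv[peak_idx])


def bragg_peak_width(curve_or_depths, dose=None, level: float = 0.8) -> float:
    """Bragg-peak width [mm] at ``level`` (0.5 or 0.8) of the peak maximum."""
    if not 0.0 < level < 1.0:
        raise DomainError(f"level must lie in (0, 1), got {level}")
    x, yv = _curve_arrays(curve_or_depths, dose)
    peak_idx = int(np.argmax(yv))
    threshold = level * yv[peak_idx]
    distal = _distal_crossing(x, yv, peak_idx, threshold)
    proximal = _proximal_crossing(x, yv, peak_idx, threshold)
    return distal - proximal


def idc_metrics(curve_or_depths, dose=None) -> IdcMetrics:
    """Extract R80, BPW50, BPW80, and peak location in one pass."""
    x, yv = _curve_arrays(curve_or_depths, dose)
    peak_idx = int(np.argmax(yv))
    return IdcMetrics(
        r80=r80(x, yv),
        bpw50=bragg_peak_width(x, yv, level=0.5),
        bpw80=bragg_peak_width(x, yv, level=0.8),
        peak_depth=float(x[peak_idx]),
        peak_value=float(yv[peak_idx]),
    )


def fwhm(profile_or_offsets, intensity=None, estimator: str = "crossings") -> float:
    """Full width at half maximum [mm] of a lateral profile.

    ``estimator`` selects between direct half-maximum crossings (default,
    with linear interpolation) and a least-squares Gaussian fit
    (``"gaussfit"``), mirroring vendor tools that fit the spot intensity.
    For a sampled Gaussian of width sigma both return 2*sqrt(2 ln 2)*sigma.
    """
    if intensity is None and hasattr(profile_or_offsets, "offsets"):
        x, yv = _as_xy(profile_or_offsets.offsets, profile_or_offsets.intensity)
    else:
        x, yv = _as_xy(profile_or_offsets, intensity)
    if estimator == "gaussfit":
        return _fwhm_gaussfit(x, yv)
    if estimator != "crossings":
        raise DomainError(f"unknown FWHM estimator {estimator!r}")
    peak_idx = int(np.argmax(yv))
    half = 0.5 * yv[peak_idx]
    # Innermost crossings: scan outward from the peak on each flank.
    left = None
    for i in range(peak_idx - 1, -1, -1):
        if yv[i] < half <= yv[i + 1]:
            left = _interp(x[i], yv[i], x[i + 1], yv[i + 1], half)
            break
    right = None
    for i in range(peak_idx, x.size - 1):
        if yv[i] >= half > yv[i + 1]:
            right = _interp(x[i], yv[i], x[i + 1], yv[i + 1], half)
            break
    if left is None or right is None:
        raise ExtractionError("profile does not cross half maximum on both flanks")
    return right - left


def _fwhm_gaussfit(x: np.ndarray, y: np.ndarray) -> float:
    from scipy.optimize import curve_fit

    def gauss(u, amp, mu, sig):
        return amp * np.exp(-0.5 * ((u - mu) / sig) ** 2)

    peak_idx = int(np.argmax(y))
    sigma0 = max((x[-1] - x[0]) / 6.0, 1e-3)
    try:
        popt, _ = curve_fit(
            gauss, x, y, p0=[y[peak_idx], x[peak_idx], sigma0], maxfev=10000
        )
    except RuntimeError as exc:  # pragma: no cover - scipy failure path
        raise ExtractionError(f"Gaussian fit failed: {exc}") from exc
    return FWHM_PER_SIGMA * abs(popt[2])


def gaussian_fwhm(sigma: float) -> float:
    """FWHM of a Gaussian of width ``sigma``: 2*sqrt(2 ln 2)*sigma."""
    if sigma < 0:
        raise DomainError("sigma must be >= 0")
    return FWHM_PER_SIGMA * sigma
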