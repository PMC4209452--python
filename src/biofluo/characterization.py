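"""Quantitative depth characterization.

Line profiles along and orthogonal to the capillary, axial-to-depth
mapping through the inclination angle, signal-versus-depth attenuation
curves, FWHM-versus-depth resolution curves, peak-to-background ratios,
detectability depth, and log-linear attenuation-coefficient recovery.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .optical_proc import Image2D

__all__ = [
    "LineProfile",
    "DepthCurve",
    "ProfileError",
    "extract_profile",
    "axial_to_depth",
    "depth_to_axial",
    "estimate_fwhm",
    "attenuation_curve",
    "trim_curve",
    "resolution_curve",
    "peak_background_ratio",
    "detectability_depth",
    "fit_attenuation_coefficient",
]


class ProfileError(ValueError):
    """Raised when a profile cannot be extracted or measured."""


@dataclass
class LineProfile:
    """A 1-D signal profile averaged over a finite width."""

    positions_mm: np.ndarray
    values: np.ndarray
    averaging_width_mm: float
    orientation: str = "axial"
    modality: str = "fluorescence"

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.positions_mm) != len(self.values):
            raise ValueError("positions and values must have equal length")
        if np.any(np.diff(self.positions_mm) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.orientation not in ("axial", "orthogonal"):
            raise ValueError("orientation must be axial or orthogonal")


@dataclass
class DepthCurve:
    """Signal or resolution as a function of capillary depth.

    Signal curves store background-subtracted, max-normalized values in
    ``value`` and the raw (unsubtracted) profile in ``values_raw``.
    """

    depth_mm: np.ndarray
    value: np.ndarray
    value_kind: str
    values_raw: np.ndarray | None = None
    background_mean: float = 0.0
    background_sd: float = 0.0

    def __post_init__(self) -> None:
        self.depth_mm = np.asarray(self.depth_mm, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if len(self.depth_mm) != len(self.value):
            raise ValueError("depth and value must have equal length")
        if np.any(np.diff(self.depth_mm) < 0):
            raise ValueError("depths must be increasing")
        if self.value_kind not in ("signal", "fwhm", "peak_background_ratio"):
            raise ValueError("invalid value_kind")
        if self.values_raw is not None:
            self.values_raw = np.asarray(self.values_raw, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"depth_mm": self.depth_mm, "value": self.value,
             "value_kind": self.value_kind}
        )


def extract_profile(
    image: Image2D,
    start_mm: tuple[float, float],
    end_mm: tuple[float, float],
    width_mm: float = 1.0,
) -> LineProfile:
    """Line profile between two image-plane points (mm).

    Samples every pixel size along the segment; each sample is the mean
    over the nearest odd number of pixels spanning ``width_mm``
    perpendicular to the line, interpolated bilinearly.
    """
    start = np.asarray(start_mm, dtype=float)
    end = np.asarray(end_mm, dtype=float)
    p = image.pixel_size_mm
    length = float(np.linalg.norm(end - start))
    if length <= 0:
        raise ProfileError("degenerate segment")
    direction = (end - start) / length
    normal = np.array([-direction[1], direction[0]])
    if not width_mm > 0:
        raise ProfileError("width_mm must be positive")
    w_px = max(1, 2 * int(round((width_mm / p - 1) / 2)) + 1)
    offsets = (np.arange(w_px) - (w_px - 1) / 2) * p
    n = int(math.floor(length / p)) + 1
    ts = np.arange(n) * p
    pts = start[None, :] + ts[:, None] * direction[None, :]
    samples = pts[None, :, :] + offsets[:, None, None] * normal[None, None, :]
    h, wid = image.pixels.shape
    x = samples[..., 0]
    y = samples[..., 1]
    if x.min() < 0 or y.min() < 0 or x.max() > wid * p or y.max() > h * p:
        raise ProfileError("profile segment (with its averaging width) leaves the image")
    vals = map_coordinates(
        image.pixels, [y.ravel() / p - 0.5, x.ravel() / p - 0.5],
        order=1, mode="nearest",
    ).reshape(w_px, n)
    return LineProfile(ts, vals.mean(axis=0), w_px * p,
                       modality=image.modality)


def axial_to_depth(
    positions_mm: np.ndarray,
    inclination_deg: float,
    entry_axial_mm: float = 0.0,
    entry_depth_mm: float = 0.0,
) -> np.ndarray:
    """Map axial positions to capillary depth through the inclination."""
    if not 0 < inclination_deg < 90:
        raise ValueError("inclination must be strictly between 0 and 90 degrees")
    slope = math.tan(math.radians(inclination_deg))
    return entry_depth_mm + (np.asarray(positions_mm, dtype=float) - entry_axial_mm) * slope


def depth_to_axial(
    depths_mm: np.ndarray,
    inclination_deg: float,
    entry_axial_mm: float = 0.0,
    entry_depth_mm: float = 0.0,
) -> np.ndarray:
    """Exact inverse of :func:`axial_to_depth`."""
    if not 0 < inclination_deg < 90:
        raise ValueError("inclination must be strictly between 0 and 90 degrees")
    slope = math.tan(math.radians(inclination_deg))
    return entry_axial_mm + (np.asarray(depths_mm, dtype=float) - entry_depth_mm) / slope


def _pedestal(values: np.ndarray) -> float:
    """Background pedestal: median of the outer 20% of samples."""
    k = max(1, int(round(0.1 * len(values))))
    return float(np.median(np.concatenate([values[:k], values[-k:]])))


def estimate_fwhm(profile: LineProfile) -> float:
    """Full width at half maximum by linear interpolation of the
    half-maximum crossings on either side of the peak, after pedestal
    subtraction."""
    v = profile.values - _pedestal(profile.values)
    pos = profile.positions_mm
    i = int(np.argmax(v))
    peak = v[i]
    if peak <= v[0] or peak <= v[-1]:
        raise ProfileError("peak is truncated at the profile boundary")
    half = peak / 2.0

    def cross(idx_from: int, step: int) -> float:
        j = idx_from
        while 0 <= j + step < len(v):
            if v[j + step] < half <= v[j]:
                # linear interpolation between j and j+step
                frac = (v[j] - half) / (v[j] - v[j + step])
                return float(pos[j] + frac * (pos[j + step] - pos[j]))
            j += step
        raise ProfileError("no half-maximum crossing found")

    left = cross(i, -1)
    right = cross(i, +1)
    return abs(right - left)


def _track_from_truth(
    truth: pd.DataFrame, image: Image2D
) -> tuple[np.ndarray, np.ndarray, float]:
    """Image-plane (x, y) of the capillary track, plus its entry axial
    position.  The capillary runs along x at constant lateral y."""
    h = image.pixels.shape[0]
    x = truth["axial_mm"].to_numpy()
    y_img = truth["y_mm"].to_numpy() + 0.5 * h * image.pixel_size_mm
    return x, y_img, float(x[0])


def attenuation_curve(
    image: Image2D,
    capillary_truth: pd.DataFrame,
    background_region: tuple[slice, slice],
    *,
    width_mm: float = 1.0,
) -> DepthCurve:
    """Signal-versus-depth curve along the capillary.

    An axial profile is extracted on the capillary track, the mean of
    ``background_region`` is subtracted, positions are converted to
    depth using the ground-truth track, and the curve is normalized so
    its maximum is exactly 1.
    """
    x, y_img, _ = _track_from_truth(capillary_truth, image)
    p = image.pixel_size_mm
    rows = np.clip((y_img / p - 0.5).round().astype(int), 0, image.pixels.shape[0] - 1)
    cols = np.clip((x / p - 0.5).round().astype(int), 0, image.pixels.shape[1] - 1)
    region_mask = np.zeros(image.pixels.shape, dtype=bool)
    region_mask[background_region] = True
    if region_mask[rows, cols].any():
        raise ValueError("background region overlaps the capillary track")
    if not region_mask.any():
        raise ValueError("background region is empty")
    profile = extract_profile(
        image, (x[0], y_img[0]), (x[-1], y_img[-1]), width_mm
    )
    bg = image.pixels[background_region]
    bg_mean = float(bg.mean())
    bg_sd = float(bg.std())
    axial = x[0] + profile.positions_mm
    depths = np.interp(axial, capillary_truth["axial_mm"], capillary_truth["depth_mm"])
    net = profile.values - bg_mean
    peak = net.max()
    if peak <= 0:
        raise ValueError("no signal above background along the capillary")
    return DepthCurve(depths, net / peak, "signal", profile.values, bg_mean, bg_sd)


def trim_curve(curve: DepthCurve, fraction: float = 0.1) -> DepthCurve:
    """Drop a fraction of the depth span at each end of a curve.

    The finite capillary length rounds both ends of the extracted
    profile (axial blur), so slope fits are restricted to the central
    region.
    """
    if not 0 <= fraction < 0.5:
        raise ValueError("fraction must be in [0, 0.5)")
    span = curve.depth_mm[-1] - curve.depth_mm[0]
    lo = curve.depth_mm[0] + fraction * span
    hi = curve.depth_mm[-1] - fraction * span
    keep = (curve.depth_mm >= lo) & (curve.depth_mm <= hi)
    return DepthCurve(
        curve.depth_mm[keep],
        curve.value[keep],
        curve.value_kind,
        None if curve.values_raw is None else curve.values_raw[keep],
        curve.background_mean,
        curve.background_sd,
    )


def resolution_curve(
    image: Image2D,
    capillary_truth: pd.DataFrame,
    depths_mm,
    *,
    width_mm: float = 1.0,
    half_span_mm: float = 4.0,
) -> DepthCurve:
    """FWHM of orthogonal profiles at the requested depths.

    Depths where the FWHM cannot be measured are recorded as NaN gaps
    rather than failing the whole curve.
    """
    depths_mm = np.asarray(depths_mm, dtype=float)
    tmin, tmax = capillary_truth["depth_mm"].min(), capillary_truth["depth_mm"].max()
    if depths_mm.min() < tmin - 1e-9 or depths_mm.max() > tmax + 1e-9:
        raise ValueError("requested depths lie outside the capillary span")
    x, y_img, _ = _track_from_truth(capillary_truth, image)
    fwhms = np.full(len(depths_mm), np.nan)
    for i, d in enumerate(depths_mm):
        ax = float(np.interp(d, capillary_truth["depth_mm"], capillary_truth["axial_mm"]))
        yc = float(np.interp(ax, x, y_img))
        try:
            prof = extract_profile(
                image, (ax, yc - half_span_mm), (ax, yc + half_span_mm), width_mm
            )
            fwhms[i] = estimate_fwhm(prof)
        except ProfileError:
            continue
    order = np.argsort(depths_mm)
    return DepthCurve(depths_mm[order], fwhms[order], "fwhm")


def peak_background_ratio(profile: LineProfile, background_level: float) -> float:
    """Raw (unsubtracted) peak value over the background level."""
    if not background_level > 0:
        raise ValueError("background_level must be positive")
    return float(profile.values.max() / background_level)


def detectability_depth(
    curve: DepthCurve,
    background_mean: float,
    background_sd: float,
    k: float = 3.0,
) -> float:
    """Smallest depth where the raw signal drops below
    ``background_mean + k * background_sd``; ``inf`` if it never does."""
    if curve.value_kind != "signal":
        raise ValueError("detectability needs a signal curve")
    vals = curve.values_raw if curve.values_raw is not None else curve.value
    threshold = background_mean + k * background_sd
    below = vals < threshold
    if not below.any():
        return math.inf
    j = int(np.argmax(below))
    if j == 0:
        return float(curve.depth_mm[0])
    d0, d1 = curve.depth_mm[j - 1], curve.depth_mm[j]
    v0, v1 = vals[j - 1], vals[j]
    if v0 == v1:
        return float(d1)
    frac = (v0 - threshold) / (v0 - v1)
    return float(d0 + frac * (d1 - d0))


def fit_attenuation_coefficient(curve: DepthCurve) -> tuple[float, float, float]:
    """Least-squares line fit to ln(signal) versus depth.

    Returns ``(mu_per_mm, intercept, r_squared)`` with ``mu = -slope``.
    """
    v = curve.value
    if np.any(v <= 0):
        raise ValueError(
            "curve has nonpositive values; subtract the background and "
            "restrict the fit to depths with signal above it"
        )
    logv = np.log(v)
    slope, intercept = np.polyfit(curve.depth_mm, logv, 1)
    pred = slope * curve.depth_mm + intercept
    ss_res = float(np.sum((logv - pred) ** 2))
    ss_tot = float(np.sum((logv - logv.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(-slope), float(intercept), r2
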