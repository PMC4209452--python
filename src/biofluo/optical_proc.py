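"""Planar CCD image processing.

Flat-field (illumination) calibration, hot-pixel median filtering,
exposure checks and exposure-rate normalization for top-view camera
images.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "MODALITIES",
    "Image2D",
    "FlatField",
    "fwhm_to_sigma",
    "sigma_to_fwhm",
    "make_flatfield",
    "apply_flatfield",
    "median_filter_hot_pixels",
    "check_exposure",
    "normalize_rate",
]

MODALITIES = ("photo", "fluorescence", "bioluminescence", "spect_sum", "calibration")

#: FWHM / sigma for a Gaussian, 2*sqrt(2*ln 2).
FWHM_OVER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: Flat-field values at or below this are treated as non-invertible.
FLATFIELD_FLOOR = 1e-6


@dataclass
class Image2D:
    """A planar camera image in detector counts.

    Pixel (0, 0) is the upper-left corner; the centre of pixel
    ``(row, col)`` sits at ``((col + 0.5) * pixel_size_mm,
    (row + 0.5) * pixel_size_mm)`` in image-plane millimetres.
    """

    pixels: np.ndarray
    pixel_size_mm: float
    exposure_s: float
    modality: str
    saturated: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("pixels must be nonnegative")
        if not self.pixel_size_mm > 0:
            raise ValueError("pixel_size_mm must be positive")
        if not self.exposure_s > 0:
            raise ValueError("exposure_s must be positive")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray, **changes) -> "Image2D":
        return replace(self, pixels=np.asarray(pixels, dtype=float), **changes)


@dataclass
class FlatField:
    """Normalized illumination pattern used for flat-field division.

    ``pattern`` has maximum exactly 1 and is strictly positive, so the
    corrected image is pixel-wise >= the input.
    """

    pattern: np.ndarray
    blur_fwhm_mm: float
    source_modality: str

    def __post_init__(self) -> None:
        self.pattern = np.asarray(self.pattern, dtype=float)
        if not np.all(np.isfinite(self.pattern)):
            raise ValueError("flat-field pattern must be finite")
        if np.any(self.pattern <= 0):
            raise ValueError("flat-field pattern must be strictly positive")
        if not np.isclose(self.pattern.max(), 1.0, rtol=0, atol=1e-12):
            raise ValueError("flat-field pattern maximum must be 1")


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Gaussian sigma for a given full width at half maximum."""
    if not fwhm_mm > 0:
        raise ValueError("fwhm must be positive")
    return fwhm_mm / FWHM_OVER_SIGMA


def sigma_to_fwhm(sigma_mm: float) -> float:
    """Inverse of :func:`fwhm_to_sigma`."""
    if not sigma_mm > 0:
        raise ValueError("sigma must be positive")
    return sigma_mm * FWHM_OVER_SIGMA


def make_flatfield(calibration_image: Image2D, blur_fwhm_mm: float) -> FlatField:
    """Build a flat field from a calibration image.

    The calibration image is smoothed with a Gaussian of the given FWHM
    (to suppress small-scale structure of the calibration target itself)
    and rescaled so its maximum is exactly 1.  ``blur_fwhm_mm = 0``
    skips the smoothing step.
    """
    if blur_fwhm_mm < 0:
        raise ValueError("blur_fwhm_mm must be >= 0")
    if blur_fwhm_mm > 0:
        sigma_px = fwhm_to_sigma(blur_fwhm_mm) / calibration_image.pixel_size_mm
        blurred = gaussian_filter(
            calibration_image.pixels, sigma_px, mode="nearest", truncate=4.0
        )
    else:
        blurred = calibration_image.pixels.copy()
    peak = blurred.max()
    if peak <= 0:
        raise ValueError("calibration image is empty after blurring")
    pattern = blurred / peak
    if np.any(pattern <= FLATFIELD_FLOOR):
        raise ValueError(
            "flat field contains values <= floor after blurring; "
            "division would amplify noise unboundedly"
        )
    return FlatField(pattern, blur_fwhm_mm, calibration_image.modality)


def apply_flatfield(image: Image2D, flat: FlatField) -> Image2D:
    """Divide an image by a normalized flat field."""
    if image.pixels.shape != flat.pattern.shape:
        raise ValueError(
            f"shape mismatch: image {image.pixels.shape} vs flat {flat.pattern.shape}"
        )
    return image.with_pixels(image.pixels / flat.pattern)


def median_filter_hot_pixels(image: Image2D, window_px: int = 4) -> Image2D:
    """Median filter with a ``window_px`` x ``window_px`` window.

    The window is anchored so the target pixel sits at position
    ``(ceil(w/2)-1, ceil(w/2)-1)``; even-sized windows therefore use the
    mean of the two central order statistics.  Borders are handled by
    edge replication.
    """
    w = int(window_px)
    if w < 2:
        raise ValueError("window_px must be >= 2")
    h, wid = image.pixels.shape
    if w > min(h, wid):
        raise ValueError("median window larger than image")
    before = (w + 1) // 2 - 1
    after = w - 1 - before
    padded = np.pad(image.pixels, ((before, after), (before, after)), mode="edge")
    windows = np.lib.stride_tricks.sliding_window_view(padded, (w, w))
    return image.with_pixels(np.median(windows, axis=(2, 3)))


def check_exposure(
    image: Image2D, adc_max: int
) -> Literal["ok", "underexposed", "saturated"]:
    """Classify an exposure against the half-ADC rule.

    Saturated if any pixel reaches ``adc_max``; otherwise ok when the
    brightest pixel exceeds half the ADC range, else underexposed.
    """
    peak = image.pixels.max()
    if peak >= adc_max:
        return "saturated"
    if peak > adc_max / 2:
        return "ok"
    return "underexposed"


def normalize_rate(image: Image2D) -> Image2D:
    """Convert counts to counts/s so differing exposures are comparable."""
    return image.with_pixels(image.pixels / image.exposure_s, exposure_s=1.0)
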