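"""Overlay of signal images on the grayscale photograph.

Thresholded colour overlays plus a deterministic, moments-based
similarity registration that replaces manual contour matching between
the emission sum image and the photograph.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from scipy.ndimage import label, map_coordinates

from .optical_proc import Image2D

__all__ = [
    "OverlayImage",
    "SimilarityTransform",
    "threshold_overlay",
    "estimate_alignment",
    "resample_to_grid",
]


@dataclass
class OverlayImage:
    """RGB overlay raster plus the provenance needed to regenerate it."""

    rgb: np.ndarray
    provenance: dict

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb, dtype=float)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be HxWx3")
        if self.rgb.min() < 0 or self.rgb.max() > 1:
            raise ValueError("rgb channels must lie in [0, 1]")

    @property
    def n_colored(self) -> int:
        return int(self.provenance["n_colored"])


@dataclass(frozen=True)
class SimilarityTransform:
    """Maps signal-image mm coordinates onto base-image mm coordinates:
    ``p_base = scale * R(rotation) @ (p_signal - center) + center + translation``.

    Rotating and scaling about ``center_mm`` (rather than the image
    corner) keeps the translation parameter decoupled from small
    rotation errors amplified by a long lever arm.
    """

    scale: float = 1.0
    rotation_deg: float = 0.0
    translation_mm: tuple[float, float] = (0.0, 0.0)
    center_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        th = math.radians(self.rotation_deg)
        c, s = math.cos(th), math.sin(th)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply_xy(self, xy_mm: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy_mm, dtype=float))
        c = np.asarray(self.center_mm)
        return (xy - c) @ self.matrix.T + c + np.asarray(self.translation_mm)

    def inverse(self) -> "SimilarityTransform":
        inv = np.linalg.inv(self.matrix)
        t = -inv @ np.asarray(self.translation_mm)
        return SimilarityTransform(
            1.0 / self.scale, -self.rotation_deg, tuple(t), self.center_mm
        )


def threshold_overlay(
    base: Image2D,
    signal: Image2D,
    threshold_fraction: float,
    colormap: str = "hot",
) -> OverlayImage:
    """Show the signal in colour on the grayscale base above a threshold.

    Pixels with signal below ``threshold_fraction`` of the signal
    maximum show the grayscale base; the rest are colormapped.  A
    threshold of 0 colours every pixel with positive signal.
    """
    if base.pixels.shape != signal.pixels.shape:
        raise ValueError("base and signal must share a grid")
    if not 0 <= threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in [0, 1)")
    base_max = base.pixels.max()
    gray = base.pixels / base_max if base_max > 0 else np.zeros_like(base.pixels)
    rgb = np.repeat(gray[:, :, None], 3, axis=2)
    sig_max = signal.pixels.max()
    if sig_max > 0:
        norm = signal.pixels / sig_max
        if threshold_fraction == 0:
            mask = signal.pixels > 0
        else:
            mask = norm >= threshold_fraction
        colors = colormaps[colormap](norm)[:, :, :3]
        rgb[mask] = colors[mask]
    else:
        mask = np.zeros(base.pixels.shape, dtype=bool)
    prov = {
        "base_modality": base.modality,
        "signal_modality": signal.modality,
        "threshold_fraction": float(threshold_fraction),
        "colormap": colormap,
        "n_colored": int(mask.sum()),
    }
    return OverlayImage(np.clip(rgb, 0.0, 1.0), prov)


def _mask_moments(image: Image2D, threshold_frac: float):
    """Largest connected component above a fraction of the maximum;
    returns (centroid_mm, orientation_rad, area_mm2)."""
    peak = image.pixels.max()
    if peak <= 0:
        raise ValueError("empty foreground mask")
    mask = image.pixels >= threshold_frac * peak
    labels, n = label(mask)
    if n == 0:
        raise ValueError("empty foreground mask")
    sizes = np.bincount(labels.ravel())[1:]
    mask = labels == (int(np.argmax(sizes)) + 1)
    rows, cols = np.nonzero(mask)
    p = image.pixel_size_mm
    x = (cols + 0.5) * p
    y = (rows + 0.5) * p
    cx, cy = x.mean(), y.mean()
    dx, dy = x - cx, y - cy
    mu20 = np.mean(dx * dx)
    mu02 = np.mean(dy * dy)
    mu11 = np.mean(dx * dy)
    theta = 0.5 * math.atan2(2.0 * mu11, mu20 - mu02)
    area = mask.sum() * p * p
    return np.array([cx, cy]), theta, area


def estimate_alignment(
    signal: Image2D,
    base: Image2D,
    *,
    mask_threshold_frac: float = 0.2,
) -> SimilarityTransform:
    """Similarity transform mapping the signal image onto the base image.

    Both images must contain one dominant foreground object; the scale
    comes from the mask area ratio, the rotation from the principal-axis
    angle difference, the translation from the centroid offset.
    """
    c_sig, th_sig, a_sig = _mask_moments(signal, mask_threshold_frac)
    c_base, th_base, a_base = _mask_moments(base, mask_threshold_frac)
    scale = math.sqrt(a_base / a_sig)
    dth = th_base - th_sig
    # principal axes are only defined modulo pi
    dth = (dth + math.pi / 2) % math.pi - math.pi / 2
    h, w = base.pixels.shape
    center = (0.5 * w * base.pixel_size_mm, 0.5 * h * base.pixel_size_mm)
    tf = SimilarityTransform(scale, math.degrees(dth), (0.0, 0.0), center)
    t = c_base - tf.apply_xy(c_sig)[0]
    return SimilarityTransform(
        scale, math.degrees(dth), (float(t[0]), float(t[1])), center
    )


def resample_to_grid(
    image: Image2D, transform: SimilarityTransform, target: Image2D
) -> Image2D:
    """Resample an image through a similarity transform onto the target
    grid with bilinear interpolation; out-of-field pixels are zero."""
    h, w = target.pixels.shape
    p = target.pixel_size_mm
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    xy_base = np.column_stack(
        [((cols + 0.5) * p).ravel(), ((rows + 0.5) * p).ravel()]
    )
    xy_src = transform.inverse().apply_xy(xy_base)
    src_cols = xy_src[:, 0] / image.pixel_size_mm - 0.5
    src_rows = xy_src[:, 1] / image.pixel_size_mm - 0.5
    out = map_coordinates(
        image.pixels, [src_rows, src_cols], order=1, mode="constant", cval=0.0
    ).reshape(h, w)
    return Image2D(
        np.maximum(out, 0.0), p, image.exposure_s, image.modality, image.saturated
    )
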