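"""Digital phantom and acquisition simulator.

A tissue-simulating gel cylinder with an obliquely inserted capillary
(uniformly filled with a fluorescent dye plus a gamma emitter) is the
scene; this module renders top-view CCD images (photo, bioluminescence,
fluorescence, illumination calibration) and draws list-mode gamma
events from it, exporting ground truth for every quantity the
downstream pipeline estimates.

Coordinates: the bed plane is (x axial, y lateral), z is depth below
the gel top surface, all in millimetres.  The gel cylinder lies along
x with its axis at (y = 0, z = gel_radius).  Camera images follow the
:class:`~biofluo.optical_proc.Image2D` convention with image columns
along x (``x_img = x``) and rows along y centred on the bed
(``y_img = y + H * pixel_size / 2``).
"""
from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .optical_proc import Image2D
from .spect_proc import EventList

__all__ = [
    "PhantomSpec",
    "CameraModel",
    "IlluminationField",
    "AcquisitionSpec",
    "GeometryError",
    "substream",
    "ground_truth_capillary",
    "phantom_to_image_xy",
    "image_to_phantom_xy",
    "default_image_shape",
    "render_point_sources",
    "render_fluorescence",
    "render_bioluminescence",
    "render_photo",
    "render_calibration",
    "apply_ccd_noise",
    "capillary_volume_mL",
    "simulate_listmode",
]


class GeometryError(ValueError):
    """Raised when the capillary centreline leaves the gel."""


def substream(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage random stream derived from one seed."""
    return np.random.default_rng([int(seed), zlib.crc32(stage.encode())])


@dataclass
class PhantomSpec:
    """Parametric description of the gel phantom and capillary source.

    Optical tissue properties (the agarose/hemoglobin recipe) enter only
    through the effective attenuation coefficients and the depth-blur
    parameters.
    """

    gel_radius_mm: float = 13.0
    gel_length_mm: float = 45.0
    capillary_inner_diameter_mm: float = 0.9
    capillary_fill_length_mm: float = 30.0
    inclination_deg: float = 25.0
    entry_point_mm: tuple[float, float, float] = (5.0, 0.0, 1.0)
    dye_concentration_uM: float = 150.0
    activity_MBq_per_mL: float = 2.0
    mu_ex_per_mm: float = 0.05
    mu_em_per_mm: float = 0.03
    blur_sigma0_mm: float = 0.45
    blur_growth_per_mm: float = 0.06
    background_fraction: float = 0.02

    @property
    def mu_total_per_mm(self) -> float:
        return self.mu_ex_per_mm + self.mu_em_per_mm

    def validate(self) -> None:
        for name in (
            "gel_radius_mm",
            "gel_length_mm",
            "capillary_inner_diameter_mm",
            "capillary_fill_length_mm",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "dye_concentration_uM",
            "activity_MBq_per_mL",
            "mu_ex_per_mm",
            "mu_em_per_mm",
            "blur_sigma0_mm",
            "blur_growth_per_mm",
            "background_fraction",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 < self.inclination_deg < 90:
            raise ValueError("inclination_deg must be strictly between 0 and 90")
        self._check_containment()

    def _centerline(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Centreline point at distance ``t`` along the capillary."""
        theta = math.radians(self.inclination_deg)
        x0, y0, z0 = self.entry_point_mm
        return (
            x0 + t * math.cos(theta),
            np.full_like(np.asarray(t, dtype=float), y0),
            z0 + t * math.sin(theta),
        )

    def _check_containment(self, n: int = 257) -> None:
        t = np.linspace(0.0, self.capillary_fill_length_mm, n)
        x, y, z = self._centerline(t)
        r = self.gel_radius_mm
        inside = (
            (x >= 0)
            & (x <= self.gel_length_mm)
            & (z >= 0)
            & (y**2 + (z - r) ** 2 <= r**2 + 1e-9)
        )
        if not inside.all():
            raise GeometryError(
                "capillary centreline exits the gel within the fill length"
            )


@dataclass
class CameraModel:
    """CCD response model for the top-view camera."""

    pixel_size_mm: float = 0.36
    read_noise_counts: float = 2.0
    dark_current_counts_per_px_s: float = 0.006
    adc_max_counts: int = 65535
    hot_pixel_rate_per_px_s: float = 0.0
    quantum_scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.pixel_size_mm > 0:
            raise ValueError("pixel_size_mm must be positive")
        if self.read_noise_counts < 0 or self.dark_current_counts_per_px_s < 0:
            raise ValueError("noise parameters must be nonnegative")
        if self.adc_max_counts < 1:
            raise ValueError("adc_max_counts must be >= 1")
        if self.hot_pixel_rate_per_px_s < 0:
            raise ValueError("hot_pixel_rate_per_px_s must be nonnegative")
        if not self.quantum_scale > 0:
            raise ValueError("quantum_scale must be positive")


@dataclass
class IlluminationField:
    """Smooth strictly-positive illumination pattern on the bed grid."""

    pattern: np.ndarray

    def __post_init__(self) -> None:
        self.pattern = np.asarray(self.pattern, dtype=float)
        if self.pattern.ndim != 2:
            raise ValueError("pattern must be 2-D")
        if not np.all(np.isfinite(self.pattern)) or np.any(self.pattern <= 0):
            raise ValueError("pattern must be finite and strictly positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pattern.shape  # type: ignore[return-value]

    @classmethod
    def flat(cls, shape: tuple[int, int], value: float = 1.0) -> "IlluminationField":
        return cls(np.full(shape, value))

    @classmethod
    def vignette(
        cls, shape: tuple[int, int], strength: float = 0.5
    ) -> "IlluminationField":
        """Radial fall-off to ``1 - strength`` at the farthest corner."""
        if not 0 <= strength < 1:
            raise ValueError("strength must be in [0, 1)")
        h, w = shape
        rr, cc = np.mgrid[0:h, 0:w]
        r2 = ((rr - (h - 1) / 2) ** 2 + (cc - (w - 1) / 2) ** 2)
        return cls(1.0 - strength * r2 / r2.max())

    def sample(self, x_img_mm: np.ndarray, y_img_mm: np.ndarray, pixel_size_mm: float) -> np.ndarray:
        rows = np.asarray(y_img_mm) / pixel_size_mm - 0.5
        cols = np.asarray(x_img_mm) / pixel_size_mm - 0.5
        return map_coordinates(self.pattern, [rows, cols], order=1, mode="nearest")


@dataclass
class AcquisitionSpec:
    """Gamma acquisition settings for the toy parallel-beam camera."""

    exposure_s: float = 60.0
    n_angles: int = 16
    detector_bins: tuple[int, int] = (80, 96)
    photopeak_keV: float = 140.0
    energy_resolution_fwhm_frac: float = 0.10
    scatter_fraction: float = 0.0
    sensitivity_counts_per_MBq_s: float = 1.0e5
    seed: int = 0
    detector_sigma_mm: float = 0.3
    scatter_band_frac: tuple[float, float] = (0.55, 1.10)
    scatter_spatial_sigma_mm: float = 3.0

    def __post_init__(self) -> None:
        if not self.exposure_s > 0:
            raise ValueError("exposure_s must be positive")
        if self.n_angles < 1:
            raise ValueError("n_angles must be >= 1")
        if min(self.detector_bins) < 1:
            raise ValueError("detector_bins must be positive")
        if not self.photopeak_keV > 0:
            raise ValueError("photopeak_keV must be positive")
        if not 0 < self.energy_resolution_fwhm_frac < 1:
            raise ValueError("energy_resolution_fwhm_frac must be in (0, 1)")
        if not 0 <= self.scatter_fraction < 1:
            raise ValueError("scatter_fraction must be in [0, 1)")
        if not self.sensitivity_counts_per_MBq_s > 0:
            raise ValueError("sensitivity must be positive")
        lo, hi = self.scatter_band_frac
        if not 0 < lo < hi:
            raise ValueError("scatter_band_frac must satisfy 0 < lo < hi")


def ground_truth_capillary(
    spec: PhantomSpec, n_samples: int, *, validate: bool = True
) -> pd.DataFrame:
    """Sampled capillary centreline with exact depth per axial position.

    Depth grows linearly with axial position at rate tan(inclination).
    ``validate=False`` bypasses the full spec validation (the geometry
    containment check always runs) so degenerate test geometries such as
    a horizontal capillary can still be tabulated.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if validate:
        spec.validate()
    else:
        spec._check_containment()
    t = np.linspace(0.0, spec.capillary_fill_length_mm, n_samples)
    x, y, z = spec._centerline(t)
    df = pd.DataFrame(
        {"axial_mm": x, "depth_mm": z, "x_mm": x, "y_mm": y, "z_mm": z}
    )
    return df.sort_values("axial_mm", ignore_index=True)


def phantom_to_image_xy(
    x_mm: np.ndarray, y_mm: np.ndarray, shape: tuple[int, int], pixel_size_mm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Bed coordinates -> image-plane mm (rows centred on the bed axis)."""
    h = shape[0]
    return np.asarray(x_mm, dtype=float), np.asarray(y_mm, dtype=float) + 0.5 * h * pixel_size_mm


def image_to_phantom_xy(
    x_img_mm: np.ndarray, y_img_mm: np.ndarray, shape: tuple[int, int], pixel_size_mm: float
) -> tuple[np.ndarray, np.ndarray]:
    h = shape[0]
    return np.asarray(x_img_mm, dtype=float), np.asarray(y_img_mm, dtype=float) - 0.5 * h * pixel_size_mm


def default_image_shape(
    spec: PhantomSpec, pixel_size_mm: float, margin_mm: float = 3.0
) -> tuple[int, int]:
    h = int(math.ceil(2 * (spec.gel_radius_mm + margin_mm) / pixel_size_mm))
    w = int(math.ceil((spec.gel_length_mm + 2 * margin_mm) / pixel_size_mm))
    return h, w


def render_point_sources(
    points_xy_mm: np.ndarray,
    amplitudes: np.ndarray,
    sigmas_mm: np.ndarray,
    shape: tuple[int, int],
    pixel_size_mm: float,
    *,
    normalize: bool = False,
) -> np.ndarray:
    """Splat Gaussian sources onto an image grid.

    With ``normalize=False`` the amplitudes are peak values (a source
    exactly on a pixel centre contributes its amplitude to that pixel).
    With ``normalize=True`` the kernel is a unit-integral 2-D Gaussian,
    so each amplitude is the total count deposited and blurring
    conserves energy.  A sigma below a tenth of a pixel collapses to a
    nearest-pixel impulse.
    """
    points = np.atleast_2d(np.asarray(points_xy_mm, dtype=float))
    amps = np.broadcast_to(np.asarray(amplitudes, dtype=float), (len(points),))
    sigmas = np.broadcast_to(np.asarray(sigmas_mm, dtype=float), (len(points),))
    h, w = shape
    p = pixel_size_mm
    img = np.zeros((h, w))
    xs = (np.arange(w) + 0.5) * p
    ys = (np.arange(h) + 0.5) * p
    for (x, y), a, s in zip(points, amps, sigmas):
        if s < 0.1 * p:
            col = min(max(int(x / p), 0), w - 1)
            row = min(max(int(y / p), 0), h - 1)
            img[row, col] += a
            continue
        half = 4.0 * s
        c0 = max(0, int((x - half) / p))
        c1 = min(w, int((x + half) / p) + 1)
        r0 = max(0, int((y - half) / p))
        r1 = min(h, int((y + half) / p) + 1)
        if c0 >= c1 or r0 >= r1:
            continue
        gx = np.exp(-((xs[c0:c1] - x) ** 2) / (2 * s * s))
        gy = np.exp(-((ys[r0:r1] - y) ** 2) / (2 * s * s))
        scale = a * p * p / (2 * np.pi * s * s) if normalize else a
        img[r0:r1, c0:c1] += scale * gy[:, None] * gx[None, :]
    return img


def apply_ccd_noise(
    expected: np.ndarray,
    cam: CameraModel,
    exposure_s: float,
    rng: np.random.Generator,
    *,
    activity_scale: float = 0.0,
) -> np.ndarray:
    """Poisson shot noise + Gaussian read noise + hot pixels, clipped to
    the ADC range.  ``expected`` must already include the dark signal.

    Hot pixels model gamma absorption events in the CCD, so their rate
    scales with the activity present (``activity_scale``).
    """
    img = rng.poisson(np.maximum(expected, 0.0)).astype(float)
    if cam.read_noise_counts > 0:
        img += rng.normal(0.0, cam.read_noise_counts, img.shape)
    lam = cam.hot_pixel_rate_per_px_s * activity_scale * exposure_s * img.size
    if lam > 0:
        n_hot = rng.poisson(lam)
        if n_hot:
            rows = rng.integers(0, img.shape[0], n_hot)
            cols = rng.integers(0, img.shape[1], n_hot)
            amps = rng.uniform(0.5, 1.0, n_hot) * cam.adc_max_counts
            img[rows, cols] = np.maximum(img[rows, cols], amps)
    return np.clip(img, 0.0, cam.adc_max_counts)


def _capillary_image(
    spec: PhantomSpec,
    cam: CameraModel,
    shape: tuple[int, int],
    exposure_s: float,
    mu_per_mm: float,
    illum: IlluminationField | None,
    source_strength: float,
) -> np.ndarray:
    """Noiseless expected capillary signal on the image grid."""
    n_src = max(2, int(math.ceil(spec.capillary_fill_length_mm / (cam.pixel_size_mm / 2))) + 1)
    truth = ground_truth_capillary(spec, n_src, validate=False)
    dl = spec.capillary_fill_length_mm / (n_src - 1)
    x_img, y_img = phantom_to_image_xy(
        truth["x_mm"].to_numpy(), truth["y_mm"].to_numpy(), shape, cam.pixel_size_mm
    )
    weight = np.ones(n_src)
    weight[[0, -1]] = 0.5  # trapezoidal line integral
    illum_at_src = (
        illum.sample(x_img, y_img, cam.pixel_size_mm) if illum is not None else 1.0
    )
    z = truth["z_mm"].to_numpy()
    amps = (
        source_strength
        * cam.quantum_scale
        * exposure_s
        * dl
        * weight
        * illum_at_src
        * np.exp(-mu_per_mm * z)
    )
    sigmas = spec.blur_sigma0_mm + spec.blur_growth_per_mm * z
    points = np.column_stack([x_img, y_img])
    return render_point_sources(
        points, amps, sigmas, shape, cam.pixel_size_mm, normalize=True
    )


def render_fluorescence(
    spec: PhantomSpec,
    cam: CameraModel,
    illum: IlluminationField,
    acq: AcquisitionSpec,
    *,
    noise: bool = True,
    rng: np.random.Generator | None = None,
) -> Image2D:
    """Top-view fluorescence image.

    Each capillary source element at depth z is attenuated by
    ``exp(-(mu_ex + mu_em) z)``, blurred with a Gaussian of sigma
    ``blur_sigma0 + blur_growth * z`` and weighted by the local
    illumination; a flat ``background_fraction`` of the unattenuated
    peak, shaped by the illumination pattern, models excitation leakage
    plus autofluorescence.
    """
    spec.validate()
    shape = illum.shape
    signal = _capillary_image(
        spec, cam, shape, acq.exposure_s, spec.mu_total_per_mm, illum,
        spec.dye_concentration_uM,
    )
    expected = signal
    if spec.background_fraction > 0 and spec.dye_concentration_uM > 0:
        unattenuated = _capillary_image(
            spec, cam, shape, acq.exposure_s, 0.0, illum, spec.dye_concentration_uM
        )
        level = spec.background_fraction * unattenuated.max()
        expected = expected + level * illum.pattern / illum.pattern.max()
    expected = expected + cam.dark_current_counts_per_px_s * acq.exposure_s
    if noise:
        rng = rng if rng is not None else substream(acq.seed, "fluorescence")
        pixels = apply_ccd_noise(
            expected, cam, acq.exposure_s, rng,
            activity_scale=spec.activity_MBq_per_mL,
        )
    else:
        pixels = np.clip(expected, 0.0, cam.adc_max_counts)
    return Image2D(pixels, cam.pixel_size_mm, acq.exposure_s, "fluorescence",
                   saturated=bool(pixels.max() >= cam.adc_max_counts))


def render_bioluminescence(
    source: PhantomSpec | np.ndarray,
    cam: CameraModel,
    acq: AcquisitionSpec,
    *,
    shape: tuple[int, int] | None = None,
    noise: bool = True,
    rng: np.random.Generator | None = None,
) -> Image2D:
    """Top-view bioluminescence image: no excitation light, no leakage
    background, only emission attenuation.

    ``source`` is either a phantom spec (the capillary emits) or an
    explicit expected-rate map in counts/s per pixel.
    """
    activity = 0.0
    if isinstance(source, PhantomSpec):
        source.validate()
        if shape is None:
            shape = default_image_shape(source, cam.pixel_size_mm)
        expected = _capillary_image(
            source, cam, shape, acq.exposure_s, source.mu_em_per_mm, None,
            source.dye_concentration_uM,
        )
        activity = source.activity_MBq_per_mL
    else:
        rate_map = np.asarray(source, dtype=float)
        if shape is not None and rate_map.shape != tuple(shape):
            raise ValueError("shape disagrees with the source map")
        expected = rate_map * acq.exposure_s
    expected = expected + cam.dark_current_counts_per_px_s * acq.exposure_s
    if noise:
        rng = rng if rng is not None else substream(acq.seed, "bioluminescence")
        pixels = apply_ccd_noise(expected, cam, acq.exposure_s, rng,
                                 activity_scale=activity)
    else:
        pixels = np.clip(expected, 0.0, cam.adc_max_counts)
    return Image2D(pixels, cam.pixel_size_mm, acq.exposure_s, "bioluminescence",
                   saturated=bool(pixels.max() >= cam.adc_max_counts))


def _reflectance_map(
    spec: PhantomSpec, shape: tuple[int, int], pixel_size_mm: float,
    gel: float = 0.85, bed: float = 0.15,
) -> np.ndarray:
    h, w = shape
    xs = (np.arange(w) + 0.5) * pixel_size_mm
    ys = (np.arange(h) + 0.5) * pixel_size_mm
    x_ph, y_ph = image_to_phantom_xy(*np.meshgrid(xs, ys), shape, pixel_size_mm)
    footprint = (np.abs(y_ph) <= spec.gel_radius_mm) & (x_ph >= 0) & (x_ph <= spec.gel_length_mm)
    return np.where(footprint, gel, bed)


def render_photo(
    spec: PhantomSpec,
    cam: CameraModel,
    illum: IlluminationField,
    exposure_s: float,
    *,
    brightness_counts_per_s: float = 2.0e4,
    noise: bool = True,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> Image2D:
    """White-light photograph: reflectance times illumination."""
    spec.validate()
    if not exposure_s > 0:
        raise ValueError("exposure_s must be positive")
    refl = _reflectance_map(spec, illum.shape, cam.pixel_size_mm)
    expected = refl * illum.pattern * brightness_counts_per_s * exposure_s
    expected = expected + cam.dark_current_counts_per_px_s * exposure_s
    if noise:
        rng = rng if rng is not None else substream(seed, "photo")
        pixels = apply_ccd_noise(expected, cam, exposure_s, rng)
    else:
        pixels = np.clip(expected, 0.0, cam.adc_max_counts)
    return Image2D(pixels, cam.pixel_size_mm, exposure_s, "photo",
                   saturated=bool(pixels.max() >= cam.adc_max_counts))


def render_calibration(
    cam: CameraModel,
    illum: IlluminationField,
    exposure_s: float,
    *,
    brightness_counts_per_s: float = 2.0e4,
    noise: bool = True,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> Image2D:
    """Image of a uniform white sheet: the illumination pattern itself."""
    expected = illum.pattern * brightness_counts_per_s * exposure_s
    expected = expected + cam.dark_current_counts_per_px_s * exposure_s
    if noise:
        rng = rng if rng is not None else substream(seed, "calibration")
        pixels = apply_ccd_noise(expected, cam, exposure_s, rng)
    else:
        pixels = np.clip(expected, 0.0, cam.adc_max_counts)
    return Image2D(pixels, cam.pixel_size_mm, exposure_s, "calibration",
                   saturated=bool(pixels.max() >= cam.adc_max_counts))


def capillary_volume_mL(spec: PhantomSpec) -> float:
    r = spec.capillary_inner_diameter_mm / 2.0
    return math.pi * r * r * spec.capillary_fill_length_mm / 1000.0


def simulate_listmode(
    spec: PhantomSpec,
    acq: AcquisitionSpec,
    *,
    rng: np.random.Generator | None = None,
) -> EventList:
    """Draw list-mode gamma events from the capillary source.

    The expected number of primaries is activity x capillary volume x
    sensitivity x exposure; scatter events add a further
    ``scatter_fraction`` of the total, drawn from a flat continuum
    (``scatter_band_frac`` x photopeak) with extra spatial blur.  Gamma
    self-attenuation in the gel is deliberately omitted.
    """
    spec.validate()
    rng = rng if rng is not None else substream(acq.seed, "listmode")
    n_primary_expected = (
        spec.activity_MBq_per_mL
        * capillary_volume_mL(spec)
        * acq.sensitivity_counts_per_MBq_s
        * acq.exposure_s
    )
    n_primary = int(rng.poisson(n_primary_expected)) if n_primary_expected > 0 else 0
    sf = acq.scatter_fraction
    n_scatter_expected = n_primary_expected * sf / (1.0 - sf) if sf > 0 else 0.0
    n_scatter = int(rng.poisson(n_scatter_expected)) if n_scatter_expected > 0 else 0
    n = n_primary + n_scatter
    if n == 0:
        empty = np.empty(0)
        return EventList(empty, empty, empty, empty, acq.n_angles,
                         np.empty(0, dtype=bool))

    t = rng.uniform(0.0, spec.capillary_fill_length_mm, n)
    x, y, z = spec._centerline(t)
    angle = rng.integers(0, acq.n_angles, n)
    phi = angle * np.pi / acq.n_angles
    u = y * np.cos(phi) + (z - spec.gel_radius_mm) * np.sin(phi)
    v = x.copy()
    if acq.detector_sigma_mm > 0:
        u = u + rng.normal(0.0, acq.detector_sigma_mm, n)
        v = v + rng.normal(0.0, acq.detector_sigma_mm, n)
    is_scatter = np.zeros(n, dtype=bool)
    is_scatter[n_primary:] = True
    if n_scatter and acq.scatter_spatial_sigma_mm > 0:
        u[n_primary:] += rng.normal(0.0, acq.scatter_spatial_sigma_mm, n_scatter)
        v[n_primary:] += rng.normal(0.0, acq.scatter_spatial_sigma_mm, n_scatter)

    sigma_e = acq.photopeak_keV * acq.energy_resolution_fwhm_frac / (
        2.0 * math.sqrt(2.0 * math.log(2.0))
    )
    energy = np.empty(n)
    energy[:n_primary] = rng.normal(acq.photopeak_keV, sigma_e, n_primary)
    lo, hi = acq.scatter_band_frac
    energy[n_primary:] = rng.uniform(
        lo * acq.photopeak_keV, hi * acq.photopeak_keV, n_scatter
    )
    energy = np.maximum(energy, 1e-3)

    order = rng.permutation(n)
    return EventList(
        angle[order], u[order], v[order], energy[order], acq.n_angles,
        is_scatter[order],
    )
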