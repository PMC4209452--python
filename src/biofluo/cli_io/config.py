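"""Run configuration: namespaced, schema-validated, unknown keys rejected."""
from __future__ import annotations

import tomllib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from ..phantom_sim import AcquisitionSpec, CameraModel, IlluminationField, PhantomSpec

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomCfg(_Strict):
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

    def to_spec(self) -> PhantomSpec:
        return PhantomSpec(**self.model_dump())


class CameraCfg(_Strict):
    pixel_size_mm: float = 0.36
    read_noise_counts: float = 2.0
    dark_current_counts_per_px_s: float = 0.006
    adc_max_counts: int = 65535
    hot_pixel_rate_per_px_s: float = 2e-6
    quantum_scale: float = 50.0

    def to_model(self) -> CameraModel:
        return CameraModel(**self.model_dump())


class IlluminationCfg(_Strict):
    kind: str = "vignette"  # flat | vignette
    vignette_strength: float = 0.5

    def to_field(self, shape: tuple[int, int]) -> IlluminationField:
        if self.kind == "flat":
            return IlluminationField.flat(shape)
        if self.kind == "vignette":
            return IlluminationField.vignette(shape, self.vignette_strength)
        raise ValueError(f"unknown illumination kind {self.kind!r}")


class AcquisitionCfg(_Strict):
    exposure_s: float = 60.0
    n_angles: int = 16
    detector_bins: tuple[int, int] = (80, 96)
    photopeak_keV: float = 140.0
    energy_resolution_fwhm_frac: float = 0.10
    scatter_fraction: float = 0.3
    sensitivity_counts_per_MBq_s: float = 1.0e5
    detector_sigma_mm: float = 0.3
    scatter_band_frac: tuple[float, float] = (0.55, 1.10)

    def to_spec(self, seed: int) -> AcquisitionSpec:
        return AcquisitionSpec(seed=seed, **self.model_dump())


class OpticalCfg(_Strict):
    photo_exposure_s: float = 0.05
    fluor_exposure_s: float = 0.5
    biolum_exposure_s: float = 60.0
    calib_exposure_s: float = 0.5
    photo_brightness_counts_per_s: float = 2.0e4


class ProcessingCfg(_Strict):
    flatfield_fwhm_mm: float = 7.30
    median_window_px: int = 4
    window_fraction: float = 0.2
    bg_window_lo_keV: tuple[float, float] = (110.0, 124.0)
    bg_window_hi_keV: tuple[float, float] = (156.0, 170.0)
    subsets: int = 16
    iterations: int = 6
    postfilter_fwhm_mm: float = 1.18
    recon_voxel_mm: float = 0.5
    recon_ny: int = 56
    recon_nz: int = 56


class CharacterizationCfg(_Strict):
    profile_width_mm: float = 1.0
    # wide averaging for the attenuation fit so the depth-dependent blur
    # does not change the captured fraction of the ridge cross-section
    attenuation_width_mm: float = 8.0
    n_depths: int = 6
    detect_k: float = 3.0
    fit_floor_frac: float = 0.05
    overlay_threshold: float = 0.3
    overlay_colormap: str = "hot"


class RunConfig(_Strict):
    """Top-level run configuration with per-stage namespaces."""

    seed: int = 0
    phantom: PhantomCfg = Field(default_factory=PhantomCfg)
    camera: CameraCfg = Field(default_factory=CameraCfg)
    illumination: IlluminationCfg = Field(default_factory=IlluminationCfg)
    acquisition: AcquisitionCfg = Field(default_factory=AcquisitionCfg)
    optical: OpticalCfg = Field(default_factory=OpticalCfg)
    processing: ProcessingCfg = Field(default_factory=ProcessingCfg)
    characterization: CharacterizationCfg = Field(default_factory=CharacterizationCfg)


def load_config(path) -> RunConfig:
    """Load a TOML or YAML config file (by extension)."""
    path = Path(path)
    if path.suffix == ".toml":
        data = tomllib.loads(path.read_text())
    else:
        data = yaml.safe_load(path.read_text()) or {}
    return RunConfig.model_validate(data)
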