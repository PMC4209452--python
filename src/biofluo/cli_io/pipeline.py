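"""End-to-end run: simulate, calibrate, reconstruct, fuse, characterize.

Every stage draws its randomness from a named substream of the single
run seed, so reruns with the same config are reproducible and stages
can be rerun in isolation.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .. import __version__
from ..characterization import (
    DepthCurve,
    attenuation_curve,
    trim_curve,
    detectability_depth,
    extract_profile,
    fit_attenuation_coefficient,
    peak_background_ratio,
    resolution_curve,
)
from ..fusion import SimilarityTransform, resample_to_grid, threshold_overlay
from ..optical_proc import (
    apply_flatfield,
    check_exposure,
    make_flatfield,
    median_filter_hot_pixels,
)
from ..phantom_sim import (
    default_image_shape,
    ground_truth_capillary,
    render_bioluminescence,
    render_calibration,
    render_fluorescence,
    render_photo,
    simulate_listmode,
    substream,
)
from ..spect_proc import (
    bin_events,
    gaussian_postfilter,
    make_geometry,
    osem_reconstruct,
    photopeak_window,
    subtract_scatter,
    sum_projection,
    tew_scatter_estimate,
    EnergyWindow,
)
from .config import RunConfig
from .io import write_events, write_image, write_volume

log = logging.getLogger("biofluo")

__all__ = ["run_pipeline", "filter_curve_floor", "spect_geometry"]


def filter_curve_floor(curve: DepthCurve, floor_frac: float) -> DepthCurve:
    """Restrict a signal curve to depths with normalized value above a
    floor, so a log-linear fit stays well defined."""
    keep = curve.value > floor_frac
    return DepthCurve(
        curve.depth_mm[keep],
        curve.value[keep],
        curve.value_kind,
        None if curve.values_raw is None else curve.values_raw[keep],
        curve.background_mean,
        curve.background_sd,
    )


def spect_geometry(config: RunConfig):
    """Binning geometry centred on the gel axis."""
    nu, nv = config.acquisition.detector_bins
    return make_geometry(
        config.acquisition.n_angles,
        nu,
        nv,
        config.processing.recon_voxel_mm,
        center_z_mm=config.phantom.gel_radius_mm,
        v0_mm=0.0,
    )


def _background_region(shape: tuple[int, int]) -> tuple[slice, slice]:
    h, w = shape
    return slice(2, max(3, h // 4)), slice(w // 4, 3 * w // 4)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full chain and write every intermediate plus a
    provenance record and summary.json into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    spec = config.phantom.to_spec()
    cam = config.camera.to_model()
    acq = config.acquisition.to_spec(seed)
    proc = config.processing
    char = config.characterization
    shape = default_image_shape(spec, cam.pixel_size_mm)
    illum = config.illumination.to_field(shape)
    log.info(
        "processing defaults: flat-field FWHM %.2f mm, median %dx%d px, "
        "%d subsets x %d iterations, post-filter FWHM %.2f mm",
        proc.flatfield_fwhm_mm, proc.median_window_px, proc.median_window_px,
        proc.subsets, proc.iterations, proc.postfilter_fwhm_mm,
    )

    def stage(name):
        log.info("stage: %s", name)
        return substream(seed, name)

    # --- simulate -----------------------------------------------------
    photo = render_photo(
        spec, cam, illum, config.optical.photo_exposure_s,
        brightness_counts_per_s=config.optical.photo_brightness_counts_per_s,
        rng=stage("photo"), seed=seed,
    )
    calib = render_calibration(
        cam, illum, config.optical.calib_exposure_s,
        brightness_counts_per_s=config.optical.photo_brightness_counts_per_s,
        rng=stage("calibration"), seed=seed,
    )
    fluor_acq = config.acquisition.to_spec(seed)
    fluor_acq.exposure_s = config.optical.fluor_exposure_s
    fluor = render_fluorescence(spec, cam, illum, fluor_acq, rng=stage("fluorescence"))
    biolum_acq = config.acquisition.to_spec(seed)
    biolum_acq.exposure_s = config.optical.biolum_exposure_s
    biolum = render_bioluminescence(
        spec, cam, biolum_acq, shape=shape, rng=stage("bioluminescence")
    )
    events = simulate_listmode(spec, acq, rng=stage("listmode"))
    truth = ground_truth_capillary(spec, 256)
    for name, img in (("photo", photo), ("calibration", calib),
                      ("fluorescence_raw", fluor), ("bioluminescence_raw", biolum)):
        write_image(outdir / f"{name}.tif", img, seed=seed)
    write_events(outdir / "events.csv", events)
    truth.to_csv(outdir / "capillary_truth.csv", index=False,
                 columns=["axial_mm", "depth_mm", "x_mm", "y_mm", "z_mm"])

    # --- optical processing ------------------------------------------
    flat = make_flatfield(calib, proc.flatfield_fwhm_mm)
    fluor_corr = apply_flatfield(fluor, flat)
    fluor_corr = median_filter_hot_pixels(fluor_corr, proc.median_window_px)
    biolum_filt = median_filter_hot_pixels(biolum, proc.median_window_px)
    exposure_state = check_exposure(fluor, cam.adc_max_counts)
    write_image(outdir / "fluorescence_corrected.tif", fluor_corr, seed=seed)
    write_image(outdir / "bioluminescence_filtered.tif", biolum_filt, seed=seed)

    # --- SPECT chain --------------------------------------------------
    geom = spect_geometry(config)
    peak_win = photopeak_window(acq.photopeak_keV, proc.window_fraction)
    lo_win = EnergyWindow(*proc.bg_window_lo_keV)
    hi_win = EnergyWindow(*proc.bg_window_hi_keV)
    peak_sino = bin_events(events, peak_win, geom)
    scatter_est = tew_scatter_estimate(
        bin_events(events, lo_win, geom), bin_events(events, hi_win, geom),
        peak_win.width_keV,
    )
    corrected = subtract_scatter(peak_sino, scatter_est)
    volume = osem_reconstruct(
        corrected, proc.recon_ny, proc.recon_nz, proc.recon_voxel_mm,
        proc.subsets, proc.iterations,
    )
    volume = gaussian_postfilter(volume, proc.postfilter_fwhm_mm)
    spect_top = sum_projection(volume, "vertical")
    spect_side = sum_projection(volume, "lateral")
    write_volume(outdir / "spect.nii", volume)
    write_image(outdir / "spect_sum_top.tif", spect_top, seed=seed)
    write_image(outdir / "spect_sum_side.tif", spect_side, seed=seed)

    # --- fusion -------------------------------------------------------
    overlay_fluor = threshold_overlay(
        photo, fluor_corr, char.overlay_threshold, char.overlay_colormap
    )
    # known grid transform: both grids are metric, rows centred on the bed
    ty = 0.5 * (photo.pixels.shape[0] * photo.pixel_size_mm
                - spect_top.pixels.shape[0] * spect_top.pixel_size_mm)
    grid_tf = SimilarityTransform(1.0, 0.0, (0.0, ty))
    spect_on_photo = resample_to_grid(spect_top, grid_tf, photo)
    overlay_spect = threshold_overlay(
        photo, spect_on_photo, char.overlay_threshold, char.overlay_colormap
    )
    np.save(outdir / "overlay_fluorescence.npy", overlay_fluor.rgb)
    np.save(outdir / "overlay_spect.npy", overlay_spect.rgb)

    # --- characterization --------------------------------------------
    bg_region = _background_region(fluor_corr.pixels.shape)
    fluor_curve = attenuation_curve(
        fluor_corr, truth, bg_region, width_mm=char.attenuation_width_mm
    )
    spect_bg = _background_region(spect_top.pixels.shape)
    spect_curve = attenuation_curve(
        spect_top, truth, spect_bg, width_mm=char.attenuation_width_mm
    )
    mu_fluor, _, r2_fluor = fit_attenuation_coefficient(
        filter_curve_floor(trim_curve(fluor_curve), char.fit_floor_frac)
    )
    mu_spect, _, r2_spect = fit_attenuation_coefficient(
        filter_curve_floor(trim_curve(spect_curve), char.fit_floor_frac)
    )
    d_lo, d_hi = truth["depth_mm"].min(), truth["depth_mm"].max()
    span = d_hi - d_lo
    depths = np.linspace(d_lo + 0.1 * span, d_hi - 0.1 * span, char.n_depths)
    res_curve = resolution_curve(
        fluor_corr, truth, depths, width_mm=char.profile_width_mm
    )
    detect = detectability_depth(
        fluor_curve, fluor_curve.background_mean, fluor_curve.background_sd,
        char.detect_k,
    )
    h = fluor_corr.pixels.shape[0]
    track_y = float(truth["y_mm"].iloc[0]) + 0.5 * h * fluor_corr.pixel_size_mm
    axial_prof = extract_profile(
        fluor_corr,
        (float(truth["axial_mm"].min()), track_y),
        (float(truth["axial_mm"].max()), track_y),
        char.profile_width_mm,
    )
    pbr = peak_background_ratio(axial_prof, max(fluor_curve.background_mean, 1e-12))

    fluor_curve.to_frame().to_csv(outdir / "attenuation_curve_fluorescence.csv",
                                  index=False)
    spect_curve.to_frame().to_csv(outdir / "attenuation_curve_spect.csv", index=False)
    res_curve.to_frame().to_csv(outdir / "resolution_curve.csv", index=False)

    summary = {
        "mu_fluor_per_mm": mu_fluor,
        "r2_fluor": r2_fluor,
        "mu_spect_per_mm": mu_spect,
        "r2_spect": r2_spect,
        "mu_truth_per_mm": spec.mu_total_per_mm,
        "detectability_depth_mm": "beyond range" if np.isinf(detect) else detect,
        "peak_background_ratio": pbr,
        "fluorescence_exposure": exposure_state,
        "n_events": len(events),
        "photopeak_counts": peak_sino.total,
        "corrected_counts": corrected.total,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    provenance = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": seed,
        "config": config.model_dump(),
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return summary
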