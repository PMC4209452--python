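import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biofluo.characterization import LineProfile, estimate_fwhm
from biofluo.phantom_sim import AcquisitionSpec, PhantomSpec, simulate_listmode, substream
from biofluo.spect_proc import (
    EnergyWindow,
    EventList,
    ParallelProjector,
    SinogramSet,
    Volume3D,
    bin_events,
    gaussian_postfilter,
    make_geometry,
    osem_reconstruct,
    photopeak_window,
    subtract_scatter,
    sum_projection,
    tew_scatter_estimate,
)


def dense_system_matrix(proj: ParallelProjector) -> np.ndarray:
    """Probe the projector as a black box, one unit voxel at a time."""
    nvox = int(np.prod(proj.vol_shape))
    nbin = proj.geometry.n_angles * proj.geometry.nu * proj.nx
    A = np.empty((nbin, nvox))
    for j in range(nvox):
        e = np.zeros(nvox)
        e[j] = 1.0
        A[:, j] = proj.forward(e.reshape(proj.vol_shape)).ravel()
    return A


def mlem_oracle(A: np.ndarray, y: np.ndarray, n_iter: int) -> list[np.ndarray]:
    """Plain dense-matrix MLEM, written independently of the package."""
    sens = A.sum(axis=0)
    x = np.ones(A.shape[1])
    iterates = []
    for _ in range(n_iter):
        p = A @ x
        ratio = np.zeros_like(p)
        np.divide(y, p, out=ratio, where=p > 1e-12)
        upd = A.T @ ratio
        x = np.where(sens > 0, x * upd / np.where(sens > 0, sens, 1.0), 0.0)
        iterates.append(x.copy())
    return iterates


class TestEnergyWindows:
    def test_tc99m_photopeak_window(self):
        w = photopeak_window(140.0, 0.20)
        assert (w.lo_keV, w.hi_keV) == pytest.approx((126.0, 154.0))

    def test_in111_photopeak_window(self):
        w = photopeak_window(171.0, 0.20)
        assert (w.lo_keV, w.hi_keV) == pytest.approx((153.9, 188.1))

    def test_width_vanishes_with_fraction(self):
        assert photopeak_window(100.0, 1e-9).width_keV == pytest.approx(0.0, abs=1e-6)

    def test_invalid_fraction(self):
        for frac in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                photopeak_window(140.0, frac)


class TestBinEvents:
    def geometry(self):
        return make_geometry(4, 8, 8, 1.0)

    def test_empty_list_all_zero(self):
        empty = np.empty(0)
        ev = EventList(empty, empty, empty, empty, 4)
        sino = bin_events(ev, EnergyWindow(126, 154), self.geometry())
        assert sino.total == 0
        assert sino.n_discarded == 0

    def test_single_event_single_count(self):
        ev = EventList([2], [0.2], [3.7], [140.0], 4)
        sino = bin_events(ev, EnergyWindow(126, 154), self.geometry())
        assert sino.total == 1
        assert sino.counts[2, 4, 3] == 1

    def test_out_of_grid_events_tallied(self):
        ev = EventList([0, 0], [100.0, 0.0], [0.5, 0.5], [140.0, 140.0], 4)
        sino = bin_events(ev, EnergyWindow(126, 154), self.geometry())
        assert sino.total == 1
        assert sino.n_discarded == 1

    def test_top_edge_closed(self):
        geom = self.geometry()
        ev = EventList([0], [geom.u_edges[-1]], [geom.v_edges[-1]], [140.0], 4)
        sino = bin_events(ev, EnergyWindow(126, 154), geom)
        assert sino.counts[0, -1, -1] == 1

    def test_partition_is_exact(self, rng):
        acq = AcquisitionSpec(
            scatter_fraction=0.3, sensitivity_counts_per_MBq_s=4500.0,
            energy_resolution_fwhm_frac=0.05,
        )
        ev = simulate_listmode(PhantomSpec(), acq, rng=rng)
        geom = make_geometry(acq.n_angles, 80, 96, 0.5, center_z_mm=13.0)
        windows = [EnergyWindow(110, 124), EnergyWindow(126, 154),
                   EnergyWindow(156, 170)]
        counted = sum(
            bin_events(ev, w, geom).total + bin_events(ev, w, geom).n_discarded
            for w in windows
        )
        outside = sum(~np.logical_or.reduce([w.contains(ev.energy_keV) for w in windows]))
        assert counted + outside == len(ev)

    def test_photopeak_fraction_matches_scatter_setting(self, rng):
        # continuum strictly below the window: in-window count ~ 0.7 N
        acq = AcquisitionSpec(
            scatter_fraction=0.3,
            sensitivity_counts_per_MBq_s=4500.0,
            energy_resolution_fwhm_frac=0.05,
            scatter_band_frac=(0.50, 0.85),
        )
        ev = simulate_listmode(PhantomSpec(), acq, rng=rng)
        geom = make_geometry(acq.n_angles, 120, 120, 0.5, center_z_mm=13.0)
        win = photopeak_window(140.0, 0.2)
        sino = bin_events(ev, win, geom)
        n_in = sino.total + sino.n_discarded
        n = len(ev)
        assert abs(n_in - 0.7 * n) < 5 * np.sqrt(n * 0.7 * 0.3)


class TestTew:
    def test_zero_backgrounds_zero_scatter(self):
        geom = make_geometry(2, 4, 4, 1.0)
        zero = SinogramSet(np.zeros((2, 4, 4)), geom, EnergyWindow(124, 136))
        zero_hi = SinogramSet(np.zeros((2, 4, 4)), geom, EnergyWindow(166, 184))
        assert np.all(tew_scatter_estimate(zero, zero_hi, 28.0) == 0)

    def test_worked_formula(self):
        # C_low=10 over 12 keV, C_high=10 over 18 keV, peak 28 keV wide
        geom = make_geometry(1, 1, 1, 1.0)
        low = SinogramSet(np.full((1, 1, 1), 10.0), geom, EnergyWindow(124, 136))
        high = SinogramSet(np.full((1, 1, 1), 10.0), geom, EnergyWindow(166, 184))
        est = tew_scatter_estimate(low, high, 28.0)
        assert est[0, 0, 0] == pytest.approx(19.444, abs=1e-3)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_corrected_counts_never_negative(self, seed):
        r = np.random.default_rng(seed)
        geom = make_geometry(2, 3, 3, 1.0)
        peak = SinogramSet(r.integers(0, 20, (2, 3, 3)).astype(float), geom,
                           EnergyWindow(126, 154))
        low = SinogramSet(r.integers(0, 20, (2, 3, 3)).astype(float), geom,
                          EnergyWindow(110, 124))
        high = SinogramSet(r.integers(0, 20, (2, 3, 3)).astype(float), geom,
                           EnergyWindow(156, 170))
        est = tew_scatter_estimate(low, high, 28.0)
        assert np.all(subtract_scatter(peak, est).counts >= 0)

    def test_improves_total_count_accuracy(self):
        # scattered acquisitions: TEW-corrected totals closer to the true
        # primaries than uncorrected, on a strong majority of replicates
        spec = PhantomSpec()
        wins = (photopeak_window(140.0, 0.2), EnergyWindow(110, 124),
                EnergyWindow(156, 170))
        hits = 0
        n_rep = 20
        for s in range(n_rep):
            acq = AcquisitionSpec(scatter_fraction=0.3,
                                  sensitivity_counts_per_MBq_s=4500.0, seed=s)
            ev = simulate_listmode(spec, acq, rng=substream(s, "tew"))
            geom = make_geometry(acq.n_angles, 120, 120, 0.5, center_z_mm=13.0)
            peak, low, high = (bin_events(ev, w, geom) for w in wins)
            true_prim = int((wins[0].contains(ev.energy_keV) & ~ev.is_scatter).sum())
            corrected = subtract_scatter(
                peak, tew_scatter_estimate(low, high, wins[0].width_keV)
            ).total
            if abs(corrected - true_prim) < abs(peak.total - true_prim):
                hits += 1
        assert hits >= int(0.95 * n_rep)


class TestProjector:
    def test_adjointness(self, rng):
        geom = make_geometry(8, 24, 16, 1.0)
        proj = ParallelProjector(geom, 16, 16, 1.0)
        x = rng.random(proj.vol_shape)
        y = rng.random((8, 24, 16))
        lhs = float(np.sum(proj.forward(x) * y))
        rhs = float(np.sum(x * proj.back(y)))
        assert lhs == pytest.approx(rhs, rel=1e-8)

    def test_v_pitch_must_match_voxel(self):
        geom = make_geometry(4, 8, 8, 1.0)
        with pytest.raises(ValueError):
            ParallelProjector(geom, 8, 8, 0.5)


class TestOsem:
    def test_zero_sinogram_zero_volume(self):
        geom = make_geometry(4, 12, 8, 1.0)
        sino = SinogramSet(np.zeros((4, 12, 8)), geom, EnergyWindow(126, 154))
        vol = osem_reconstruct(sino, 8, 8, 1.0, 4, 3)
        assert np.all(vol.voxels == 0)

    def test_one_subset_equals_dense_mlem_oracle(self, rng):
        geom = make_geometry(8, 24, 16, 1.0)
        proj = ParallelProjector(geom, 16, 16, 1.0)
        A = dense_system_matrix(proj)
        truth = np.zeros(proj.vol_shape)
        truth[7, 4, 9] = 50.0
        truth[9, 10, 6] = 30.0
        y = rng.poisson(proj.forward(truth) + 0.5).astype(float)
        sino = SinogramSet(y, geom, EnergyWindow(126, 154))
        oracle = mlem_oracle(A, y.ravel(), 5)
        for it in range(1, 6):
            vol = osem_reconstruct(sino, 16, 16, 1.0, 1, it)
            assert np.allclose(vol.voxels.ravel(), oracle[it - 1], rtol=1e-10,
                               atol=1e-12)

    def test_point_source_localized(self):
        geom = make_geometry(16, 24, 16, 1.0)
        proj = ParallelProjector(geom, 16, 16, 1.0)
        truth = np.zeros(proj.vol_shape)
        truth[8, 5, 11] = 100.0
        sino = SinogramSet(proj.forward(truth), geom, EnergyWindow(126, 154))
        rec = osem_reconstruct(sino, 16, 16, 1.0, 16, 6)
        peak = np.unravel_index(np.argmax(rec.voxels), rec.voxels.shape)
        assert np.max(np.abs(np.array(peak) - np.array([8, 5, 11]))) <= 1

    def test_mlem_count_preservation(self, rng):
        geom = make_geometry(8, 24, 16, 1.0)
        proj = ParallelProjector(geom, 16, 16, 1.0)
        truth = rng.random(proj.vol_shape) * 5.0
        y = rng.poisson(proj.forward(truth)).astype(float)
        sino = SinogramSet(y, geom, EnergyWindow(126, 154))
        rec = osem_reconstruct(sino, 16, 16, 1.0, 1, 50)
        projected = proj.forward(rec.voxels).sum()
        assert abs(projected - y.sum()) / y.sum() < 0.005


class TestPostfilter:
    def test_delta_fwhm(self):
        vol = Volume3D(np.zeros((33, 33, 33)), 0.2)
        vol.voxels[16, 16, 16] = 1.0
        out = gaussian_postfilter(vol, 0.47)
        prof = LineProfile((np.arange(33) + 0.5) * 0.2, out.voxels[16, 16, :], 0.2)
        assert estimate_fwhm(prof) == pytest.approx(0.47, abs=0.1)

    def test_constant_unchanged(self):
        vol = Volume3D(np.full((12, 12, 12), 3.0), 0.2)
        out = gaussian_postfilter(vol, 1.18)
        assert np.allclose(out.voxels, 3.0, rtol=1e-10)

    def test_sum_conserved(self, rng):
        vol = Volume3D(rng.random((20, 18, 16)), 0.2)
        out = gaussian_postfilter(vol, 1.18)
        assert out.voxels.sum() == pytest.approx(vol.voxels.sum(), rel=1e-3)


class TestSumProjection:
    def test_vertical_sum_of_ones(self):
        vol = Volume3D(np.ones((10, 10, 25)), 0.2)
        img = sum_projection(vol, "vertical")
        assert img.pixels.shape == (10, 10)
        assert np.allclose(img.pixels, 25.0)
        assert img.modality == "spect_sum"
        assert img.pixel_size_mm == 0.2

    def test_total_intensity_conserved(self, rng):
        vol = Volume3D(rng.random((9, 7, 5)), 0.2)
        for axis in ("vertical", "lateral", "axial"):
            assert sum_projection(vol, axis).pixels.sum() == pytest.approx(
                vol.voxels.sum(), rel=1e-12
            )

    def test_invalid_axis(self):
        with pytest.raises(ValueError):
            sum_projection(Volume3D(np.ones((2, 2, 2)), 0.2), "diagonal")

    def test_cylinder_chord_profile_fwhm(self):
        # 0.9 mm cylinder digitized at 0.05 mm: chord profile sqrt(d^2-4y^2)
        # has FWHM d*sqrt(3)/2 = 0.779 mm
        vox = 0.05
        n = 48
        yy, zz = np.meshgrid(
            (np.arange(n) - (n - 1) / 2) * vox,
            (np.arange(n) - (n - 1) / 2) * vox,
            indexing="ij",
        )
        cyl = (yy**2 + zz**2 <= 0.45**2).astype(float)
        vol = Volume3D(np.repeat(cyl[None, :, :], 8, axis=0), vox)
        img = sum_projection(vol, "vertical")
        prof = LineProfile((np.arange(n) + 0.5) * vox, img.pixels[:, 4], vox)
        assert estimate_fwhm(prof) == pytest.approx(0.9 * np.sqrt(3) / 2, abs=vox)


class TestCapillaryFlatness:
    def test_reconstructed_axial_profile_flat(self):
        # no gamma attenuation is simulated, so the reconstructed
        # capillary profile along the axis is flat (CV < 10% centrally)
        spec = PhantomSpec()
        acq = AcquisitionSpec(scatter_fraction=0.0, seed=11)
        ev = simulate_listmode(spec, acq, rng=substream(11, "flat"))
        geom = make_geometry(acq.n_angles, 80, 96, 0.5, center_z_mm=spec.gel_radius_mm)
        sino = bin_events(ev, photopeak_window(140.0, 0.2), geom)
        vol = gaussian_postfilter(
            osem_reconstruct(sino, 56, 56, 0.5, 16, 6), 1.18
        )
        top = sum_projection(vol, "vertical")
        x0 = spec.entry_point_mm[0]
        x1 = x0 + spec.capillary_fill_length_mm * np.cos(np.radians(spec.inclination_deg))
        c0 = int((x0 + 0.1 * (x1 - x0)) / 0.5)
        c1 = int((x0 + 0.9 * (x1 - x0)) / 0.5)
        axial = top.pixels[:, c0:c1].sum(axis=0)
        assert axial.std() / axial.mean() < 0.10
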