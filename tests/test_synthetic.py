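"""Forward model, phantoms, noise statistics and serialization round trips."""

import numpy as np
import pytest

import myoscan as ms
from myoscan.reduction import azimuthal_average, azimuthal_profile, default_q_bins
from myoscan.synthetic import (render_frame, von_mises_modulation,
                               beamstop_mask)
from myoscan.peakfit import fit_profile, FitConfig
from conftest import single_point_truth


class TestVonMisesCalibration:
    def test_anisotropy_kappa_roundtrip(self):
        for a in (0.0, 0.1, 0.35, 0.6, 0.9):
            kappa = ms.kappa_from_anisotropy(a)
            assert ms.anisotropy_from_kappa(kappa) == pytest.approx(a, abs=1e-6)

    def test_modulation_has_unit_circular_mean(self):
        phi = np.arange(0.5, 360, 1.0)
        for kappa in (0.0, 1.0, 5.0, 50.0):
            assert von_mises_modulation(phi, 40.0, kappa).mean() == \
                pytest.approx(1.0, rel=1e-6)

    def test_modulation_period_180(self):
        phi = np.linspace(0, 180, 91)
        a = von_mises_modulation(phi, 30.0, 2.0)
        b = von_mises_modulation(phi + 180.0, 30.0, 2.0)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ms.kappa_from_anisotropy(1.5)
        with pytest.raises(ValueError):
            ms.anisotropy_from_kappa(-1.0)


class TestPhantoms:
    def test_sham_has_no_lesion(self):
        truth = ms.make_default_phantom((16, 16), "sham")
        assert not truth.lesion_mask.any()
        assert not truth.ring_mask.any()

    @pytest.mark.parametrize("delta", [1.7, 2.2, 2.4])
    def test_ring_spacing_difference_matches_delta(self, delta):
        truth = ms.make_default_phantom((32, 32), "ring", ring_delta=delta)
        inner = np.median(truth.spacing[truth.ring_mask])
        bulk = 39.5   # base myocardium level
        assert bulk - inner == pytest.approx(delta, abs=1e-9)

    def test_lesion_spacing_above_threshold(self):
        truth = ms.make_default_phantom((24, 24), "tac_lesion")
        assert truth.lesion_mask.any()
        assert (truth.spacing[truth.lesion_mask] > 46.0).all()
        assert (truth.peak_intensity == 0).sum() > 0

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            ms.make_default_phantom((16, 16), "nonsense")

    def test_minimum_grid_enforced(self):
        with pytest.raises(ValueError):
            ms.make_default_phantom((8, 8), "sham")


class TestForwardModel:
    def test_noise_free_spacing_roundtrip(self, geometry, coord_maps):
        # uniform 38.9 nm spacing: fitted q0 = 4π/38.9 within 1e-3 nm⁻¹
        truth = single_point_truth(spacing=38.9)
        frame = render_frame(truth, 0, 0, coord_maps)
        mask = beamstop_mask(geometry)
        bg = render_frame(single_point_truth(spacing=38.9, peak=0.0), 0, 0,
                          coord_maps)
        prof = azimuthal_average(frame - bg, coord_maps, mask,
                                 default_q_bins(coord_maps))
        fit = fit_profile(prof, FitConfig())
        assert fit.q0 == pytest.approx(4 * np.pi / 38.9, abs=1e-3)

    def test_isotropic_point_measures_no_anisotropy(self, geometry, coord_maps):
        # A(φ) ≡ 1: the pixel grid imprints a 90°-periodic ripple on I(φ),
        # but under angle doubling the measured anisotropy stays at zero
        from myoscan.orientation import circular_stats

        truth = single_point_truth(anisotropy=0.0)
        frame = render_frame(truth, 0, 0, coord_maps)
        bg = render_frame(single_point_truth(peak=0.0), 0, 0, coord_maps)
        azi = azimuthal_profile(frame - bg, coord_maps, beamstop_mask(geometry))
        assert circular_stats(azi).anisotropy <= 0.02

    def test_poisson_mean_converges_to_model(self, geometry, coord_maps):
        truth = single_point_truth()
        lam = render_frame(truth, 0, 0, coord_maps)
        rng = np.random.default_rng(7)
        n = 100
        mean = sum(rng.poisson(lam) for _ in range(n)) / n
        bound = 3.0 * np.sqrt(np.maximum(lam, 1e-12)) / np.sqrt(n)
        outside = np.abs(mean - lam) > np.maximum(bound, 1e-9)
        assert outside.mean() < 0.01   # ~0.3% expected at 3σ

    def test_truth_shape_mismatch_rejected(self):
        one = np.ones((2, 2))
        with pytest.raises(ValueError):
            ms.GroundTruthFields(one, one, one, np.ones((3, 3)), one, one, one,
                                 np.zeros((2, 2), bool), np.zeros((2, 2), bool))


class TestScanStack:
    def test_counts_nonnegative_integers(self, sham_poisson):
        frames = sham_poisson.stack.frames
        assert np.issubdtype(frames.dtype, np.integer)
        assert frames.min() >= 0

    def test_twenty_empty_frames_per_line(self, sham_poisson):
        flags = sham_poisson.stack.empty_flags
        assert (flags.sum(axis=1) == 20).all()

    def test_empty_frames_lack_ring(self, geometry, coord_maps, sham_poisson):
        # empty-frame profile fits the background: d ≈ 3, peak ≈ 0
        stack = sham_poisson.stack
        empty = stack.frames[0, stack.empty_flags[0]].mean(axis=0)
        prof = azimuthal_average(empty.astype(float), coord_maps, stack.mask,
                                 default_q_bins(coord_maps))
        fit = fit_profile(prof, FitConfig())
        assert fit.I_p < 0.05
        assert fit.d == pytest.approx(3.0, abs=0.3)

    def test_beamstop_masks_vertical_wire(self, geometry):
        mask = beamstop_mask(geometry)
        half_px = 0.5 * 1000.0 / geometry.pixel_size
        assert mask[:, 127].all() and mask[:, 128].all()
        assert not mask[:, 127 - int(half_px) - 2].any()

    def test_hdf5_roundtrip_lossless(self, sham_poisson, tmp_path):
        path = tmp_path / "scan.h5"
        ms.save_scan(sham_poisson.stack, path)
        back = ms.load_scan(path)
        np.testing.assert_array_equal(back.frames, sham_poisson.stack.frames)
        np.testing.assert_array_equal(back.mask, sham_poisson.stack.mask)
        np.testing.assert_array_equal(back.empty_flags,
                                      sham_poisson.stack.empty_flags)
        assert back.geometry == sham_poisson.stack.geometry
        np.testing.assert_array_equal(back.truth.spacing,
                                      sham_poisson.truth.spacing)

    def test_same_seed_reproduces_frames(self, geometry):
        truth = single_point_truth()
        a = ms.simulate_scan(truth, geometry, noise_seed=5, n_empty=1)
        b = ms.simulate_scan(truth, geometry, noise_seed=5, n_empty=1)
        np.testing.assert_array_equal(a.frames, b.frames)


class TestSimulateSHG:
    def test_straight_striation_spectral_peak(self):
        # orientation 30°, period 20 px → PSD peak at 1/20 cycles/px, azimuth 30°
        img = ms.simulate_shg(orientation_deg=30.0, period_um=2.0,
                              pixel_size_um=0.1, noise_level=0.0, seed=0)
        psd = ms.compute_psd(img.pixels, window=False)
        iy, ix = np.unravel_index(np.argmax(psd.psd), psd.psd.shape)
        freq = np.hypot(psd.fx[iy, ix], psd.fy[iy, ix])
        azimuth = np.degrees(np.arctan2(psd.fy[iy, ix], psd.fx[iy, ix])) % 180
        assert freq == pytest.approx(1 / 20.0, abs=1.0 / 512)
        assert azimuth == pytest.approx(30.0, abs=1.0)

    def test_undulation_widens_azimuthal_spread(self):
        # azimuthal second moment about the principal axis grows with U
        spreads = []
        for u in (0.0, 0.2, 0.4, 0.6):
            img = ms.simulate_shg(orientation_deg=0.0, undulation_amp_um=u,
                                  noise_level=0.0, seed=0)
            psd = ms.compute_psd(img.pixels)
            azim = np.arctan2(psd.fy, psd.fx) % np.pi
            d = np.minimum(azim, np.pi - azim)   # distance to 0° axis
            spreads.append(np.sum(psd.psd * d ** 2) / psd.psd.sum())
        assert all(a < b for a, b in zip(spreads, spreads[1:]))

    def test_aliasing_period_rejected(self):
        with pytest.raises(ValueError):
            ms.simulate_shg(period_um=0.5, pixel_size_um=0.3)

    def test_tiff_sidecar_roundtrip(self, tmp_path):
        import json
        import tifffile

        img = ms.simulate_shg(seed=3)
        path = tmp_path / "shg.tif"
        from myoscan.synthetic import save_shg
        save_shg(img, path)
        np.testing.assert_array_equal(tifffile.imread(path), img.pixels)
        sidecar = json.loads((tmp_path / "shg.tif.json").read_text())
        assert sidecar["truth"]["orientation_deg"] == 30.0
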