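"""Map assembly, k-means, KDE mode, pseudo-Voigt and lesion thresholding."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import myoscan as ms
from myoscan.segmentation import (ParameterMaps, assemble_maps,
                                  dice_coefficient, kde_mode, kmeans_segment,
                                  pseudo_voigt_fit, region_average,
                                  threshold_lesion, _pseudo_voigt)


def synthetic_maps(labels_truth, seed=0):
    """ParameterMaps whose 5-D fit features form three separated blobs."""
    rng = np.random.default_rng(seed)
    ny, nx = labels_truth.shape
    centers = {
        0: dict(S=0.02, d=2.0, Ip=0.5, q0=0.34, Ibgr=0.05, a=37.0),
        1: dict(S=0.05, d=3.0, Ip=1.5, q0=0.32, Ibgr=0.15, a=39.5),
        2: dict(S=0.09, d=4.0, Ip=3.0, q0=0.30, Ibgr=0.30, a=42.0),
    }
    rows = []
    for iy in range(ny):
        for ix in range(nx):
            c = centers[labels_truth[iy, ix]]
            rows.append(dict(
                iy=iy, ix=ix,
                S=c["S"] + rng.normal(0, 1e-4), d=c["d"] + rng.normal(0, 1e-3),
                Ip=c["Ip"] + rng.normal(0, 1e-3),
                q0=c["q0"] + rng.normal(0, 1e-5),
                Ibgr=c["Ibgr"] + rng.normal(0, 1e-4),
                a=c["a"] + rng.normal(0, 1e-3),
                residual_rms=0.0, converged=True, at_bound=False))
    table = pd.DataFrame(rows)
    blank = np.zeros((ny, nx))
    return assemble_maps(table, blank, blank, blank, blank)


class TestAssembleMaps:
    def test_all_converged_all_valid(self, sham_noisefree):
        assert sham_noisefree.maps.valid.all()

    def test_single_failed_fit_single_invalid(self, sham_noisefree):
        table = sham_noisefree.fits.copy()
        table.loc[5, "converged"] = False
        blank = np.zeros((16, 16))
        pmaps = assemble_maps(table, blank, blank, blank, blank)
        assert (~pmaps.valid).sum() == 1

    def test_shape_mismatch_rejected(self, sham_noisefree):
        with pytest.raises(ValueError):
            assemble_maps(sham_noisefree.fits, np.zeros((4, 4)),
                          np.zeros((4, 4)), np.zeros((4, 4)), np.zeros((4, 4)))


class TestKMeans:
    def test_separable_blobs_perfect_recovery(self):
        rng = np.random.default_rng(3)
        truth = rng.integers(0, 3, size=(20, 20))
        pmaps = synthetic_maps(truth)
        result = kmeans_segment(pmaps, k=3, seed=0)
        assert adjusted_rand_score(truth.ravel(),
                                   result.labels.ravel()) == pytest.approx(1.0)

    def test_labels_ascend_with_spacing(self):
        rng = np.random.default_rng(4)
        truth = rng.integers(0, 3, size=(20, 20))
        result = kmeans_segment(synthetic_maps(truth), k=3, seed=0)
        spacing = synthetic_maps(truth).fit_params["a"].to_numpy().reshape(20, 20)
        means = [spacing[result.labels == lab].mean() for lab in (1, 2, 3)]
        assert means[0] < means[1] < means[2]

    def test_deterministic_for_fixed_seed(self):
        truth = np.random.default_rng(5).integers(0, 3, size=(20, 20))
        pmaps = synthetic_maps(truth)
        a = kmeans_segment(pmaps, k=3, seed=11)
        b = kmeans_segment(pmaps, k=3, seed=11)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_zero_variance_feature_dropped_with_warning(self):
        truth = np.random.default_rng(6).integers(0, 3, size=(20, 20))
        pmaps = synthetic_maps(truth)
        pmaps.fit_params["Ibgr"] = 0.1
        with pytest.warns(UserWarning, match="Ibgr"):
            result = kmeans_segment(pmaps, k=3, seed=0)
        assert "Ibgr" not in result.feature_names

    def test_sham_phantom_layer_structure(self, sham_poisson):
        # lowest-spacing cluster on the epicardial rim, highest on the
        # outer myocardial layer
        run = sham_poisson
        result = kmeans_segment(run.maps, k=3, seed=0)
        spacing_truth = run.truth.spacing
        rim = spacing_truth == 38.0
        outer = spacing_truth == 41.2
        assert (result.labels[rim] == 1).mean() > 0.9
        assert (result.labels[outer] == 3).mean() > 0.9


class TestKdeMode:
    def test_unimodal_sample(self):
        values = np.random.default_rng(0).normal(39.0, 0.5, 10_000)
        assert kde_mode(values) == pytest.approx(39.0, abs=0.1)

    def test_bimodal_sample_takes_taller_mode(self):
        rng = np.random.default_rng(1)
        values = np.concatenate([rng.normal(38.7, 0.25, 7000),
                                 rng.normal(40.3, 0.25, 3000)])
        assert kde_mode(values) == pytest.approx(38.7, abs=0.1)

    def test_constant_sample(self):
        assert kde_mode(np.full(100, 41.5)) == 41.5

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            kde_mode(np.arange(10))


class TestPseudoVoigt:
    centers = np.linspace(35, 45, 60)

    def test_pure_gaussian_limit(self):
        y = _pseudo_voigt(self.centers, 10.0, 39.5, 1.2, 0.0)
        fit = pseudo_voigt_fit(self.centers, y)
        assert fit.converged
        assert fit.eta == pytest.approx(0.0, abs=0.05)
        assert fit.center == pytest.approx(39.5, abs=0.1)

    def test_pure_lorentzian_limit(self):
        y = _pseudo_voigt(self.centers, 10.0, 39.5, 1.2, 1.0)
        fit = pseudo_voigt_fit(self.centers, y)
        assert fit.eta == pytest.approx(1.0, abs=0.05)

    def test_half_mixture_recovery(self):
        y = _pseudo_voigt(self.centers, 8.0, 40.0, 1.5, 0.5)
        y = y + np.random.default_rng(2).normal(0, 0.02, y.size)
        fit = pseudo_voigt_fit(self.centers, y)
        assert 0.4 <= fit.eta <= 0.6

    def test_sparse_histogram_rejected(self):
        with pytest.raises(ValueError):
            pseudo_voigt_fit(self.centers[:5], np.ones(5))


class TestLesion:
    def test_sham_has_no_lesion(self, sham_noisefree):
        result = threshold_lesion(sham_noisefree.maps)
        assert result.mask.mean() < 0.01
        assert result.inside is None

    def test_lesion_phantom_dice(self, lesion_poisson):
        run = lesion_poisson
        result = threshold_lesion(run.maps)
        assert dice_coefficient(result.mask, run.truth.lesion_mask) > 0.9

    def test_lower_anisotropy_inside(self, lesion_poisson):
        result = threshold_lesion(lesion_poisson.maps)
        assert result.inside.mean_anisotropy < result.outside.mean_anisotropy

    def test_threshold_monotone(self, lesion_poisson):
        low = threshold_lesion(lesion_poisson.maps, threshold=44.0)
        high = threshold_lesion(lesion_poisson.maps, threshold=48.0)
        assert high.mask.sum() <= low.mask.sum()
        assert not (high.mask & ~low.mask).any()

    def test_small_components_removed(self, sham_noisefree):
        pmaps = sham_noisefree.maps
        spiked = ParameterMaps(
            spacing=pmaps.spacing.copy(), peak_intensity=pmaps.peak_intensity,
            anisotropy=pmaps.anisotropy, orientation=pmaps.orientation,
            total_intensity=pmaps.total_intensity, valid=pmaps.valid,
            at_bound=pmaps.at_bound, fit_params=pmaps.fit_params)
        spiked.spacing[3, 3] = 47.0   # isolated single-pixel speckle
        result = threshold_lesion(spiked, min_region_px=4)
        assert not result.mask[3, 3]


class TestRegionAverage:
    def test_single_point_mask(self, sham_noisefree):
        mask = np.zeros((16, 16), bool)
        mask[4, 7] = True
        stats = region_average(sham_noisefree.maps, mask)
        assert stats.n_points == 1
        assert stats.mean_anisotropy == pytest.approx(
            sham_noisefree.maps.anisotropy[4, 7])

    def test_complementary_masks_partition_mean(self, sham_noisefree):
        pmaps = sham_noisefree.maps
        mask = np.zeros((16, 16), bool)
        mask[:8] = True
        a = region_average(pmaps, mask)
        b = region_average(pmaps, ~mask)
        whole = np.nanmean(pmaps.anisotropy)
        combined = (a.mean_anisotropy * a.n_points
                    + b.mean_anisotropy * b.n_points) / (a.n_points + b.n_points)
        assert combined == pytest.approx(whole, rel=1e-9)

    def test_ring_phantom_modal_difference(self, geometry, coord_maps):
        from conftest import run_pipeline
        truth = ms.make_default_phantom((24, 24), "ring", ring_delta=2.2)
        run = run_pipeline(truth, geometry, coord_maps, seed=4, poisson=False)
        inner = region_average(run.maps, truth.ring_mask)
        outer_mask = ~truth.ring_mask & (truth.spacing == 39.5)
        outer = region_average(run.maps, outer_mask)
        assert outer.modal_spacing - inner.modal_spacing == \
            pytest.approx(2.2, abs=0.1)

    def test_empty_mask_rejected(self, sham_noisefree):
        with pytest.raises(ValueError):
            region_average(sham_noisefree.maps, np.zeros((16, 16), bool))
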