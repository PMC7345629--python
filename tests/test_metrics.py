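"""SMR / SCR contrast metrics, uncertainties and localization error."""

import numpy as np
import pytest

from bmiradar import (
    Image,
    MetricRegions,
    ScanConfig,
    evaluate,
    localization_error,
    metric_uncertainties,
    scr,
    smr,
)


def toy_regions():
    """2x2 grid: top row = tumor, bottom row = clutter."""
    coords = np.array([[-0.01, 0.01], [0.01, 0.01], [-0.01, -0.01], [0.01, -0.01]])
    tumor = np.array([True, True, False, False])
    breast = np.ones(4, bool)
    return MetricRegions(
        tumor_center=(0.0, 0.01),
        tumor_radius=0.005,
        tumor_mask=tumor,
        breast_mask=breast,
        clutter_mask=breast & ~tumor,
        pixel_coords=coords,
        pixel_size=0.02,
    )


def masked_regions(values_shape, config, center, radius):
    return MetricRegions.from_config(config, center, radius)


class TestContrastRatios:
    def test_smr_hand_value(self):
        """Tumor {9, 4}, clutter {1, 3}: SMR = 20 log10(9 / 2)."""
        img = np.array([9.0, 4.0, 1.0, 3.0])
        assert smr(img, toy_regions(), square=False) == pytest.approx(
            20 * np.log10(9 / 2)
        )

    def test_scr_hand_value(self):
        img = np.array([9.0, 4.0, 1.0, 3.0])
        assert scr(img, toy_regions(), square=False) == pytest.approx(
            20 * np.log10(9 / 3)
        )

    def test_equal_peaks_give_zero_db(self):
        img = np.array([5.0, 1.0, 5.0, 5.0])
        assert scr(img, toy_regions(), square=False) == pytest.approx(0.0)

    def test_tenfold_peak_gives_20_db(self):
        img = np.array([10.0, 0.0, 1.0, 1.0])
        assert smr(img, toy_regions(), square=False) == pytest.approx(20.0)

    def test_uniform_clutter_smr_equals_scr(self):
        img = np.array([8.0, 2.0, 3.0, 3.0])
        r = toy_regions()
        assert smr(img, r, square=False) == pytest.approx(scr(img, r, square=False))

    def test_zero_clutter_flags_infinity(self):
        img = np.array([1.0, 1.0, 0.0, 0.0])
        r = toy_regions()
        assert smr(img, r, square=False) == np.inf
        assert scr(img, r, square=False) == np.inf

    def test_scale_invariance(self, rng):
        r = toy_regions()
        img = rng.random(4) + 0.1
        assert smr(17.3 * img, r) == pytest.approx(smr(img, r))
        assert scr(17.3 * img, r) == pytest.approx(scr(img, r))

    def test_smr_never_below_scr(self, rng):
        r = toy_regions()
        for _ in range(100):
            img = rng.random(4) + 1e-6
            assert smr(img, r) >= scr(img, r) - 1e-12

    def test_squaring_doubles_db_values(self, rng):
        """scr(x^2) = 2 scr(x) exactly (max commutes with squaring); the same
        holds for smr when the clutter is uniform (then the mean commutes
        too) — this pins the squared-map display convention."""
        r = toy_regions()
        img = rng.random(4) + 0.1
        assert scr(img**2, r, square=False) == pytest.approx(
            2 * scr(img, r, square=False)
        )
        uniform = np.array([img[0], img[1], 0.3, 0.3])  # constant clutter
        assert smr(uniform**2, r, square=False) == pytest.approx(
            2 * smr(uniform, r, square=False)
        )
        # and the default path squares: smr(img) == smr_raw(img^2)
        assert smr(img, r) == pytest.approx(smr(img**2, r, square=False))
        assert scr(img, r) == pytest.approx(scr(img**2, r, square=False))


class TestUncertainties:
    def test_equal_tumor_pixels_zero_sigma(self):
        img = np.array([4.0, 4.0, 1.0, 2.0])
        sig_smr, _ = metric_uncertainties(img, toy_regions(), square=False)
        assert sig_smr == 0.0

    def test_brute_force_percentile_rule(self):
        """Tumor {1,2,3,4}: 75th pct = 3.25 -> only {4} survives -> undefined."""
        coords = np.zeros((8, 2))
        coords[:, 0] = np.linspace(-0.03, 0.04, 8)
        tumor = np.array([True] * 4 + [False] * 4)
        r = MetricRegions(
            tumor_center=(0.0, 0.0), tumor_radius=0.01,
            tumor_mask=tumor, breast_mask=np.ones(8, bool),
            clutter_mask=~tumor, pixel_coords=coords, pixel_size=0.01,
        )
        img = np.array([1.0, 2, 3, 4, 1, 1, 2, 2])
        sig_smr, _ = metric_uncertainties(img, r, square=False)
        assert np.isnan(sig_smr)  # fewer than 2 pixels above the cutoff

    def test_sigma_matches_manual_subset(self):
        """Tumor {1..8}: cutoff = 6.25? No: pct75 of 1..8 = 6.25 -> {7, 8}."""
        coords = np.zeros((16, 2))
        coords[:, 0] = np.linspace(-0.05, 0.05, 16)
        tumor = np.array([True] * 8 + [False] * 8)
        r = MetricRegions(
            tumor_center=(0.0, 0.0), tumor_radius=0.01,
            tumor_mask=tumor, breast_mask=np.ones(16, bool),
            clutter_mask=~tumor, pixel_coords=coords, pixel_size=0.01,
        )
        vals = np.array([1.0, 2, 3, 4, 5, 6, 7, 8] + [1.0] * 8)
        cutoff = np.percentile(vals[:8], 75)
        manual = np.std(vals[:8][vals[:8] >= cutoff])
        sig_smr, _ = metric_uncertainties(vals, r, square=False)
        assert sig_smr == pytest.approx(20 / np.log(10) * manual / 8.0)

    def test_scr_sigma_at_least_smr_sigma(self, rng):
        """Quadrature: adding the clutter term can only grow the uncertainty."""
        r = toy_regions()
        for _ in range(20):
            img = rng.random(4) + 0.1
            sig_smr, sig_scr = metric_uncertainties(img, r, square=False)
            if not (np.isnan(sig_smr) or np.isnan(sig_scr)):
                assert sig_scr >= sig_smr


class TestLocalization:
    def cfg(self):
        return ScanConfig.reduced()

    def test_peak_at_tumor_center(self):
        cfg = self.cfg()
        regions = MetricRegions.from_config(cfg, (0.02, 0.01), 0.005)
        img = np.zeros(cfg.n_pixels)
        d = np.hypot(*(regions.pixel_coords - np.array([0.02, 0.01])).T)
        img[np.argmin(d)] = 1.0
        err = localization_error(img, regions)
        assert err <= cfg.pixel_size * np.sqrt(2) / 2 * 1e3  # half pixel diagonal

    def test_offset_peak_distance(self):
        cfg = self.cfg()
        regions = MetricRegions.from_config(cfg, (0.0, 0.0), 0.005)
        target = np.array([0.01, 0.0])  # 10 mm along +x
        d = np.hypot(*(regions.pixel_coords - target).T)
        img = np.zeros(cfg.n_pixels)
        img[np.argmin(d)] = 1.0
        err = localization_error(img, regions)
        assert err == pytest.approx(10.0, abs=cfg.pixel_size * 1e3)

    def test_all_zero_image_flagged(self):
        cfg = self.cfg()
        regions = MetricRegions.from_config(cfg, (0.0, 0.0), 0.005)
        assert np.isnan(localization_error(np.zeros(cfg.n_pixels), regions))

    def test_argmax_outside_breast_ignored(self):
        """Strong response outside the breast must not win the argmax."""
        cfg = self.cfg()
        regions = MetricRegions.from_config(cfg, (0.0, 0.0), 0.005)
        img = np.zeros(cfg.n_pixels)
        img[~regions.breast_mask] = 100.0
        d = np.hypot(*regions.pixel_coords.T)
        img[np.argmin(d)] = 1.0
        assert localization_error(img, regions) <= cfg.pixel_size * 1e3


class TestRegionsAndReport:
    def test_masks_are_disjoint_and_nested(self):
        cfg = ScanConfig.reduced()
        r = MetricRegions.from_config(cfg, (0.02, 0.01), 0.01)
        assert not np.any(r.tumor_mask & r.clutter_mask)
        assert np.all(r.tumor_mask <= r.breast_mask)
        assert np.all(r.clutter_mask <= r.breast_mask)

    def test_tumor_region_includes_5mm_margin(self):
        cfg = ScanConfig.reduced()
        r = MetricRegions.from_config(cfg, (0.0, 0.0), 0.01)
        d = np.hypot(*r.pixel_coords.T)
        inside = d <= 0.015 - cfg.pixel_size  # strictly inside r_t + 5 mm
        assert np.all(r.tumor_mask[inside])

    def test_identifiable_iff_scr_positive(self, three_scatterer_regions, rng):
        img = rng.random(three_scatterer_regions.breast_mask.size)
        rep = evaluate(img, three_scatterer_regions)
        assert rep.identifiable == (rep.scr_db > 0)
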