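"""Synthetic monostatic scan simulator."""

import numpy as np
import pytest

from bmiradar import (
    InvalidPhantomError,
    PhantomSpec,
    Scatterer,
    envelope,
    estimate_propagation_speed,
    forward_project,
    iczt,
    ideal_skin_subtract,
    simulate_scan,
    standard_fixtures,
    time_of_flight,
)


def point_phantom(pos=(0.02, 0.01), amp=1.0):
    return PhantomSpec([Scatterer(pos, amp, 0.0)], breast_radius=0.055)


class TestSimulateScan:
    def test_scatterer_outside_breast_rejected(self):
        with pytest.raises(InvalidPhantomError):
            PhantomSpec([Scatterer((0.06, 0.0), 1.0, 0.0)], breast_radius=0.055)

    def test_sphere_extending_past_breast_rejected(self):
        with pytest.raises(InvalidPhantomError):
            PhantomSpec([Scatterer((0.05, 0.0), 1.0, 0.01)], breast_radius=0.055)

    def test_noiseless_single_scatterer_peaks_at_predicted_bin(self, reduced_config):
        """ICZT envelope peaks at the round-trip-delay bin for every antenna."""
        cfg = reduced_config
        phantom = point_phantom()
        full, _ = simulate_scan(phantom, cfg, 0.0)
        env = envelope(iczt(full, cfg.time_grid), cfg.time_grid)
        speed = estimate_propagation_speed(cfg)
        p = np.asarray(phantom.tumor.position)
        dt = cfg.time_grid[1] - cfg.time_grid[0]
        for m in range(cfg.n_positions):
            d = np.hypot(*(p - cfg.antenna_positions[m]))
            expected_bin = int(round(2 * d / (speed * dt)))
            assert abs(int(env.values[m].argmax()) - expected_bin) <= 1

    def test_reference_excludes_only_the_tumor(self, reduced_config):
        phantom = PhantomSpec(
            [
                Scatterer((0.02, 0.0), 1.0, 0.0),
                Scatterer((-0.02, 0.01), 0.5, 0.0),
            ],
            breast_radius=0.055,
            tumor_index=0,
        )
        full, ref = simulate_scan(phantom, reduced_config, 0.0)
        tumor_only, _ = simulate_scan(point_phantom((0.02, 0.0)), reduced_config, 0.0)
        diff = ideal_skin_subtract(full, ref)
        assert np.allclose(diff.values, tumor_only.values, rtol=1e-12, atol=1e-14)

    def test_reflectivity_linearity(self, reduced_config):
        full1, _ = simulate_scan(point_phantom(amp=1.0), reduced_config, 0.0)
        full2, _ = simulate_scan(point_phantom(amp=2.0), reduced_config, 0.0)
        assert np.allclose(full2.values, 2.0 * full1.values, rtol=1e-12)

    def test_seeded_noise_is_reproducible(self, reduced_config):
        a = simulate_scan(point_phantom(), reduced_config, 0.1, seed=42)
        b = simulate_scan(point_phantom(), reduced_config, 0.1, seed=42)
        assert np.array_equal(a[0].values, b[0].values)
        assert np.array_equal(a[1].values, b[1].values)

    def test_full_and_reference_noise_independent(self, reduced_config):
        phantom = point_phantom()
        full, ref = simulate_scan(phantom, reduced_config, 0.1, seed=0)
        clean_full, clean_ref = simulate_scan(phantom, reduced_config, 0.0)
        nf = full.values - clean_full.values
        nr = ref.values - clean_ref.values
        assert not np.allclose(nf, nr)
        corr = np.corrcoef(np.abs(nf).ravel(), np.abs(nr).ravel())[0, 1]
        assert abs(corr) < 0.05

    def test_sphere_rasterization_spreads_reflectivity(self, reduced_config):
        sphere = PhantomSpec(
            [Scatterer((0.0, 0.0), 1.0, 0.01)], breast_radius=0.055
        )
        full_sphere, _ = simulate_scan(sphere, reduced_config, 0.0)
        full_point, _ = simulate_scan(point_phantom((0.0, 0.0)), reduced_config, 0.0)
        # same total reflectivity, different spatial support -> different spectra
        assert not np.allclose(full_sphere.values, full_point.values)
        # at f -> low frequency limit both approach the same coherent sum
        assert abs(full_sphere.values[0, 0]) == pytest.approx(
            abs(full_point.values[0, 0]), rel=0.05
        )

    def test_adipose_only_reference_retains_clutter(self, reduced_config):
        """With all inner components removed for the reference scan, the
        calibrated difference keeps tumor AND clutter responses."""
        phantom = PhantomSpec(
            [
                Scatterer((0.02, 0.0), 1.0, 0.0),
                Scatterer((-0.02, 0.01), 0.5, 0.0),
            ],
            breast_radius=0.055,
            tumor_index=0,
        )
        full, ref = simulate_scan(
            phantom, reduced_config, 0.0, reference_mode="adipose-only"
        )
        assert np.all(ref.values == 0)
        diff = ideal_skin_subtract(full, ref)
        assert np.allclose(diff.values, full.values)

    def test_unknown_reference_mode_rejected(self, reduced_config):
        with pytest.raises(InvalidPhantomError):
            simulate_scan(point_phantom(), reduced_config, 0.0, reference_mode="bogus")

    def test_speed_mismatch_knob_changes_delays(self, reduced_config):
        a, _ = simulate_scan(point_phantom(), reduced_config, 0.0)
        b, _ = simulate_scan(point_phantom(), reduced_config, 0.0, eps_true=10.0)
        assert not np.allclose(a.values, b.values)


class TestSimulatorMatchesForwardModel:
    def test_peak_bins_agree_with_time_domain_projector(self, reduced_config, speed,
                                                        delays):
        """Frequency-domain simulation -> ICZT -> envelope peaks in the same
        bins as the nearest-bin forward projection of the rasterized phantom."""
        cfg = reduced_config
        phantom = point_phantom((0.015, -0.02))
        full, _ = simulate_scan(phantom, cfg, 0.0)
        env = envelope(iczt(full, cfg.time_grid), cfg.time_grid)

        img = np.zeros(cfg.n_pixels)
        coords = cfg.pixel_coords()
        d = np.hypot(*(coords - np.asarray(phantom.tumor.position)).T)
        img[np.argmin(d)] = 1.0
        proj = forward_project(img, delays)
        for m in range(cfg.n_positions):
            assert abs(int(env.values[m].argmax()) - int(proj.values[m].argmax())) <= 1


class TestStandardFixtures:
    def test_fixture_names_and_configs(self):
        fx = standard_fixtures(0)
        assert {"point-tumor-clean", "three-scatterer", "class-I", "class-II",
                "class-III", "class-IV"} <= set(fx)
        for f in fx.values():
            assert f.config.n_positions == 24
            assert f.config.time_grid.size == 128
            assert f.config.image_size == 100
            assert f.full_config.n_positions == 72
            assert f.full_config.freq_grid.size == 1001
            assert f.full_config.time_grid.size == 700
            assert f.full_config.image_size == 500

    def test_fixtures_deterministic_under_seed(self, reduced_config):
        a = standard_fixtures(7)
        b = standard_fixtures(7)
        for name in a:
            sa = a[name].phantom.scatterers
            sb = b[name].phantom.scatterers
            assert len(sa) == len(sb)
            for x, y in zip(sa, sb):
                assert x.position == y.position and x.reflectivity == y.reflectivity

    def test_density_classes_grade_clutter(self):
        fx = standard_fixtures(3)
        counts = [len(fx[f"class-{c}"].phantom.scatterers) for c in "I II III IV".split()]
        assert counts == sorted(counts)
        assert counts[0] < counts[-1]
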