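import numpy as np
import pytest

from skindrs.optics import (McConfig, MediumOptics, PathDatabase,
                            ProbeGeometry, build_path_database,
                            diffusion_reflectance, interrogation_depth,
                            rescale_reflectance, rescale_reflectance_with_se,
                            sample_hg_cosine, simulate_reflectance)


class TestTypes:
    def test_probe_invariants(self):
        with pytest.raises(ValueError):
            ProbeGeometry(fiber_diameter_mm=-0.1)
        with pytest.raises(ValueError):
            ProbeGeometry(sds_mm=(0.3,))  # below fiber diameter
        with pytest.raises(ValueError):
            ProbeGeometry(sds_mm=(2.0, 1.0))
        with pytest.raises(ValueError):
            ProbeGeometry(fiber_na=0.0)

    def test_medium_invariants_and_similarity(self):
        m = MediumOptics(0.01, 1.0, 0.8)
        assert m.mu_s == pytest.approx(5.0)
        with pytest.raises(ValueError):
            MediumOptics(-0.1, 1.0)
        with pytest.raises(ValueError):
            MediumOptics(0.1, 0.0)
        with pytest.raises(ValueError):
            MediumOptics(0.1, 1.0, 1.0)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            McConfig(n_photons=0)
        with pytest.raises(ValueError):
            McConfig(roulette_survival=1.5)


class TestHenyeyGreenstein:
    def test_isotropic_limit_is_uniform(self):
        u = np.linspace(0.0, 0.999999, 101)
        np.testing.assert_allclose(sample_hg_cosine(0.0, u), 2 * u - 1,
                                   rtol=1e-12)

    def test_mean_cosine_equals_g(self):
        rng = np.random.default_rng(11)
        u = rng.random(1_000_000)
        c = sample_hg_cosine(0.8, u)
        se = c.std() / np.sqrt(c.size)
        assert abs(c.mean() - 0.8) < 3 * se
        assert np.all((c >= -1) & (c <= 1))

    def test_empirical_cdf_matches_numeric_hg_integral(self):
        """ECDF of 1e6 samples vs trapezoid integration of the HG density
        for g = 0.8: max deviation < 0.005."""
        g = 0.8
        rng = np.random.default_rng(202)
        samples = np.sort(sample_hg_cosine(g, rng.random(1_000_000)))
        grid = np.linspace(-1.0, 1.0, 20_001)
        dens = 0.5 * (1 - g**2) / (1 + g**2 - 2 * g * grid) ** 1.5
        cdf = np.concatenate(([0.0], np.cumsum(
            0.5 * (dens[1:] + dens[:-1]) * np.diff(grid))))
        cdf /= cdf[-1]
        probe_pts = np.linspace(-0.99, 0.999, 400)
        ecdf = np.searchsorted(samples, probe_pts) / samples.size
        oracle = np.interp(probe_pts, grid, cdf)
        assert np.max(np.abs(ecdf - oracle)) < 0.005

    def test_invalid_g_rejected(self):
        with pytest.raises(ValueError):
            sample_hg_cosine(1.0, 0.5)
        with pytest.raises(ValueError):
            sample_hg_cosine(-0.1, 0.5)


@pytest.fixture(scope="module")
def white_db(probe):
    return build_path_database(MediumOptics(0.0, 1.0), probe,
                               McConfig(n_photons=60_000, seed=42))


class TestSimulateReflectance:
    def test_pure_absorber_returns_zero(self, probe):
        res = simulate_reflectance(MediumOptics(10.0, 1e-6, 0.0), probe,
                                   McConfig(n_photons=20_000, seed=1))
        assert np.all(res.reflectance == 0.0)
        assert res.zero_detection

    def test_energy_conservation(self, probe):
        res = simulate_reflectance(MediumOptics(0.05, 1.0), probe,
                                   McConfig(n_photons=50_000, seed=2))
        b = res.weight_balance
        total = (b["detected"] + b["escaped"] + b["absorbed"]
                 + b["truncated"] + b["roulette_net"])
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_fixed_seed_bit_identical(self, probe):
        cfg = McConfig(n_photons=20_000, seed=77)
        med = MediumOptics(0.02, 1.2)
        r1 = simulate_reflectance(med, probe, cfg)
        r2 = simulate_reflectance(med, probe, cfg)
        np.testing.assert_array_equal(r1.reflectance, r2.reflectance)
        np.testing.assert_array_equal(r1.standard_error, r2.standard_error)
        np.testing.assert_array_equal(r1.n_detected, r2.n_detected)

    def test_reflectance_decreases_with_absorption(self, white_db):
        mus = [0.01, 0.05, 0.2, 0.8]
        refs = [rescale_reflectance(white_db, m) for m in mus]
        for lo, hi in zip(refs[:-1], refs[1:]):
            assert np.all(hi <= lo)

    def test_se_scales_with_photon_count(self, probe):
        """Quadrupling the photon budget should halve the standard error
        (within 20%)."""
        med = MediumOptics(0.01, 1.5)
        se1 = simulate_reflectance(med, probe,
                                   McConfig(n_photons=40_000, seed=5)
                                   ).standard_error[0]
        se2 = simulate_reflectance(med, probe,
                                   McConfig(n_photons=160_000, seed=6)
                                   ).standard_error[0]
        assert se1 / se2 == pytest.approx(2.0, rel=0.2)

    def test_mismatched_boundary_runs_and_conserves(self):
        probe_mm = ProbeGeometry(n_ambient=1.0)
        res = simulate_reflectance(MediumOptics(0.05, 1.0), probe_mm,
                                   McConfig(n_photons=30_000, seed=9))
        b = res.weight_balance
        total = (b["detected"] + b["escaped"] + b["absorbed"]
                 + b["truncated"] + b["roulette_net"])
        assert total == pytest.approx(1.0, abs=1e-3)
        assert np.all(res.reflectance >= 0)


class TestPathDatabase:
    def test_requires_zero_absorption(self, probe):
        with pytest.raises(ValueError, match="mu_a"):
            build_path_database(MediumOptics(0.1, 1.0), probe,
                                McConfig(n_photons=100, seed=0))

    def test_path_lengths_respect_geometric_lower_bound(self, white_db, probe):
        """A photon detected at separation d entered within one fiber
        radius of the axis and exited within one radius of the detector
        centre, so its path is at least d minus the fiber diameter."""
        sds = np.array(white_db.sds_mm)
        lower = sds[white_db.detector_id] - probe.fiber_diameter_mm
        assert np.all(white_db.path_length_mm >= lower)
        assert np.all(white_db.max_depth_mm > 0)

    def test_identity_rescale_matches_zero_absorption_run(self, white_db, probe):
        direct = simulate_reflectance(
            MediumOptics(0.0, 1.0), probe,
            McConfig(n_photons=60_000, seed=42))
        np.testing.assert_allclose(rescale_reflectance(white_db, 0.0),
                                   direct.reflectance, rtol=1e-12)

    def test_negative_absorption_rejected(self, white_db):
        with pytest.raises(ValueError):
            rescale_reflectance(white_db, -0.01)

    @pytest.mark.parametrize("mu_a", [0.05, 0.2])
    def test_rescaled_matches_direct_simulation(self, white_db, probe, mu_a):
        """White-MC reweighting vs an independent direct simulation at the
        same absorption: agreement within 3 combined standard errors."""
        r_w, se_w = rescale_reflectance_with_se(white_db, mu_a)
        direct = simulate_reflectance(MediumOptics(mu_a, 1.0), probe,
                                      McConfig(n_photons=150_000, seed=314))
        comb = np.sqrt(se_w**2 + direct.standard_error**2)
        assert np.all(np.abs(r_w - direct.reflectance) < 3 * comb)

    def test_save_load_round_trip_and_hash_guard(self, white_db, probe,
                                                 tmp_path):
        p = tmp_path / "paths.npz"
        white_db.save(p)
        back = PathDatabase.load(p, expect_geometry=probe)
        np.testing.assert_array_equal(back.path_length_mm,
                                      white_db.path_length_mm)
        np.testing.assert_array_equal(back.exit_weight, white_db.exit_weight)
        other = ProbeGeometry(sds_mm=(1.5, 2.5))
        with pytest.raises(ValueError, match="geometry hash"):
            PathDatabase.load(p, expect_geometry=other)


class TestInterrogationDepth:
    def test_constant_depths_return_that_depth(self):
        db = PathDatabase(detector_id=np.zeros(10, int),
                          path_length_mm=np.full(10, 5.0),
                          max_depth_mm=np.full(10, 0.42),
                          exit_weight=np.ones(10), n_photons=100, seed=0,
                          geometry_hash="x", sds_mm=(1.0,))
        for stat in ("mean", "median"):
            d = interrogation_depth(db, 0.05, statistic=stat)
            assert d[0] == pytest.approx(0.42)

    def test_depth_decreases_with_absorption(self, white_db):
        depths = [interrogation_depth(white_db, m)[0]
                  for m in (0.0, 0.05, 0.2, 0.8)]
        assert all(b < a for a, b in zip(depths[:-1], depths[1:]))

    def test_skin_like_depths_in_plausible_range(self, white_db):
        """At the absorption levels of the water-overtone bands
        (mu_a 0.3-0.9 mm^-1) the interrogation depth should be a few
        hundred micrometres up to about a millimetre.  At weaker
        absorption the mean of the maximum depths is tail-dominated and
        grows beyond 1 mm (photons wander deep when little absorbs them)."""
        for mu_a in (0.3, 0.5, 0.9):
            d = interrogation_depth(white_db, mu_a)
            assert np.all(d > 0.25) and np.all(d < 1.2)
        assert interrogation_depth(white_db, 0.01)[1] > 1.0

    def test_empty_detector_warns_and_returns_nan(self):
        db = PathDatabase(detector_id=np.zeros(5, int),
                          path_length_mm=np.full(5, 3.0),
                          max_depth_mm=np.full(5, 0.3),
                          exit_weight=np.ones(5), n_photons=50, seed=0,
                          geometry_hash="x", sds_mm=(1.0, 2.0))
        with pytest.warns(UserWarning, match="detector 1"):
            d = interrogation_depth(db, 0.0)
        assert np.isnan(d[1]) and not np.isnan(d[0])


def test_diffusion_formula_sanity():
    """The closed form must decay with distance and with absorption."""
    r = diffusion_reflectance(0.01, 1.0, np.array([1.0, 2.0, 3.0]))
    assert np.all(np.diff(r) < 0)
    assert diffusion_reflectance(0.1, 1.0, 1.0) < diffusion_reflectance(
        0.01, 1.0, 1.0)
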