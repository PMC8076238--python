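import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skindrs.io import Spectrum
from skindrs.spectral import (FIRST_OVERTONE, SECOND_OVERTONE, Band,
                              BoundWaterPerturbation, apply_bound_water_model,
                              fit_power_law, fit_pure_water, get_band,
                              synthetic_water_reference)

BANDS = [SECOND_OVERTONE, FIRST_OVERTONE]


@pytest.fixture(scope="module")
def ref():
    return synthetic_water_reference()


class TestWaterReference:
    def test_overtone_structure(self, ref):
        wl = ref.wavelength_nm
        assert wl.min() <= 925 and wl.max() >= 1400
        assert np.all(ref.mu_a > 0)
        assert np.all(np.diff(wl) > 0)
        i970 = np.argmin(np.abs(wl - 970))
        assert ref.mu_a[i970] > ref.mu_a[np.argmin(np.abs(wl - 940))]
        assert ref.mu_a[i970] > ref.mu_a[np.argmin(np.abs(wl - 1000))]
        # steep first-overtone rise past the analysis window
        assert ref.interp(np.array([1400.0]))[0] > ref.interp(np.array([1380.0]))[0] > ref.interp(np.array([1300.0]))[0]


class TestFitPureWater:
    @pytest.mark.parametrize("band", BANDS, ids=lambda b: b.name)
    @pytest.mark.parametrize("c", [0.3, 0.7, 1.0, 2.5])
    def test_exact_scaled_reference_recovers_amplitude(self, ref, band, c):
        sp = Spectrum(ref.wavelength_nm, c * ref.mu_a, kind="absorption")
        res = fit_pure_water(sp, band, ref)
        assert res.amplitude == pytest.approx(c, rel=1e-12)
        assert res.rho == pytest.approx(0.0, abs=1e-20)

    def test_rho_scales_quadratically_under_joint_scaling(self, ref):
        wl = np.arange(940.0, 1001.0)
        shape = ref.interp(wl) + 0.01 * np.sin((wl - 940) / 8.0)
        base = fit_pure_water(Spectrum(wl, shape), SECOND_OVERTONE, ref).rho
        for k in (2.0, 5.0):
            scaled = fit_pure_water(Spectrum(wl, k * shape),
                                    SECOND_OVERTONE, ref).rho
            assert scaled == pytest.approx(k**2 * base, rel=1e-9)

    def test_matches_brute_force_grid_search_on_shifted_water(self, ref):
        """A +5 nm shifted water spectrum: the analytic amplitude and rho
        must match a fine 1-D grid minimization over c."""
        wl = np.arange(940.0, 1001.0)
        shifted = ref.interp(wl - 5.0)
        sp = Spectrum(wl, shifted)
        res = fit_pure_water(sp, SECOND_OVERTONE, ref)
        w = ref.interp(wl)
        cs = np.linspace(0.0, 3.0, 300_001)
        rss = ((shifted[None, :] - cs[:, None] * w[None, :]) ** 2).sum(axis=1)
        best = np.argmin(rss)
        assert res.amplitude == pytest.approx(cs[best], abs=2e-5)
        assert res.rho == pytest.approx(100.0 * rss[best] / wl.size, rel=1e-6)
        assert res.rho > 0

    def test_insufficient_points_rejected(self, ref):
        sp = Spectrum(np.array([950.0, 960.0, 970.0]), np.ones(3))
        with pytest.raises(ValueError, match="insufficient"):
            fit_pure_water(sp, SECOND_OVERTONE, ref)

    def test_rho_invariant_to_point_reordering(self, ref):
        wl = np.arange(1230.0, 1381.0, 5.0)
        vals = ref.interp(wl) * 0.8 + 0.02
        r1 = fit_pure_water(Spectrum(wl, vals), FIRST_OVERTONE, ref).rho
        order = np.random.RandomState(3).permutation(wl.size)
        with pytest.warns(UserWarning):
            sp2 = Spectrum(wl[order], vals[order])
        r2 = fit_pure_water(sp2, FIRST_OVERTONE, ref).rho
        assert r1 == pytest.approx(r2, rel=1e-12)


class TestBoundWaterModel:
    @pytest.mark.parametrize("band", BANDS, ids=lambda b: b.name)
    def test_identity_when_no_bound_fraction(self, ref, band):
        out = apply_bound_water_model(ref, BoundWaterPerturbation(3.0, 1.2, 0.0),
                                      band)
        np.testing.assert_allclose(out.values, ref.interp(out.wavelength_nm),
                                   rtol=1e-12)

    def test_identity_when_no_shape_change(self, ref):
        out = apply_bound_water_model(ref, BoundWaterPerturbation(0.0, 1.0, 0.7),
                                      SECOND_OVERTONE)
        np.testing.assert_allclose(out.values, ref.interp(out.wavelength_nm),
                                   rtol=1e-12)

    def test_red_shift_gives_positive_residual(self, ref):
        """Second-overtone defaults (red shift +3 nm) must break the pure
        water shape and yield rho > 0."""
        out = apply_bound_water_model(ref, BoundWaterPerturbation(3.0, 1.0, 0.5),
                                      SECOND_OVERTONE)
        res = fit_pure_water(out, SECOND_OVERTONE, ref)
        assert res.rho > 0

    @pytest.mark.parametrize("band,pert", [
        (SECOND_OVERTONE, (3.0, 1.0)),
        (FIRST_OVERTONE, (-15.0, 1.25)),
    ], ids=["second", "first"])
    def test_rho_nondecreasing_in_bound_fraction(self, ref, band, pert):
        shift, width = pert
        rhos = []
        for fb in (0.0, 0.25, 0.5, 0.75, 1.0):
            out = apply_bound_water_model(
                ref, BoundWaterPerturbation(shift, width, fb), band)
            rhos.append(fit_pure_water(out, band, ref).rho)
        assert rhos[0] == pytest.approx(0.0, abs=1e-20)
        assert all(b > a for a, b in zip(rhos[:-1], rhos[1:]))

    def test_continuity_in_parameters(self, ref):
        """Small parameter changes produce small spectral changes."""
        base = apply_bound_water_model(
            ref, BoundWaterPerturbation(3.0, 1.1, 0.5), SECOND_OVERTONE)
        for dp in (1e-4, 1e-6):
            pert = BoundWaterPerturbation(3.0 + dp, 1.1 + dp, 0.5 + dp)
            out = apply_bound_water_model(ref, pert, SECOND_OVERTONE)
            assert np.max(np.abs(out.values - base.values)) < 100 * dp

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            BoundWaterPerturbation(width_factor=0.5)
        with pytest.raises(ValueError):
            BoundWaterPerturbation(bound_fraction=1.5)


class TestPowerLaw:
    @pytest.mark.parametrize("a,b", [
        (315.565, 0.808),       # second-overtone lesion magnitude scale
        (330.316, 0.777),
        (257912.881, 1.762),    # first-overtone extreme
        (484.744, 0.823),
        (10.0, 0.3),
        (1e6, 2.5),
    ])
    def test_noiseless_round_trip(self, a, b):
        band = SECOND_OVERTONE if a < 1e4 else FIRST_OVERTONE
        wl = np.arange(band.lo_nm, band.hi_nm + 1.0, 2.0)
        sp = Spectrum(wl, a * wl ** (-b), kind="reduced_scattering")
        fit = fit_power_law(sp, band)
        assert fit.a == pytest.approx(a, rel=1e-6)
        assert fit.b == pytest.approx(b, rel=1e-6)

    def test_constant_spectrum_is_flat_power_law(self):
        wl = np.arange(940.0, 1001.0, 2.0)
        fit = fit_power_law(Spectrum(wl, np.full_like(wl, 1.2)),
                            SECOND_OVERTONE)
        assert fit.b == pytest.approx(0.0, abs=1e-9)
        assert fit.a == pytest.approx(1.2, rel=1e-9)

    def test_matches_loglog_regression_oracle_on_noiseless_data(self):
        wl = np.arange(1230.0, 1381.0, 2.0)
        y = 500.0 * wl ** (-0.9)
        fit = fit_power_law(Spectrum(wl, y), FIRST_OVERTONE)
        slope, intercept = np.polyfit(np.log(wl), np.log(y), 1)
        assert fit.b == pytest.approx(-slope, rel=1e-8)
        assert fit.a == pytest.approx(np.exp(intercept), rel=1e-8)

    def test_nonpositive_values_named(self):
        wl = np.arange(940.0, 1001.0, 2.0)
        y = 300.0 * wl ** (-0.8)
        y[5] = -0.1
        with pytest.raises(ValueError, match="950"):
            fit_power_law(Spectrum(wl, y), SECOND_OVERTONE)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(c=st.floats(min_value=1e-3, max_value=1e3),
       band_name=st.sampled_from(["second", "first"]))
def test_scaled_reference_always_fits_exactly(c, band_name):
    """Invariant: any positive rescaling of the pure-water reference gives
    amplitude c and zero residual on either band."""
    ref = synthetic_water_reference()
    band = get_band(band_name)
    sp = Spectrum(ref.wavelength_nm, c * ref.mu_a)
    res = fit_pure_water(sp, band, ref)
    assert res.amplitude == pytest.approx(c, rel=1e-9)
    assert res.rho <= 1e-12 * max(1.0, c**2)


def test_band_lookup_and_validation():
    assert get_band("second").lo_nm == 940.0
    assert get_band("first_overtone").hi_nm == 1380.0
    with pytest.raises(KeyError):
        get_band("third")
    with pytest.raises(ValueError):
        Band("bad", 1000.0, 900.0, 950.0)
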