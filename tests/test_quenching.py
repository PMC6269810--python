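import numpy as np
import pytest
from hypothesis import given, strategies as st

import fluorbind as fb
from fluorbind.quenching import classify_fit


class TestSternVolmer:
    def test_no_quenching_gives_zero_ksv(self, band):
        lam = np.arange(280.0, 421.0)
        y = 100 * np.exp(-((lam - 340) ** 2) / 450)
        spectra = [fb.Spectrum(lam, y) for _ in range(5)]
        series = fb.TitrationSeries(np.linspace(0, 4e-13, 5), spectra)
        assert fb.stern_volmer_fit(series).ksv == pytest.approx(0.0, abs=1e-3)

    def test_noiseless_recovery(self, make_series):
        fit = fb.stern_volmer_fit(make_series(ksv=2e12))
        assert fit.ksv == pytest.approx(2e12, rel=1e-6)
        assert fit.kq == fit.ksv / fit.tau0

    def test_intensity_at_wavelength_readout(self, make_series):
        fit = fb.stern_volmer_fit(make_series(ksv=2e12), readout=340.0)
        assert fit.ksv == pytest.approx(2e12, rel=1e-6)

    def test_points_above_f0_excluded_with_warning(self, make_series):
        series = make_series(ksv=2e12, grid=np.linspace(0, 5e-13, 8))
        series.spectra[3] = series.spectra[3].scaled(3.0)  # F > F0 outlier
        with pytest.warns(UserWarning, match="F > F0"):
            fit = fb.stern_volmer_fit(series)
        assert fit.ksv == pytest.approx(2e12, rel=1e-6)

    def test_nonpositive_intensity_refused(self, make_series):
        series = make_series(ksv=2e12)
        series.spectra[2] = series.spectra[2].scaled(-1.0)
        with pytest.raises(ValueError, match="[Nn]onpositive"):
            fb.stern_volmer_fit(series)

    def test_two_regime_split_recovery_and_score(self, make_series):
        series = make_series("two_regime", ksv=(2.4e12, 1.2e12), split=5e-13,
                             grid=np.linspace(0, 1e-12, 13))
        single = fb.stern_volmer_fit(series)
        fit = fb.stern_volmer_fit(series, two_regime=True)
        assert fit.split_index == 6
        assert fit.ksv == pytest.approx(2.4e12, rel=1e-6)
        assert fit.ksv2 == pytest.approx(1.2e12, rel=1e-6)
        # on genuinely two-regime data the split model beats the single line
        assert fit.sse < single.sse


class TestRateConstantAndMechanism:
    @given(st.floats(1e6, 1e15), st.floats(0.1, 10.0))
    def test_rate_constant_is_linear_in_ksv(self, ksv, a):
        assert fb.quenching_rate_constant(a * ksv) == pytest.approx(
            a * fb.quenching_rate_constant(ksv), rel=1e-12)

    def test_above_diffusion_limit_is_static(self):
        assert fb.classify_mechanism(2.4e20) == "static"

    def test_below_limit_dynamic_possible(self):
        assert fb.classify_mechanism(1e9) == "dynamic_possible"

    def test_boundary_value_is_not_static(self):
        assert fb.classify_mechanism(2e10) == "dynamic_possible"

    def test_unit_mismatch_refused_with_hint(self):
        with pytest.raises(ValueError, match="per_concentration_to_per_molar"):
            fb.classify_mechanism(2.4e20, unit="mM")

    def test_classify_fit_converts_units(self, band):
        # Ksv in mM^-1 small enough that a naive read would miss 'static'
        cfg = fb.GeneratorConfig(band=band, quencher_grid=np.linspace(0, 5e-7, 6),
                                 mechanism="simple_static", ksv=2e6, unit="mM")
        fit = fb.stern_volmer_fit(fb.gen_quenching_titration(cfg))
        # kq = 2e14 mM^-1 s^-1 = 2e17 M^-1 s^-1 > 2e10
        assert classify_fit(fit) == "static"

    def test_nonpositive_tau0_refused(self):
        with pytest.raises(ValueError):
            fb.quenching_rate_constant(1e12, tau0=0.0)


class TestModifiedSternVolmer:
    def test_fully_accessible_gives_unit_intercept(self, make_series):
        series = make_series("accessible_fraction", fa=1.0, ka=1e12)
        fit = fb.modified_stern_volmer_fit(series)
        assert fit.intercept == pytest.approx(1.0, rel=1e-9)
        assert fit.fa == pytest.approx(1.0, rel=1e-9)

    def test_noiseless_two_parameter_recovery(self, make_series):
        fit = fb.modified_stern_volmer_fit(
            make_series("accessible_fraction", fa=0.8, ka=1e12))
        assert fit.fa == pytest.approx(0.8, rel=1e-6)
        assert fit.ka == pytest.approx(1e12, rel=1e-6)

    def test_fa_unity_reproduces_plain_stern_volmer_ksv(self, make_series):
        # with fa=1 the accessible-fraction law reduces to Stern-Volmer,
        # so ka from the modified fit equals Ksv from the plain fit
        series = make_series("accessible_fraction", fa=1.0, ka=7e11)
        msv = fb.modified_stern_volmer_fit(series)
        sv = fb.stern_volmer_fit(series)
        assert msv.ka == pytest.approx(sv.ksv, rel=1e-6)

    def test_overaccessible_fraction_flagged_not_clamped(self, make_series):
        series = make_series("accessible_fraction", fa=1.23, ka=1e5,
                             grid=np.linspace(0, 2e-5, 11))
        with pytest.warns(UserWarning, match="unphysical"):
            fit = fb.modified_stern_volmer_fit(series)
        assert fit.unphysical
        assert fit.fa == pytest.approx(1.23, rel=1e-6)  # raw value retained

    def test_two_regime_split_index_matches_generator(self, make_series):
        series = make_series("two_regime", ksv=(2.4e12, 1.2e12), split=5e-13,
                             grid=np.linspace(0, 1e-12, 13))
        res = fb.modified_stern_volmer_fit(series, two_regime=True)
        assert res.split_index == 6
        assert res.sse < res.sse_single


class TestDoubleLog:
    def test_single_site_data_gives_unit_exponent(self, make_series):
        fit = fb.double_log_fit(make_series(ksv=2e12))
        assert fit.n == pytest.approx(1.0, rel=1e-6)

    def test_noiseless_hill_recovery(self, make_series):
        series = make_series("hill", ka=1e6, n_hill=1.21,
                             grid=np.concatenate([[0], np.logspace(-7, -5, 10)]))
        fit = fb.double_log_fit(series)
        assert fit.n == pytest.approx(1.21, rel=1e-6)
        assert fit.log_ka == pytest.approx(6.0, abs=1e-6)

    def test_agrees_with_stern_volmer_on_simple_static(self, make_series):
        # Eq consistency: simple-static data satisfies the Hill law with n=1
        # and KA=Ksv, so the two independent fits must agree
        series = make_series(ksv=2e12)
        sv = fb.stern_volmer_fit(series)
        dl = fb.double_log_fit(series)
        assert dl.n == pytest.approx(1.0, rel=1e-4)
        assert dl.ka == pytest.approx(sv.ksv, rel=1e-4)

    def test_unquenched_points_dropped_with_warning(self, band):
        lam = np.arange(280.0, 421.0)
        y0 = 100 * np.exp(-((lam - 340) ** 2) / 450)
        grid = np.array([0.0, 1e-13, 2e-13, 3e-13, 4e-13])
        scales = 1 / (1 + 2e12 * grid)
        scales[1] = 1.0  # an unquenched point
        spectra = [fb.Spectrum(lam, y0 * s) for s in scales]
        series = fb.TitrationSeries(grid, spectra)
        with pytest.warns(UserWarning, match="unquenched"):
            fit = fb.double_log_fit(series)
        assert fit.n == pytest.approx(1.0, rel=1e-4)
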