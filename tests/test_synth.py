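import numpy as np
import pytest

import fluorbind as fb


class TestEmissionBand:
    def test_unshifted_peak_value_and_position(self, band):
        s = fb.gen_emission_band(band, (280.0, 420.0, 1.0), concentration=0.0)
        assert fb.peak_intensity(s) == pytest.approx(100.0, rel=1e-6)
        assert fb.emission_maximum(s) == pytest.approx(340.0, abs=1e-9)

    def test_red_shift_linear_in_concentration(self):
        # 2.4e5 nm/mM at 8.33e-6 mM shifts the 340-nm band to ~342 nm
        band = fb.BandModel(center=340.0, width=15.0, amplitude=100.0,
                            shift_rate=2.4e5)
        c = 8.33e-6
        s = fb.gen_emission_band(band, (280.0, 420.0, 1.0), concentration=c)
        assert fb.emission_maximum(s) == pytest.approx(340.0 + 2.4e5 * c,
                                                       abs=0.01)

    def test_zero_amplitude_gives_null_band(self):
        band = fb.BandModel(amplitude=0.0)
        s = fb.gen_emission_band(band, (280.0, 420.0, 1.0))
        assert np.all(s.intensities == 0.0)

    def test_narrow_grid_refused(self, band):
        with pytest.raises(ValueError, match="too narrow"):
            fb.gen_emission_band(band, (330.0, 350.0, 1.0))


class TestQuenchingTitration:
    def test_half_quenching_at_reciprocal_ksv(self, band):
        # Eq: F0/F = 1 + Ksv[Q]; Ksv=2e12, [Q]=5e-13 -> F0/F = 2
        cfg = fb.GeneratorConfig(band=band, quencher_grid=np.array([0.0, 5e-13]),
                                 mechanism="simple_static", ksv=2e12)
        series = fb.gen_quenching_titration(cfg)
        f0 = fb.peak_intensity(series.spectra[0])
        f = fb.peak_intensity(series.spectra[1])
        assert f == pytest.approx(f0 / 2, rel=1e-12)

    def test_zero_concentration_matches_unquenched_band(self, make_series):
        series = make_series(ksv=2e12)
        ref = fb.gen_emission_band(fb.BandModel(), (280.0, 420.0, 1.0))
        assert np.array_equal(series.spectra[0].intensities, ref.intensities)

    def test_seeded_determinism(self, band):
        cfg = dict(band=band, quencher_grid=np.linspace(0, 5e-13, 6),
                   mechanism="simple_static", ksv=2e12, noise_sd=0.05, seed=7)
        a = fb.gen_quenching_titration(fb.GeneratorConfig(**cfg))
        b = fb.gen_quenching_titration(fb.GeneratorConfig(**cfg))
        for sa, sb in zip(a.spectra, b.spectra):
            assert np.array_equal(sa.intensities, sb.intensities)

    def test_unphysical_accessible_fraction_refused(self, band):
        cfg = fb.GeneratorConfig(band=band,
                                 quencher_grid=np.linspace(0, 1e-3, 6),
                                 mechanism="accessible_fraction",
                                 fa=1.5, ka=1e8)
        with pytest.raises(ValueError, match="unphysical"):
            fb.gen_quenching_titration(cfg)

    @pytest.mark.parametrize("mechanism,params", [
        ("simple_static", dict(ksv=2e12, grid=np.linspace(0, 5e-13, 11))),
        ("accessible_fraction", dict(fa=0.8, ka=1e12,
                                     grid=np.linspace(0, 5e-13, 11))),
        ("two_regime", dict(ksv=(2.4e12, 2.2e12), split=5e-13,
                            grid=np.linspace(0, 1e-12, 13))),
        ("hill", dict(ka=1e6, n_hill=1.21,
                      grid=np.concatenate([[0], np.logspace(-7, -5, 10)]))),
    ])
    def test_noiseless_f_nonincreasing_in_concentration(self, make_series,
                                                        mechanism, params):
        series = make_series(mechanism, **params)
        f = [fb.peak_intensity(s) for s in series.spectra]
        assert np.all(np.diff(f) <= 1e-9 * f[0])

    def test_round_trip_simple_static(self, make_series):
        fit = fb.stern_volmer_fit(make_series(ksv=2e12))
        assert fit.ksv == pytest.approx(2e12, rel=1e-6)

    def test_round_trip_accessible_fraction(self, make_series):
        series = make_series("accessible_fraction", fa=0.8, ka=1e12)
        fit = fb.modified_stern_volmer_fit(series)
        assert fit.fa == pytest.approx(0.8, rel=1e-6)
        assert fit.ka == pytest.approx(1e12, rel=1e-6)
        assert not fit.unphysical

    def test_round_trip_two_regime(self, make_series):
        series = make_series("two_regime", ksv=(2.4e12, 2.2e12), split=5e-13,
                             grid=np.linspace(0, 1e-12, 13))
        fit = fb.stern_volmer_fit(series, two_regime=True)
        assert fit.ksv == pytest.approx(2.4e12, rel=1e-6)
        assert fit.ksv2 == pytest.approx(2.2e12, rel=1e-6)
        assert fit.regime_split == pytest.approx(5e-13, rel=1e-9)

    def test_round_trip_hill(self, make_series):
        series = make_series("hill", ka=1e6, n_hill=1.21,
                             grid=np.concatenate([[0], np.logspace(-7, -5, 10)]))
        fit = fb.double_log_fit(series)
        assert fit.n == pytest.approx(1.21, rel=1e-6)
        assert fit.ka == pytest.approx(1e6, rel=1e-6)

    def test_noise_bias_envelope_over_replicates(self, band):
        # sanity envelope: relative bias of the fitted Ksv stays below the
        # injected relative noise level over 200 seeded replicates (fixed-
        # wavelength readout; the peak readout picks the maximum of noisy
        # samples and carries a selection bias by construction)
        noise_sd, ksv = 0.02, 2e12
        master = np.random.default_rng(20260922)
        seeds = master.integers(0, 2**31, size=200)
        grid = np.linspace(0, 5e-13, 11)
        fits = []
        for seed in seeds:
            cfg = fb.GeneratorConfig(band=band, quencher_grid=grid,
                                     mechanism="simple_static", ksv=ksv,
                                     noise_sd=noise_sd, seed=int(seed))
            series = fb.gen_quenching_titration(cfg)
            fits.append(fb.stern_volmer_fit(series, readout=340.0).ksv)
        rel_bias = abs(np.mean(fits) - ksv) / ksv
        assert rel_bias < noise_sd

    def test_config_file_round_trip(self, band, tmp_path):
        cfg = fb.GeneratorConfig(band=band, quencher_grid=np.linspace(0, 5e-13, 6),
                                 mechanism="two_regime", ksv=(2.4e12, 2.2e12),
                                 split=3e-13, noise_sd=0.01, seed=42, unit="mM")
        path = tmp_path / "gen.cfg"
        fb.synth.save_config(cfg, path)
        back = fb.synth.load_config(path)
        assert back.mechanism == cfg.mechanism
        assert back.ksv == tuple(cfg.ksv)
        assert back.seed == cfg.seed and back.unit == cfg.unit
        assert np.array_equal(back.quencher_grid, cfg.quencher_grid)


class TestAbsorptionAndRls:
    def test_flat_extinction_constant(self):
        s = fb.gen_absorption_spectrum("flat", dict(eps0=1000.0), (250, 450, 1.0))
        assert np.all(s.intensities == 1000.0)

    def test_zero_extinction_null_spectrum(self):
        s = fb.gen_absorption_spectrum("flat", dict(eps0=0.0), (250, 450, 1.0))
        assert np.all(s.intensities == 0.0)

    def test_negative_extinction_refused(self):
        with pytest.raises(ValueError):
            fb.gen_absorption_spectrum("flat", dict(eps0=-1.0), (250, 450, 1.0))

    def test_disjoint_acceptor_gives_negligible_overlap(self, band):
        # narrow acceptor far below the donor band: brute-force J ~ 0
        donor = fb.gen_emission_band(band, (280.0, 420.0, 1.0))
        acc = fb.gen_absorption_spectrum(
            "gaussian", dict(center=270.0, width=0.5, eps_max=1e4),
            (280.0, 420.0, 1.0))
        flat = fb.gen_absorption_spectrum("flat", dict(eps0=1e4),
                                          (280.0, 420.0, 1.0))
        assert fb.overlap_integral(donor, acc) < 1e-6 * fb.overlap_integral(donor, flat)

    def test_rls_zero_slope_flat(self):
        curve = fb.gen_rls_series(5e-7, 100.0, 0.0, np.linspace(0, 1e-6, 21))
        assert np.all(curve.intensities == 100.0)

    def test_rls_seeded_determinism(self):
        a = fb.gen_rls_series(5e-7, 100.0, 1e8, np.linspace(0, 1e-6, 21),
                              noise_sd=0.02, seed=3)
        b = fb.gen_rls_series(5e-7, 100.0, 1e8, np.linspace(0, 1e-6, 21),
                              noise_sd=0.02, seed=3)
        assert np.array_equal(a.intensities, b.intensities)

    def test_rls_onset_outside_grid_refused(self):
        with pytest.raises(ValueError, match="strictly inside"):
            fb.gen_rls_series(2e-6, 100.0, 1e8, np.linspace(0, 1e-6, 21))
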