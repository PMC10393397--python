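"""Sharpe-Schoolfield curve, fitting, and trait extraction."""

import numpy as np
import pytest

import ctpc
from ctpc.tpc import CELSIUS_TO_KELVIN

from conftest import run_trace_pipeline, synthetic_hr_series


class TestSSRate:
    def test_rate_at_reference_when_inactivation_negligible(self):
        p = ctpc.SSParams(r_tref=55.0, E=0.6, Eh=6.0, Th=400.0)  # Th >> Tref
        assert ctpc.ss_rate(p, ctpc.TREF_C) == pytest.approx(55.0, rel=1e-6)

    def test_half_inactivation_at_th(self):
        p = ctpc.SSParams(r_tref=60.0, E=0.8, Eh=4.0, Th=320.0)
        t_h_C = 320.0 - CELSIUS_TO_KELVIN
        # at T = Th the inactivation denominator equals exactly 2
        arrhenius_only = ctpc.SSParams(60.0, 0.8, 4.0, 10_000.0)
        assert ctpc.ss_rate(p, t_h_C) == pytest.approx(
            ctpc.ss_rate(arrhenius_only, t_h_C) / 2.0, rel=1e-9)

    def test_unimodal_with_single_interior_maximum(self):
        p = ctpc.SSParams(60.0, 0.8, 4.0, 320.0)
        grid = np.linspace(-10.0, 70.0, 4001)
        r = np.asarray(ctpc.ss_rate(p, grid))
        assert np.all(r > 0)
        signs = np.sign(np.diff(r))
        # increasing then decreasing: exactly one sign change
        assert np.sum(np.diff(signs) != 0) == 1

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ctpc.SSParams(60.0, 4.0, 0.8, 320.0)
        with pytest.raises(ValueError):
            ctpc.SSParams(-1.0, 0.8, 4.0, 320.0)


class TestToptClosedForm:
    def test_matches_numerical_argmax_on_parameter_grid(self):
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(100):
            E = rng.uniform(0.2, 1.5)
            Eh = rng.uniform(2.0, 8.0)
            topt_target = rng.uniform(38.0, 50.0)
            p = ctpc.SSParams(60.0, E, Eh, ctpc.th_for_topt(E, Eh, topt_target))
            closed = ctpc.topt_closed_form(p)
            grid = np.arange(closed - 5.0, closed + 5.0, 0.001)
            numeric = grid[np.argmax(np.asarray(ctpc.ss_rate(p, grid)))]
            worst = max(worst, abs(numeric - closed))
        assert worst <= 0.02

    def test_th_for_topt_inverts_closed_form(self):
        p = ctpc.SSParams(60.0, 0.8, 4.0, ctpc.th_for_topt(0.8, 4.0, 44.0))
        assert ctpc.topt_closed_form(p) == pytest.approx(44.0, abs=1e-9)


class TestFitSS:
    def test_exact_data_recovered(self):
        truth = ctpc.SSParams(60.0, 0.8, 4.0, 320.0)
        series = synthetic_hr_series(truth)
        fit = ctpc.fit_ss(series, n_starts=10, seed=0)
        assert fit.fit_ok
        assert fit.rss == pytest.approx(0.0, abs=1e-6)
        assert fit.params.E == pytest.approx(0.8, rel=1e-3)
        assert fit.params.Th == pytest.approx(320.0, abs=0.05)

    def test_constant_series_degenerate(self):
        temps = np.arange(30.0, 50.0, 1.0)
        series = ctpc.HeartRateSeries(temps, np.full_like(temps, 60.0),
                                      np.full(len(temps), 30, dtype=int),
                                      np.arange(len(temps)) * 30.0, 60.0, 30.0)
        fit = ctpc.fit_ss(series, n_starts=10, seed=0)
        assert (not fit.fit_ok) or fit.params.E < 0.05 or fit.rss < 1e-8

    def test_too_few_windows_flagged(self):
        truth = ctpc.SSParams(60.0, 0.8, 4.0, 320.0)
        series = synthetic_hr_series(truth, temps=np.arange(30.0, 34.0, 1.0))
        fit = ctpc.fit_ss(series, seed=0)
        assert not fit.fit_ok

    def test_best_of_starts_never_worse_than_single_start(self):
        truth = ctpc.SSParams(60.0, 0.8, 4.0, 320.0)
        rng = np.random.default_rng(3)
        temps = np.arange(30.0, 52.0, 0.5)
        hr = np.asarray(ctpc.ss_rate(truth, temps)) + rng.normal(0, 5.0, temps.size)
        series = ctpc.HeartRateSeries(temps, np.abs(hr),
                                      np.round(hr).astype(int),
                                      np.arange(len(temps)) * 30.0, 60.0, 30.0)
        multi = ctpc.fit_ss(series, n_starts=15, seed=0)
        singles = [ctpc.fit_ss(series, n_starts=1, seed=s) for s in range(5)]
        for s in singles:
            if s.fit_ok:
                assert multi.rss <= s.rss + 1e-9

    def test_recovery_degrades_with_noise(self, default_traits, fast_ramp):
        errs = []
        for noise in (0.0, 0.2, 0.6):
            per_seed = []
            for seed in range(3):
                tr = ctpc.simulate_trace(default_traits, fast_ramp,
                                         noise_sd=noise, seed=seed)
                traits, _, _ = run_trace_pipeline(tr, seed=seed)
                per_seed.append(abs(traits.slope_gradient - default_traits.E))
            errs.append(np.median(per_seed))
        assert errs[0] <= errs[-1]


class TestUpslopeCurvature:
    def test_linear_input_zero_curvature(self):
        temps = np.arange(30.0, 40.0, 1.0)
        hr = 10.0 + 2.0 * temps
        series = ctpc.HeartRateSeries(temps, hr, np.round(hr).astype(int),
                                      np.arange(len(temps)) * 30.0, 60.0, 30.0)
        poly = ctpc.upslope_curvature(series, topt=45.0)
        assert poly.curvature == pytest.approx(0.0, abs=1e-9)

    def test_exact_quadratic_recovered(self):
        temps = np.arange(1.0, 11.0, 1.0)
        hr = 1.0 + temps - 0.5 * temps ** 2
        series = ctpc.HeartRateSeries(temps, hr, np.ones(len(temps), dtype=int),
                                      np.arange(len(temps)) * 30.0, 60.0, 30.0)
        poly = ctpc.upslope_curvature(series, topt=20.0)
        assert poly.curvature == pytest.approx(-1.0, abs=1e-9)

    def test_only_points_below_topt_used(self):
        temps = np.arange(30.0, 50.0, 1.0)
        hr = 5.0 + temps
        series = ctpc.HeartRateSeries(temps, hr, np.ones(len(temps), dtype=int),
                                      np.arange(len(temps)) * 30.0, 60.0, 30.0)
        poly = ctpc.upslope_curvature(series, topt=40.0)
        assert poly.n_points == np.sum(temps < 40.0)

    def test_duplicated_points_leave_curvature_unchanged(self):
        temps = np.arange(1.0, 9.0, 1.0)
        hr = 2.0 + 3.0 * temps - 0.25 * temps ** 2
        dup_t = np.concatenate([temps, temps])
        dup_hr = np.concatenate([hr, hr])
        order = np.argsort(dup_t, kind="stable")
        s1 = ctpc.HeartRateSeries(temps, hr, np.ones(len(temps), dtype=int),
                                  np.arange(len(temps)) * 30.0, 60.0, 30.0)
        s2 = ctpc.HeartRateSeries(dup_t[order], dup_hr[order],
                                  np.ones(len(dup_t), dtype=int),
                                  np.arange(len(dup_t)) * 30.0, 60.0, 30.0)
        c1 = ctpc.upslope_curvature(s1, topt=20.0).curvature
        c2 = ctpc.upslope_curvature(s2, topt=20.0).curvature
        assert c1 == pytest.approx(c2, abs=1e-9)

    def test_too_few_points_gives_none(self):
        temps = np.array([30.0, 31.0, 45.0, 46.0])
        hr = np.array([50.0, 55.0, 90.0, 85.0])
        series = ctpc.HeartRateSeries(temps, hr, np.ones(4, dtype=int),
                                      np.arange(4) * 30.0, 60.0, 30.0)
        assert ctpc.upslope_curvature(series, topt=33.0) is None


class TestExtractTraits:
    def test_numerical_topt_matches_closed_form(self):
        truth = ctpc.SSParams(60.0, 0.8, 4.0, ctpc.th_for_topt(0.8, 4.0, 44.0))
        series = synthetic_hr_series(truth)
        fit = ctpc.fit_ss(series, n_starts=10, seed=0)
        traits = ctpc.extract_traits(fit, series)
        assert traits.t_opt == pytest.approx(ctpc.topt_closed_form(fit.params),
                                             abs=0.02)
        assert traits.hr_max >= np.max(np.asarray(
            ctpc.ss_rate(fit.params, series.temp_mid))) - 1e-6

    def test_missing_flatline_leaves_other_traits(self):
        truth = ctpc.SSParams(60.0, 0.8, 4.0, 320.0)
        series = synthetic_hr_series(truth)
        fit = ctpc.fit_ss(series, n_starts=10, seed=0)
        traits = ctpc.extract_traits(fit, series, flatline=None)
        assert traits.ult is None
        assert traits.t_opt is not None and traits.hr_max is not None

    def test_end_to_end_recovery_on_generated_trace(self, default_traits,
                                                    assay_ramp):
        tr = ctpc.simulate_trace(default_traits, assay_ramp, noise_sd=0.2, seed=11)
        traits, _, flat = run_trace_pipeline(tr, seed=11)
        true_topt = ctpc.topt_closed_form(default_traits.ss_params)
        assert traits.fit_ok
        assert traits.slope_gradient == pytest.approx(default_traits.E, rel=0.15)
        assert traits.t_opt == pytest.approx(true_topt, abs=0.5)
        assert traits.ult == pytest.approx(default_traits.ULT_true, abs=0.5)
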