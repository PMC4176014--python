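"""Growth-curve evaluation, fitting, model selection and moult timing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from moultfit import BirdSeries, DataError, ParameterError, growth
from moultfit.growth import (GrowthFit, aicc, delta_rate_observed,
                             evidence_ratio, fit_growth, gompertz_value,
                             logistic_value, moult_timing, summarize_cohorts,
                             time_at_fraction)

from conftest import zero_noise_template
from moultfit import synthetic


def make_fit(A, mu, lam, model="gompertz"):
    return GrowthFit(model, A, mu, lam, 0.0, 12, np.nan, True)


class TestCurveValues:
    def test_gompertz_inflection_is_a_over_e(self):
        A, mu, lam = 137.7, 5.91, 10.0
        t_inf = lam + A / (mu * math.e)
        assert gompertz_value(t_inf, A, mu, lam) == pytest.approx(A / math.e, rel=1e-12)

    def test_gompertz_asymptote(self):
        assert gompertz_value(1e6, 100.0, 5.0, 0.0) == pytest.approx(100.0, abs=1e-6)

    def test_gompertz_matches_direct_scalar_evaluation(self):
        # independent hand evaluation of A*exp(-exp((mu*e/A)*(lam-t)+1))
        A, mu, lam, t = 137.7, 5.91, 10.0, 20.0
        inner = (mu * math.exp(1) / A) * (lam - t) + 1.0
        expected = A * math.exp(-math.exp(inner))
        assert gompertz_value(t, A, mu, lam) == pytest.approx(expected, rel=1e-14)

    def test_logistic_inflection_and_asymptote(self):
        A, mu, lam = 150.0, 4.0, 5.0
        assert logistic_value(lam + A / (2 * mu), A, mu, lam) == pytest.approx(A / 2)
        assert logistic_value(1e6, A, mu, lam) == pytest.approx(A, abs=1e-6)

    def test_logistic_max_slope_is_mu(self):
        A, mu, lam = 150.0, 4.0, 5.0
        t = lam + A / (2 * mu)
        h = 1e-5
        d = (logistic_value(t + h, A, mu, lam) - logistic_value(t - h, A, mu, lam)) / (2 * h)
        assert d == pytest.approx(mu, rel=1e-4)

    @pytest.mark.parametrize("func", [gompertz_value, logistic_value])
    def test_nonpositive_parameters_rejected(self, func):
        with pytest.raises(ParameterError):
            func(0.0, -1.0, 5.0, 0.0)
        with pytest.raises(ParameterError):
            func(0.0, 100.0, 0.0, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(A=st.floats(50, 300), mu=st.floats(1, 10), lam=st.floats(-30, 260))
    def test_gompertz_monotone_with_max_slope_mu(self, A, mu, lam):
        # window between the 0.01% and 99.9% crossings, clear of underflow
        fit = make_fit(A, mu, lam)
        t = np.linspace(time_at_fraction(fit, 1e-4),
                        time_at_fraction(fit, 0.999), 4000)
        y = gompertz_value(t, A, mu, lam)
        assert np.all(np.diff(y) > 0)
        slopes = np.diff(y) / np.diff(t)
        assert slopes.max() <= mu * (1 + 1e-3)
        assert slopes.max() == pytest.approx(mu, rel=5e-3)


class TestModelSelection:
    def test_evidence_ratio_values(self):
        assert evidence_ratio(10.0, 10.0) == pytest.approx(1.0)
        # printed support ratio 5.76 corresponds to an AICc gap of 3.503
        assert evidence_ratio(103.503, 100.0) == pytest.approx(5.76, abs=0.01)
        assert evidence_ratio(2 * math.log(2), 0.0) == pytest.approx(2.0)

    def test_aicc_approaches_aic_for_large_n(self):
        n, k, rss = 10**6, 4, 123.0
        aic = n * math.log(rss / n) + 2 * k
        assert aicc(rss, n, k) / aic == pytest.approx(1.0, rel=1e-9)

    def test_aicc_undefined_below_minimum_n(self):
        assert aicc(1.0, 5) == math.inf


class TestTimeAtFraction:
    def test_inflection_identity(self):
        fit = make_fit(137.7, 5.91, 10.0)
        expected = 10.0 + 137.7 / (5.91 * math.e)
        assert time_at_fraction(fit, math.exp(-1)) == pytest.approx(expected, rel=1e-12)

    def test_round_trip_against_bisection(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            A = rng.uniform(60, 250)
            mu = rng.uniform(1, 9)
            lam = rng.uniform(-20, 250)
            f = rng.uniform(0.01, 0.99)
            fit = make_fit(A, mu, lam)
            t = time_at_fraction(fit, f)
            assert gompertz_value(t, A, mu, lam) == pytest.approx(f * A, abs=1e-9 * A)
            # independent root-finder on the curve agrees
            t_oracle = brentq(lambda s: gompertz_value(s, A, mu, lam) - f * A,
                              lam - 200, lam + 2000, xtol=1e-10)
            assert t == pytest.approx(t_oracle, abs=1e-7)

    def test_monotone_in_fraction(self):
        fit = make_fit(150.0, 4.0, 0.0)
        days = [time_at_fraction(fit, f) for f in np.linspace(0.02, 0.98, 25)]
        assert np.all(np.diff(days) > 0)

    @pytest.mark.parametrize("f", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_fraction_rejected(self, f):
        with pytest.raises(ParameterError):
            time_at_fraction(make_fit(100, 5, 0), f)


def _series_from_curve(A, mu, lam, days=None, model=gompertz_value):
    days = np.arange(0, 84, 7, dtype=float) if days is None else days
    return BirdSeries("b1", "HADU", "F", days, model(days, A, mu, lam))


class TestFitGrowth:
    def test_zero_noise_recovery(self):
        A, mu, lam = 150.0, 4.0, 5.0
        fit = fit_growth(_series_from_curve(A, mu, lam, np.arange(0, 84, 7.0)))
        assert fit.converged
        assert fit.A == pytest.approx(A, abs=0.1)
        assert fit.mu == pytest.approx(mu, abs=0.01)
        assert fit.lambda_ == pytest.approx(lam, abs=0.05)

    def test_logistic_zero_noise_recovery(self):
        A, mu, lam = 150.0, 4.0, 5.0
        s = _series_from_curve(A, mu, lam, model=logistic_value)
        fit = fit_growth(s, model="logistic")
        assert fit.converged
        assert fit.A == pytest.approx(A, abs=0.1)
        assert fit.mu == pytest.approx(mu, abs=0.01)

    def test_gompertz_preferred_on_gompertz_truth(self):
        rng = np.random.default_rng(3)
        days = np.arange(0, 98, 7.0)
        y = gompertz_value(days, 150.0, 4.0, 5.0) + rng.normal(0, 1.0, days.size)
        s = BirdSeries("b", "HADU", "F", days, np.clip(y, 0, None))
        g = fit_growth(s, "gompertz")
        l = fit_growth(s, "logistic")
        assert g.aicc < l.aicc
        assert evidence_ratio(l.aicc, g.aicc) > 1.0

    def test_constant_series_reports_nonconvergence(self):
        s = BirdSeries("b", "HADU", "F", np.arange(5.0), np.full(5, 30.0))
        fit = fit_growth(s)
        assert not fit.converged
        assert fit.message

    def test_too_few_points_raises(self):
        s = BirdSeries("b", "HADU", "F", [0, 7, 14], [1.0, 10.0, 30.0])
        with pytest.raises(DataError):
            fit_growth(s)

    def test_missing_preshed_points_excluded(self):
        days = np.arange(0, 98, 7.0)
        y = gompertz_value(days, 140.0, 5.0, 20.0)
        y[:3] = np.nan  # old feather still in place
        s = BirdSeries("b", "HADU", "F", days, y)
        fit = fit_growth(s)
        assert fit.n_obs == 11
        assert fit.A == pytest.approx(140.0, abs=0.1)

    def test_noisy_recovery_bias_and_timing(self, noisy_recovery):
        _, truths, fits, timings, true_timings = noisy_recovery
        errs_A = np.array([f.A - t.true_A for f, t in zip(fits, truths)])
        assert np.all([f.converged for f in fits])
        assert abs(errs_A.mean()) < 1.0
        fl_err = np.abs([tm.flightless_days - tt.flightless_days
                         for tm, tt in zip(timings, true_timings)])
        assert np.median(fl_err) < 1.5


class TestMoultTiming:
    def test_flightless_duration_closed_form(self):
        # Delta-t between the 1 mm and 90% crossings, independent closed form
        A, mu = 137.7, 5.91
        timing = moult_timing(make_fit(A, mu, 200.0))
        f1 = 1.0 / A
        dt = (A / (mu * math.e)) * (math.log(-math.log(f1)) - math.log(-math.log(0.90)))
        assert timing.flightless_days == pytest.approx(dt, rel=1e-12)
        assert timing.flightless_days == pytest.approx(32.9, abs=0.1)

    def test_delta_to_max_ratio_is_universal_constant(self):
        # (hi-lo)*e / (ln(-ln lo) - ln(-ln hi)) with lo=0.05, hi=0.90
        const = 0.85 * math.e / (math.log(-math.log(0.05)) - math.log(-math.log(0.90)))
        rng = np.random.default_rng(11)
        for _ in range(50):
            fit = make_fit(rng.uniform(80, 250), rng.uniform(2, 8), rng.uniform(0, 250))
            timing = moult_timing(fit)
            assert timing.delta_rate / timing.max_rate == pytest.approx(const, rel=1e-12)
            # brute-force check through the crossing times themselves
            t_lo = time_at_fraction(fit, 0.05)
            t_hi = time_at_fraction(fit, 0.90)
            brute = 0.85 * fit.A / (t_hi - t_lo)
            assert timing.delta_rate == pytest.approx(brute, rel=1e-12)
        assert const == pytest.approx(0.690, abs=0.001)

    def test_flightless_invariant_to_lambda(self):
        base = moult_timing(make_fit(150.0, 4.5, 0.0))
        for shift in (-40.0, 13.0, 200.0):
            shifted = moult_timing(make_fit(150.0, 4.5, shift))
            assert shifted.flightless_days == pytest.approx(base.flightless_days, abs=1e-9)
            assert shifted.shed_day - base.shed_day == pytest.approx(shift, abs=1e-9)

    def test_degenerate_window_duration_vanishes(self):
        fit = make_fit(150.0, 4.5, 0.0)
        shed_mm = 0.899999 * 150.0
        timing = moult_timing(fit, shed_length_mm=shed_mm, flight_threshold=0.9)
        assert 0 < timing.flightless_days < 1e-3

    def test_invalid_arguments(self):
        fit = make_fit(100.0, 5.0, 0.0)
        with pytest.raises(ParameterError):
            moult_timing(fit, shed_length_mm=100.0)
        with pytest.raises(ParameterError):
            moult_timing(fit, lo=0.9, hi=0.05)

    def test_observed_delta_rate_close_to_fitted(self):
        A, mu, lam = 140.0, 5.0, 5.0
        s = _series_from_curve(A, mu, lam, np.arange(0, 120, 3.5))
        fit = fit_growth(s)
        obs = delta_rate_observed(s, fit.A)
        fitted = moult_timing(fit).delta_rate
        assert obs == pytest.approx(fitted, rel=0.05)


class TestSummarize:
    def test_single_bird_cohort_sd_zero(self):
        s = _series_from_curve(150.0, 4.0, 5.0)
        fit = fit_growth(s)
        out = summarize_cohorts([(s, fit, moult_timing(fit))])
        assert out.loc[0, "n"] == 1
        assert out.loc[0, "p9_final_mm_std"] == 0.0

    def test_zero_noise_cohort_matches_template(self):
        template = zero_noise_template()
        birds, _ = synthetic.simulate_cohort(template, seed=5)
        records = []
        for b in birds:
            fit = fit_growth(b)
            records.append((b, fit, moult_timing(fit)))
        out = summarize_cohorts(records)
        row = out.iloc[0]
        assert row["p9_final_mm_mean"] == pytest.approx(template.mean_A, rel=1e-3)
        assert row["max_rate_mean"] == pytest.approx(template.mean_mu, rel=1e-3)
        assert row["shed_day_mean"] == pytest.approx(template.mean_shed_day, rel=1e-3)
        assert row["initial_mass_g_mean"] == pytest.approx(template.mean_mass0, rel=1e-3)
        # published arithmetic: 4.66 mm/day on a 129.0 mm feather is 3.6 %/day
        assert round(float(row["max_rate_pct_mean"]), 1) == 3.6
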