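"""Per-bird feather growth-curve fitting and derived moult-timing quantities.

Flight-feather regrowth is modelled with the Zwietering parameterization of
the Gompertz curve,

    y(t) = A * exp(-exp((mu*e/A) * (lambda - t) + 1)),

where A (mm) is the asymptotic feather length, mu (mm/day) the maximum growth
rate (the slope at the inflection, reached at y = A/e), and lambda (day) the
lag-phase parameter locating the curve's takeoff.  The logistic alternative
uses the matching parameterization A / (1 + exp((4*mu/A)*(lambda - t) + 2)),
with maximum slope mu at y = A/2.  Models are compared by AICc; from the
selected curve we derive the shedding day of the old 9th primary (curve
crossing 1 mm), the day flight ability is regained (default 90% of A), the
flightless duration, and the "delta" growth rate — the average rate between
5% and 90% of final feather length.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .datatypes import MIN_P9_POINTS, BirdSeries
from .errors import DataError, ParameterError

_E = math.e


def _check_positive(A: float, mu: float) -> None:
    if not (A > 0 and mu > 0):
        raise ParameterError(f"A and mu must be positive (got A={A}, mu={mu})")


def gompertz_value(t, A: float, mu: float, lambda_: float):
    """Zwietering-Gompertz curve value at day(s) ``t``.

    Strictly increasing in t, tends to A as t -> inf, and attains its maximum
    slope mu at the inflection point t = lambda_ + A/(mu*e), where y = A/e.
    """
    _check_positive(A, mu)
    t = np.asarray(t, dtype=float)
    out = A * np.exp(-np.exp((mu * _E / A) * (lambda_ - t) + 1.0))
    return out if out.ndim else float(out)


def logistic_value(t, A: float, mu: float, lambda_: float):
    """Logistic growth-curve value at day(s) ``t`` (maximum slope mu at A/2)."""
    _check_positive(A, mu)
    t = np.asarray(t, dtype=float)
    out = A / (1.0 + np.exp((4.0 * mu / A) * (lambda_ - t) + 2.0))
    return out if out.ndim else float(out)


_MODEL_FUNCS = {"gompertz": gompertz_value, "logistic": logistic_value}


@dataclass
class GrowthFit:
    """Fitted growth-curve parameters and diagnostics for one bird.

    ``A`` (mm), ``mu`` (mm/day) and ``lambda_`` (day) are NaN when the fit did
    not converge (``converged`` is False); callers must check the flag.
    """

    model: str
    A: float
    mu: float
    lambda_: float
    rss: float
    n_obs: int
    aicc: float
    converged: bool
    message: str = ""


def aicc(rss: float, n: int, k: int = 4) -> float:
    """Small-sample corrected Akaike criterion for a least-squares fit.

    ``k`` counts the residual variance alongside the curve parameters
    (3 + 1 = 4).  Returns +inf when the correction term is undefined
    (n <= k + 1).
    """
    if n <= k + 1:
        return math.inf
    rss = max(float(rss), 1e-300)
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def evidence_ratio(aicc_worse: float, aicc_better: float) -> float:
    """Akaike evidence ratio exp((AICc_worse - AICc_better)/2)."""
    return math.exp((aicc_worse - aicc_better) / 2.0)


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float] | None:
    slopes = np.diff(y) / np.diff(t)
    if slopes.size == 0 or np.max(slopes) <= 0 or np.ptp(y) == 0:
        return None
    A0 = float(np.max(y))
    i = int(np.argmax(slopes))
    mu0 = float(slopes[i])
    t_mid = 0.5 * (t[i] + t[i + 1])
    y_mid = 0.5 * (y[i] + y[i + 1])
    lam0 = float(t_mid - y_mid / mu0)
    return A0, mu0, lam0


def fit_growth(series: BirdSeries, model: str = "gompertz",
               n_restarts: int = 10) -> GrowthFit:
    """Fit a growth curve to one bird's P9 series by nonlinear least squares.

    Multi-start strategy: a data-driven initial guess (A0 = max observed
    length, mu0 = steepest successive-difference slope, lambda0 back-projected
    from the steepest segment), then up to ``n_restarts`` log-normally
    jittered restarts, keeping the lowest residual sum of squares.
    Non-convergence is reported via ``converged=False``, never silently.
    """
    if model not in _MODEL_FUNCS:
        raise ParameterError(f"unknown model {model!r}")
    func = _MODEL_FUNCS[model]
    t, y = series.p9_observations()
    if t.size < MIN_P9_POINTS:
        raise DataError(
            f"bird {series.bird_id}: {t.size} P9 points, need >= {MIN_P9_POINTS}"
        )
    n = int(t.size)
    guess = _initial_guess(t, y)
    if guess is None:
        return GrowthFit(model, math.nan, math.nan, math.nan, math.nan, n,
                         math.inf, False, "degenerate series (no positive slope)")

    def resid(p):
        return func(t, p[0], p[1], p[2]) - y

    rng = np.random.default_rng(20080708)  # fixed: fitting is deterministic
    A0, mu0, lam0 = guess
    starts = [(A0, mu0, lam0)]
    for _ in range(n_restarts):
        f = rng.lognormal(0.0, 0.25, size=2)
        starts.append((A0 * f[0], mu0 * f[1], lam0 + rng.normal(0.0, 7.0)))

    best = None
    lo = [1e-6, 1e-6, -np.inf]
    hi = [np.inf, np.inf, np.inf]
    for j, x0 in enumerate(starts):
        try:
            res = least_squares(resid, x0, bounds=(lo, hi), ftol=1e-8,
                                xtol=1e-10, method="trf")
        except Exception:  # numerical failure on a bad start
            continue
        rss = float(2.0 * res.cost)
        if res.success and (best is None or rss < best[0] * (1 - 1e-10)):
            best = (rss, res)
        # cheap early exit: the first start almost always suffices
        if best is not None and j >= 3 and best[0] <= np.var(y) * n:
            break
    if best is None:
        return GrowthFit(model, math.nan, math.nan, math.nan, math.nan, n,
                         math.inf, False, "no convergent start")
    rss, res = best
    A, mu, lam = (float(v) for v in res.x)
    return GrowthFit(model, A, mu, lam, rss, n, aicc(rss, n), True, res.message)


def time_at_fraction(fit: GrowthFit, f: float) -> float:
    """Day at which the fitted Gompertz curve reaches fraction ``f`` of A.

    Closed-form inverse: t = lambda + (A/(mu*e)) * (1 - ln(-ln f)).
    """
    if not 0.0 < f < 1.0:
        raise ParameterError(f"fraction must lie in (0, 1), got {f}")
    if fit.model != "gompertz":
        raise ParameterError("time_at_fraction requires a Gompertz fit")
    _check_positive(fit.A, fit.mu)
    return fit.lambda_ + (fit.A / (fit.mu * _E)) * (1.0 - math.log(-math.log(f)))


@dataclass
class MoultTiming:
    """Derived per-bird moult-timing quantities (days, mm/day, %/day)."""

    shed_day: float
    flight_day: float
    flightless_days: float
    delta_rate: float
    max_rate: float
    delta_rate_pct: float
    max_rate_pct: float
    flight_threshold: float


def moult_timing(fit: GrowthFit, shed_length_mm: float = 1.0,
                 flight_threshold: float = 0.90,
                 lo: float = 0.05, hi: float = 0.90) -> MoultTiming:
    """Shedding day, flight-regain day, flightless duration and growth rates.

    The shedding day of the old P9 is when the fitted curve crosses
    ``shed_length_mm`` (1 mm by convention); flight is regained when the curve
    reaches ``flight_threshold`` of final length.  The delta growth rate is
    the average rate between fractions ``lo`` and ``hi`` of final length,
    computed from the fitted-curve crossing times.
    """
    if not (0.0 < lo < hi < 1.0):
        raise ParameterError(f"need 0 < lo < hi < 1, got lo={lo}, hi={hi}")
    if not shed_length_mm < fit.A:
        raise ParameterError(
            f"shed length {shed_length_mm} mm must be below the asymptote {fit.A} mm"
        )
    shed = time_at_fraction(fit, shed_length_mm / fit.A)
    flight = time_at_fraction(fit, flight_threshold)
    t_lo = time_at_fraction(fit, lo)
    t_hi = time_at_fraction(fit, hi)
    delta = (hi - lo) * fit.A / (t_hi - t_lo)
    return MoultTiming(
        shed_day=shed,
        flight_day=flight,
        flightless_days=flight - shed,
        delta_rate=delta,
        max_rate=fit.mu,
        delta_rate_pct=rate_percent(delta, fit.A),
        max_rate_pct=rate_percent(fit.mu, fit.A),
        flight_threshold=flight_threshold,
    )


def rate_percent(rate: float, final_length: float) -> float:
    """Growth rate as daily percent change of final feather length."""
    return 100.0 * rate / final_length


def delta_rate_observed(series: BirdSeries, A: float,
                        lo: float = 0.05, hi: float = 0.90) -> float:
    """Delta growth rate from the raw observations rather than the fit.

    Linearly interpolates the observed series to the days it crosses lo*A and
    hi*A.  Requires observations bracketing both crossings.
    """
    if not (0.0 < lo < hi < 1.0):
        raise ParameterError(f"need 0 < lo < hi < 1, got lo={lo}, hi={hi}")
    t, y = series.p9_observations()
    y_lo, y_hi = lo * A, hi * A
    if y.min() > y_lo or y.max() < y_hi:
        raise DataError(
            f"bird {series.bird_id}: observations do not bracket "
            f"{100 * lo:g}%-{100 * hi:g}% of final length"
        )
    t_lo = float(np.interp(y_lo, y, t))
    t_hi = float(np.interp(y_hi, y, t))
    if t_hi <= t_lo:
        raise DataError(f"bird {series.bird_id}: non-increasing crossing times")
    return (y_hi - y_lo) / (t_hi - t_lo)


def initial_mass(series: BirdSeries, shed_day: float) -> float:
    """Initial (pre-shed) body mass: the last mass measured before shedding.

    Returns NaN when the bird has no mass observation before ``shed_day``.
    """
    d, m = series.mass_observations()
    pre = d < shed_day
    if not pre.any():
        return math.nan
    return float(m[pre][-1])


def summarize_cohorts(records) -> pd.DataFrame:
    """Cohort (species x sex) summary of timing and growth-rate quantities.

    ``records`` is an iterable of (BirdSeries, GrowthFit, MoultTiming)
    triples.  Returns one row per cohort with n and mean +/- SD of shedding
    day, initial body mass, final P9 length (A-hat), delta and maximal growth
    rates (absolute and as daily percent change) and flightless duration.
    SD is reported as 0 for single-bird cohorts.  Empty cohorts are omitted.
    """
    rows = []
    for series, fit, timing in records:
        if not fit.converged:
            warnings.warn(f"bird {series.bird_id}: unconverged fit excluded "
                          "from cohort summary")
            continue
        rows.append({
            "species": series.species,
            "sex": series.sex,
            "bird_id": series.bird_id,
            "shed_day": timing.shed_day,
            "initial_mass_g": initial_mass(series, timing.shed_day),
            "p9_final_mm": fit.A,
            "delta_rate": timing.delta_rate,
            "max_rate": timing.max_rate,
            "delta_rate_pct": timing.delta_rate_pct,
            "max_rate_pct": timing.max_rate_pct,
            "flightless_days": timing.flightless_days,
        })
    if not rows:
        raise DataError("no convergent fits to summarize")
    return summarize_bird_table(pd.DataFrame(rows))


def summarize_bird_table(df: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a per-bird quantity table into the cohort summary layout.

    Expects one row per bird with columns species, sex, bird_id, shed_day,
    initial_mass_g, p9_final_mm, delta_rate, max_rate, delta_rate_pct,
    max_rate_pct, flightless_days.
    """
    agg = df.groupby(["species", "sex"], sort=True).agg(
        n=("bird_id", "size"),
        **{
            f"{c}_{s}": (c, s)
            for c in ["shed_day", "initial_mass_g", "p9_final_mm", "delta_rate",
                      "max_rate", "delta_rate_pct", "max_rate_pct",
                      "flightless_days"]
            for s in ("mean", "std")
        },
    ).reset_index()
    sd_cols = [c for c in agg.columns if c.endswith("_std")]
    agg[sd_cols] = agg[sd_cols].fillna(0.0)  # n = 1 cohorts: SD reported as 0
    return agg
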