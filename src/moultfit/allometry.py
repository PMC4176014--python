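"""Allometric scaling of feather growth against body mass.

Traits Y (delta growth rate of the 9th primary, mm/day, or its final length,
mm) are related to initial body mass M (g) through the allometric power law
Y = a * M**b, fitted as a straight line on natural-log axes.  Because both
axes carry sampling error, the ordinary least-squares (OLS) slope is
complemented by the two standard model-II estimators: reduced major axis
(RMA, slope = sign(r) * sd(ln y)/sd(ln x)) and major axis (MA, principal
eigenvector of the 2x2 covariance matrix).  Slope confidence intervals use
the parametric formula for OLS and Jolicoeur's method for MA/RMA, with a
seeded bootstrap fallback when the analytic MA interval is undefined.

A genus-level analysis of covariance (type III sums of squares, sum-to-zero
factor coding) screens for slope heterogeneity before pooling species into a
single inter-specific slope, and per-species Pearson correlations probe the
intra-specific level.  The combined moult-duration exponent is the exponent
of length/rate: b_length - b_rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, ParameterError

_METHODS = ("OLS", "MA", "RMA")


@dataclass
class AllometryResult:
    """One log-log allometric fit: ln y = ln a + b * ln M."""

    response: str
    method: str
    slope_b: float
    intercept_ln_a: float
    r: float
    n: int
    df: int
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class AncovaResult:
    """Genus ANCOVA on log-transformed values (type III tests)."""

    factor: str
    interaction_F: float
    interaction_p: float
    main_F: float
    main_p: float
    common_slope: float


def _validated_logs(x_mass, y):
    x = np.asarray(x_mass, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DataError("x and y must have equal length")
    if x.size < 3:
        raise DataError(f"need n >= 3 points, got {x.size}")
    if np.any(x <= 0) or np.any(y <= 0):
        raise DataError("all values must be positive (log-log fit)")
    return np.log(x), np.log(y)


def ma_slope(lx: np.ndarray, ly: np.ndarray) -> float:
    """Major-axis slope: principal eigenvector of cov([ln x, ln y])."""
    cov = np.cov(lx, ly)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, int(np.argmax(evals))]
    if v[0] == 0:
        raise DataError("major axis is vertical; slope undefined")
    return float(v[1] / v[0])


def loglog_fit(x_mass, y, method: str = "OLS", response: str = "",
               alpha: float = 0.05, n_boot: int = 2000,
               seed: int = 0) -> AllometryResult:
    """Fit the allometric power law on log-log axes by OLS, MA or RMA."""
    if method not in _METHODS:
        raise ParameterError(f"method must be one of {_METHODS}, got {method!r}")
    lx, ly = _validated_logs(x_mass, y)
    n = int(lx.size)
    df = n - 2
    r, p_r = sps.pearsonr(lx, ly)
    r = float(r)
    mx, my = float(np.mean(lx)), float(np.mean(ly))
    sx = float(np.std(lx, ddof=1))
    sy = float(np.std(ly, ddof=1))
    if sx == 0:
        raise DataError("zero variance in ln(mass)")
    f_crit = float(sps.f.ppf(1.0 - alpha, 1, df))

    if method == "OLS":
        res = sps.linregress(lx, ly)
        b = float(res.slope)
        t_crit = float(sps.t.ppf(1.0 - alpha / 2.0, df))
        lo = b - t_crit * res.stderr
        hi = b + t_crit * res.stderr
        intercept = float(res.intercept)
        p = float(res.pvalue)
    elif method == "RMA":
        if sy == 0:
            raise DataError("zero variance in ln(y)")
        b = math.copysign(sy / sx, r if r != 0 else 1.0)
        intercept = my - b * mx
        # Jolicoeur-style interval: B = F (1 - r^2) / (n - 2)
        B = f_crit * (1.0 - r * r) / df
        lo = b * (math.sqrt(B + 1.0) - math.sqrt(B))
        hi = b * (math.sqrt(B + 1.0) + math.sqrt(B))
        p = float(p_r)
    else:  # MA
        b = ma_slope(lx, ly)
        intercept = my - b * mx
        cov = np.cov(lx, ly)
        lam = np.linalg.eigvalsh(cov)
        l2, l1 = float(lam[0]), float(lam[1])
        lo = hi = math.nan
        if l2 > 0 and l1 > l2:
            H = f_crit / ((l1 / l2 + l2 / l1 - 2.0) * df / 4.0)
            if H < 1.0:
                t_d = math.sqrt(H / (1.0 - H))  # tan of the angle half-width
                lo = (b - t_d) / (1.0 + b * t_d)
                hi = (b + t_d) / (1.0 - b * t_d)
        if not (math.isfinite(lo) and math.isfinite(hi) and lo <= b <= hi):
            lo, hi = _bootstrap_slope_ci(lx, ly, ma_slope, alpha, n_boot, seed)
        p = float(p_r)
    if lo > hi:
        lo, hi = hi, lo
    return AllometryResult(response, method, float(b), float(intercept), r,
                           n, df, float(lo), float(hi), p)


def _bootstrap_slope_ci(lx, ly, slope_fn, alpha, n_boot, seed):
    """Percentile bootstrap CI for a slope estimator (case resampling)."""
    rng = np.random.default_rng(seed)
    n = lx.size
    slopes = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            slopes[i] = slope_fn(lx[idx], ly[idx])
        except DataError:
            slopes[i] = np.nan
    slopes = slopes[np.isfinite(slopes)]
    lo, hi = np.quantile(slopes, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def genus_ancova(table: pd.DataFrame) -> AncovaResult:
    """ANCOVA of ln y on ln mass with genus as a factor (type III SS).

    ``table`` needs columns ``ln_mass``, ``ln_y`` and ``genus``.  Tests the
    genus x covariate interaction (slope heterogeneity) and the genus main
    effect with sum-to-zero factor coding; the common slope comes from the
    no-interaction model.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for col in ("ln_mass", "ln_y", "genus"):
        if col not in table.columns:
            raise DataError(f"missing column {col!r}")
    counts = table.groupby("genus").size()
    if len(counts) < 2:
        raise DataError("need >= 2 genera")
    if (counts < 3).any():
        small = counts[counts < 3].index.tolist()
        raise DataError(f"need >= 3 points per genus; too few for {small}")
    full = smf.ols("ln_y ~ C(genus, Sum) * ln_mass", data=table).fit()
    if np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        raise DataError("singular ANCOVA design matrix (rank deficient)")
    a3 = sm.stats.anova_lm(full, typ=3)
    inter = a3.loc["C(genus, Sum):ln_mass"]
    main = a3.loc["C(genus, Sum)"]
    additive = smf.ols("ln_y ~ C(genus, Sum) + ln_mass", data=table).fit()
    return AncovaResult(
        factor="genus",
        interaction_F=float(inter["F"]), interaction_p=float(inter["PR(>F)"]),
        main_F=float(main["F"]), main_p=float(main["PR(>F)"]),
        common_slope=float(additive.params["ln_mass"]),
    )


def duration_exponent(b_length: float, b_rate: float) -> float:
    """Exponent of moult duration vs body mass: length/rate scales as
    M**(b_length - b_rate)."""
    return b_length - b_rate


def mass_doubling_pct(b: float) -> float:
    """Percent increase of an allometric trait when body mass doubles."""
    return 100.0 * (2.0 ** b - 1.0)


def intraspecific_correlations(per_species: dict) -> dict:
    """Per-species Pearson correlation of ln(delta rate) on ln(mass).

    ``per_species`` maps species code -> (masses, rates).  Returns species
    code -> (r, two-sided p).
    """
    out = {}
    for species, (mass, rate) in per_species.items():
        lx, ly = _validated_logs(mass, rate)
        if np.ptp(np.asarray(mass, float)) == 0 or np.ptp(np.asarray(rate, float)) == 0:
            raise DataError(f"{species}: zero variance, correlation undefined")
        r, p = sps.pearsonr(lx, ly)
        out[species] = (float(r), float(p))
    return out
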