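"""Body-mass trajectories across moult phases and flight-regain inference.

Moult progress is binned into phases on fractional P9 regrowth: phase 0 is
the pre-shed initial state, phase I feather emergence, phase II the period of
fastest growth (containing the Gompertz inflection at A/e ~ 0.37), phase III
the first slowing of growth, phase IV the second slowing — the window in
which flight ability is regained — and phase V completion.  Mass
observations are mapped to phases through the bird's fitted growth curve and
expressed as percent of initial (last pre-shed) mass.

Whether birds are lighter at flight regain than at moult onset is tested on
the per-bird paired difference (phase-IV mass minus initial mass) with a
studentized bootstrap confidence interval, and each phase is compared
against the initial mass with a many-to-one (Dunnett-style) procedure whose
family-wise adjustment is estimated by Monte Carlo from the max-|t| null
distribution under the estimated correlation of the contrasts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import BirdSeries
from .errors import DataError, ParameterError
from .growth import GrowthFit, MoultTiming, gompertz_value, initial_mass

PHASE_LABELS = ("0", "I", "II", "III", "IV", "V")


@dataclass(frozen=True)
class PhaseDefinition:
    """Moult phases as upper boundaries on fractional P9 growth.

    Defaults: I (0, 0.25], II (0.25, 0.60], III (0.60, 0.80],
    IV (0.80, 0.95], V (0.95, 1].  Phase 0 is reserved for pre-shed.
    """

    boundaries: tuple = (0.25, 0.60, 0.80, 0.95, 1.0)

    def __post_init__(self):
        b = self.boundaries
        if len(b) != 5 or not all(x < y for x, y in zip(b, b[1:])):
            raise ParameterError("boundaries must be 5 strictly increasing values")
        if not (0.0 < b[0] and b[-1] == 1.0):
            raise ParameterError("boundaries must lie in (0, 1] and end at 1")


def assign_phase(p9_fraction: float,
                 defs: PhaseDefinition = PhaseDefinition()) -> str:
    """Phase label for a fractional P9 growth value (NaN / pre-shed -> '0')."""
    if p9_fraction is None or (isinstance(p9_fraction, float) and math.isnan(p9_fraction)):
        return "0"
    if not 0.0 <= p9_fraction <= 1.0:
        raise DataError(f"P9 fraction {p9_fraction} outside [0, 1]")
    if p9_fraction == 0.0:
        return "0"
    for label, upper in zip(PHASE_LABELS[1:], defs.boundaries):
        if p9_fraction <= upper:
            return label
    return "V"


def pct_initial_mass(series: BirdSeries, fit: GrowthFit, timing: MoultTiming,
                     defs: PhaseDefinition = PhaseDefinition()) -> pd.DataFrame:
    """Per-phase body mass as percent of the bird's initial mass.

    Each mass observation is assigned a phase through the fitted curve's
    fraction at the observation day (phase 0 before the shedding day) and
    expressed as 100 * mass / initial mass; multiple observations within a
    phase are averaged.  Raises DataError when no pre-shed (phase 0) mass
    exists.
    """
    m0 = initial_mass(series, timing.shed_day)
    if not math.isfinite(m0):
        raise DataError(f"bird {series.bird_id}: no pre-shed (phase 0) mass")
    days, masses = series.mass_observations()
    rows = []
    for day, mass in zip(days, masses):
        if day < timing.shed_day:
            phase = "0"
        else:
            frac = min(gompertz_value(day, fit.A, fit.mu, fit.lambda_) / fit.A, 1.0)
            phase = assign_phase(frac, defs)
        rows.append({"phase": phase, "pct_initial": 100.0 * mass / m0,
                     "mass_g": mass})
    df = pd.DataFrame(rows)
    out = df.groupby("phase", sort=False).agg(
        pct_initial=("pct_initial", "mean"), mass_g=("mass_g", "mean"),
        n_obs=("phase", "size")).reset_index()
    order = {p: i for i, p in enumerate(PHASE_LABELS)}
    return out.sort_values("phase", key=lambda s: s.map(order)).reset_index(drop=True)


def skewness(values) -> float:
    """Sample skewness g1 = m3 / m2**1.5 (moment definition)."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise DataError(f"need n >= 3 for skewness, got {v.size}")
    if np.ptp(v) == 0:
        raise DataError("zero variance: skewness undefined")
    return float(sps.skew(v, bias=True))


@dataclass
class MassDelta:
    """Studentized-bootstrap inference on the phase-IV minus initial mass."""

    species: str
    sex: str
    n: int
    delta_mean: float
    ci_low: float
    ci_high: float
    B: int
    skewness: float
    significant: bool
    seed: int = None


def studentized_bootstrap_delta(initial, phase4, B: int = 10000,
                                seed: int = None, alpha: float = 0.05,
                                species: str = "", sex: str = "") -> MassDelta:
    """Studentized (bootstrap-t) CI for the mean paired mass difference.

    Per-bird deltas d_i = phase4_i - initial_i; B resamples of the birds with
    replacement; each resample's pivot t* = (mean* - mean) / (sd*/sqrt(n));
    the interval is [mean - t*_(1-a/2) se, mean - t*_(a/2) se].  The inner
    standard error is analytic (sd*/sqrt(n)), the standard choice at these
    sample sizes.
    """
    x0 = np.asarray(initial, dtype=float)
    x4 = np.asarray(phase4, dtype=float)
    if x0.size != x4.size:
        raise DataError("initial and phase-IV vectors must be paired")
    n = int(x0.size)
    if n < 3:
        raise DataError(f"need n >= 3 paired birds, got {n}")
    if B < 1000:
        raise ParameterError(f"B must be >= 1000, got {B}")
    d = x4 - x0
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        warnings.warn("zero variance in deltas: degenerate CI")
        return MassDelta(species, sex, n, mean, mean, mean, B, math.nan,
                         significant=not (mean == 0.0), seed=seed)
    se = sd / math.sqrt(n)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    res = d[idx]
    means = res.mean(axis=1)
    sds = res.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstar = (means - mean) / (sds / math.sqrt(n))
    tstar = tstar[np.isfinite(tstar)]
    q_lo, q_hi = np.quantile(tstar, [alpha / 2.0, 1.0 - alpha / 2.0])
    ci_low = mean - q_hi * se
    ci_high = mean - q_lo * se
    significant = bool(ci_low > 0.0 or ci_high < 0.0)
    return MassDelta(species, sex, n, mean, float(ci_low), float(ci_high),
                     B, skewness(d), significant, seed=seed)


def _nearest_correlation(R: np.ndarray) -> np.ndarray:
    """Clip eigenvalues to keep the estimated contrast correlation PSD."""
    evals, evecs = np.linalg.eigh(R)
    evals = np.clip(evals, 1e-10, None)
    R = evecs @ np.diag(evals) @ evecs.T
    d = np.sqrt(np.diag(R))
    return R / np.outer(d, d)


def max_t_adjust(t_obs, corr, dfs, n_draws: int = 100_000,
                 seed: int = None) -> np.ndarray:
    """Family-wise adjusted p-values from the Monte-Carlo max-|t| null.

    Null draws have numerators jointly normal with correlation ``corr`` and
    per-contrast independent chi-square denominators with ``dfs`` degrees of
    freedom (matching per-contrast variance estimates of paired differences).
    Each adjusted p is P(max_i |T_i| >= |t_j|), floored at the raw
    per-contrast p so that adjusted >= raw holds under MC noise.
    """
    t_obs = np.atleast_1d(np.asarray(t_obs, dtype=float))
    dfs = np.atleast_1d(np.asarray(dfs, dtype=float))
    k = t_obs.size
    corr = _nearest_correlation(np.atleast_2d(np.asarray(corr, dtype=float)))
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(corr)
    Z = rng.standard_normal((n_draws, k)) @ L.T
    chi = rng.chisquare(dfs, size=(n_draws, k))
    T = Z / np.sqrt(chi / dfs)
    max_abs = np.abs(T).max(axis=1)
    p_adj = np.array([(max_abs >= abs(t)).mean() for t in t_obs])
    p_raw = 2.0 * sps.t.sf(np.abs(t_obs), dfs)
    return np.maximum(p_adj, p_raw)


def dunnett_vs_initial(phase_masses: pd.DataFrame, n_draws: int = 100_000,
                       seed: int = None) -> pd.DataFrame:
    """Many-to-one comparison of each moult phase against the initial mass.

    ``phase_masses`` is a wide per-bird table (rows = birds, columns = phase
    labels including '0'); contrasts are per-bird paired differences
    phase_j - phase_0, tested with paired t statistics and adjusted
    family-wise by the Monte-Carlo max-|t| procedure under the estimated
    contrast correlation.  Contrasts with fewer than 3 complete pairs are
    dropped with a warning.
    """
    if "0" not in phase_masses.columns:
        raise DataError("phase_masses must contain the initial phase column '0'")
    if phase_masses["0"].notna().sum() < 3:
        raise DataError("need >= 3 birds with an initial (phase 0) mass")
    diffs = {}
    for phase in [c for c in phase_masses.columns if c != "0"]:
        d = (phase_masses[phase] - phase_masses["0"]).dropna()
        if d.size < 3 or d.std(ddof=1) == 0:
            warnings.warn(f"phase {phase}: contrast dropped "
                          "(too few pairs or zero variance)")
            continue
        diffs[phase] = d
    if not diffs:
        raise DataError("no testable phase contrasts")
    phases = list(diffs)
    t_obs, dfs, means = [], [], []
    for p in phases:
        d = diffs[p]
        t_obs.append(d.mean() / (d.std(ddof=1) / math.sqrt(d.size)))
        dfs.append(d.size - 1)
        means.append(d.mean())
    diff_frame = pd.DataFrame({p: diffs[p] for p in phases})
    if len(phases) > 1:
        R = diff_frame.corr(min_periods=2).to_numpy()
        R[~np.isfinite(R)] = 0.0
        np.fill_diagonal(R, 1.0)
    else:
        R = np.eye(1)
    p_adj = max_t_adjust(t_obs, R, dfs, n_draws=n_draws, seed=seed)
    p_raw = 2.0 * sps.t.sf(np.abs(t_obs), dfs)
    return pd.DataFrame({
        "phase": phases,
        "n": [diffs[p].size for p in phases],
        "mean_diff_g": means,
        "t": t_obs,
        "df": dfs,
        "p_raw": p_raw,
        "p_adjusted": p_adj,
    })
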