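# Methods

## Growth model and derived timing

Each bird's P9 regrowth is modelled with the Zwietering parameterization of
the Gompertz function, `y(t) = A·exp(−exp((μe/A)(λ−t)+1))`, chosen because
its three parameters are directly interpretable: `A` is the asymptotic
feather length (mm), `μ` the maximal growth rate (mm/day, attained at the
inflection `y = A/e`), and `λ` the lag phase (day). The logistic
alternative `A/(1+exp((4μ/A)(λ−t)+2))` uses the matching convention (maximal
slope `μ` at `A/2`). These are the parameterizations popularized by
microbial-growth curve software, and they make every downstream quantity
closed-form:

- time at fraction `f` of final length: `t(f) = λ + (A/(μe))(1 − ln(−ln f))`,
  the exact inverse of the curve (verified to 1e-9·A);
- shedding day of the old feather: `t(1 mm / A)`. The 1 mm convention
  operationalizes "the old feather has dropped and the new one is just
  emerging";
- flight-regain day: `t(0.90)` by default. The 90% threshold is the standard
  field estimate for seaducks; it is configurable (`flight_threshold`)
  because the true threshold is species-dependent (likely lower for eiders);
- flightless duration: `t(0.90) − t(1mm/A)`, which is independent of `λ`
  (pure time translation) — an invariant the tests assert;
- delta growth rate: `0.85·A / (t(0.90) − t(0.05))`, the mean rate over the
  5–90% window. With this fitted-curve definition the ratio delta/μ is the
  universal constant `0.85e/(ln(−ln 0.05) − ln(−ln 0.90)) ≈ 0.690` for any
  parameters. An alternative (`delta_from_observations` /
  `--delta-from-observations`) interpolates the raw measurements to the
  5% and 90% crossings instead; observed ratios in real data tend to run
  slightly higher (~0.71–0.74) because measurement noise and finite sampling
  bias the crossing times, so both definitions are provided.

Fitting is plain nonlinear least squares (`scipy.optimize.least_squares`,
TRF with positivity bounds on `A` and `μ`). Starting values are data-driven
(`A₀` = max observed length, `μ₀` = steepest successive-difference slope,
`λ₀` back-projected from the steepest segment) with up to 10 log-normally
jittered restarts; the first start almost always converges and an early exit
avoids redundant restarts. Convergence tolerance is 1e-8 on relative RSS.
Pre-shed occasions (old feather still in place) are missing values and are
excluded from the fit, never imputed as zero. A series needs at least 4
non-missing points; constant or non-increasing series return
`converged=False` with a diagnostic message rather than raising.

Model comparison uses the least-squares AICc, `n·ln(RSS/n) + 2k +
2k(k+1)/(n−k−1)` with `k = 4` (three curve parameters plus the residual
variance); it is `+inf` for `n ≤ 5`, where the correction is undefined.
Evidence ratios are `exp(ΔAICc/2)`.

## Allometry

Traits (delta rate, P9 final length) are regressed on initial body mass on
natural-log axes, per bird rather than on species means — the study design
this emulates has ~61 birds and reports df = 59 — with a species-means
option implicit in summarising first. Because mass and rate both carry
error, OLS is complemented by reduced major axis (slope =
sign(r)·sd(ln y)/sd(ln x)) and major axis (principal eigenvector of the 2×2
covariance). Confidence intervals: parametric t-interval for OLS;
Jolicoeur-style intervals for RMA (`b·(√(B+1) ± √B)`, `B = F(1−r²)/(n−2)`)
and MA (rotation-angle interval via `H = F/((λ₁/λ₂+λ₂/λ₁−2)(n−2)/4)`), with
a seeded 2000-resample percentile bootstrap as fallback when the analytic MA
interval is undefined (H ≥ 1). Note the MA slope is not scale-invariant, so
the familiar |OLS| ≤ |MA| ≤ |RMA| ordering only holds when
sd(ln y) ≤ sd(ln x); |OLS| ≤ |RMA| is unconditional.

The genus ANCOVA (slope-heterogeneity screen before pooling) is an OLS with
sum-to-zero factor coding and type III F-tests via statsmodels; the common
slope comes from the no-interaction model. The moult-duration exponent is
`b_length − b_rate` (duration = length/rate), with a CI from the
quadrature-combined OLS slope half-widths. `mass_doubling_pct(b) =
100·(2^b − 1)` converts an exponent to the percent trait increase per mass
doubling; for b = 0.059 this is 4.2% (the arithmetic follows the formula,
whatever rounding appears elsewhere).

## Body-mass phases and inference

Moult progress is binned on fractional P9 growth: 0 pre-shed, I (0, 0.25],
II (0.25, 0.60], III (0.60, 0.80], IV (0.80, 0.95], V (0.95, 1]. The
boundaries are configurable; the defaults put the Gompertz inflection
(A/e ≈ 0.37) inside phase II (fastest growth) and make phase IV the
flight-regain window (80–95%). Initial mass is the last measurement before
the shedding day; birds without one are excluded with a warning.

The flight-regain test subtracts initial mass from phase-IV mass per bird
and builds a studentized (bootstrap-t) 95% CI from B = 10,000 resamples of
the birds: pivot `t* = (mean* − mean)/(sd*/√n)` with the analytic inner
standard error (a nested bootstrap would cost B² for no benefit at n = 3–13).
Symmetry of the deltas is screened with the moment skewness g₁ = m₃/m₂^1.5.
Zero-variance deltas yield a degenerate [mean, mean] interval with a warning.

Each phase is also compared against initial mass, many-to-one. The
repeated-measures structure is honoured by differencing within bird; each
contrast gets a paired t statistic with its own df, and the family-wise
adjustment is Monte-Carlo: ≥10⁵ draws of jointly normal numerators under the
estimated contrast correlation with per-contrast independent chi-square
denominators, adjusted p = P(max|T| ≥ |t_j|). Per-contrast denominators
(rather than a shared pooled variance) match the paired-difference variance
estimates and make the zero-correlation two-contrast case reduce exactly to
Šidák, `1 − (1−p)²`, which the tests verify. Adjusted p is floored at the
raw p so monotonicity survives Monte-Carlo noise. A delegated random-
intercept mixed-model route is deliberately out of scope; the within-bird
differencing is the contract honoured here.

## Auxiliary tests

Mann-Whitney U (sex comparisons; exact enumeration when n₁n₂ ≤ 400 and the
pooled sample is tie-free, otherwise the tie-corrected normal approximation;
U is reported as min(U₁, U₂) and the convention labelled, since the raw
statistic is convention-dependent), one-way ANOVA with Tukey HSD
(Tukey-Kramer for unbalanced groups), Bartlett, and Shapiro-Wilk are
delegated to scipy.stats behind this package's result types; the test suite
validates them against brute-force oracles (exhaustive U enumeration,
two-group Tukey = t-test, null-uniformity of p).

## Synthetic cohorts

The generator emulates the captive-seaduck study conditions: 10 species-sex
cohorts whose sample sizes, shedding dates, body masses, final P9 lengths
and maximal growth rates are the published cohort statistics
(`reference_cohorts()`); weekly P9 occasions from 8 July to 8 October (14
occasions, day-of-year of a leap study year) and fortnightly mass occasions
(7). Truths are truncated-normal draws (rejection sampling, 1000-retry cap,
positivity for A, μ, mass); A and μ are drawn independently within cohorts
(the within-cohort correlation is not known; a correlation knob would be the
natural extension). λ is set so each bird's curve crosses 1 mm exactly on
its drawn shedding day, so the simulated truth lives in the fitted family
and recovery is a meaningful test. P9 noise is Gaussian (default 2 mm,
clipped at 0); occasions before shedding are recorded as missing, which
forces the fitter to handle left-censored starts.

Body mass follows a piecewise-linear function of fractional feather growth
through nodes (0, 0.25, 0.55, 1.0) at multipliers (1, rise, dip, 1) of
initial mass — mass peaks during feather emergence (default rise 1.05),
dips during fastest growth (default dip 0.97, chosen as a realistic few-
percent swing consistent with the qualitative published pattern) and returns
to initial at completion — plus Gaussian noise (default 10 g).

What the generator does **not** emulate: within-cohort mass-rate
correlation, sex- or species-specific mass-pattern shapes, measurement
rounding to 1 mm, multi-year cycles, or any ecological process (predation,
food limitation). Passing recovery tests therefore demonstrates the
estimators are correct under the assumed data-generating model, not that
the model is right for any particular wild population.

## Problem sizes and numerical choices

The default pipeline runs the 61-bird published design. Validation sims use
200 birds for parameter-recovery distributions, 300 birds (10 cohorts
spanning 500–2000 g with built-in exponents 0.285/0.059) for
duration-exponent recovery, 1000 seeds × B = 1000 for bootstrap coverage,
and 2×10⁴–4×10⁵ Monte-Carlo draws for the max-|t| checks — sizes chosen so
Monte-Carlo error is well below the tolerances being asserted. All
randomness flows from explicit seeds (`numpy.random.default_rng` /
`SeedSequence` child streams); fitting restarts use a fixed internal seed so
fits are pure functions of the data. Report files are written with fixed
float formatting, making bundles byte-identical for identical config + seed
(the manifest necessarily embeds the output path).

## Known limitations

- The flightless duration inherits the 90% threshold's species bias; the
  per-species thresholds are unknown and left to the user.
- The fitted-curve delta rate is deterministically 0.690·μ, so its allometric
  exponent equals that of μ; the observation-interpolated variant breaks this
  tie but is noisier.
- The Dunnett-style adjustment estimates the contrast correlation from
  complete pairs; with heavy missingness the estimate is rough (eigenvalue
  clipping keeps it positive semidefinite).
- ANCOVA requires ≥ 2 genera with ≥ 3 points each and a non-singular design;
  degenerate (e.g. noise-free) cohorts skip it with a warning.
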