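"""Auxiliary hypothesis tests used across the moult analysis.

Thin, contract-checked wrappers over the standard routines: Mann-Whitney U
for sex comparisons (exact null distribution when n1*n2 <= 400 and the
pooled sample is tie-free, tie-corrected normal approximation otherwise),
one-way ANOVA with Tukey HSD for between-species comparisons, Bartlett's
test for homogeneity of variance, and Shapiro-Wilk normality screening.
The U statistic is reported under the min(U1, U2) convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError

#: Largest n1*n2 for which the exact U null distribution is enumerated.
EXACT_U_LIMIT = 400


@dataclass
class TestResult:
    """A named test statistic with its p-value and sample sizes."""

    method: str
    statistic: float
    p_value: float
    n: tuple = ()
    detail: dict = field(default_factory=dict)


def mann_whitney_u(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test; U reported as min(U1, U2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    exact = (a.size * b.size <= EXACT_U_LIMIT) and not ties
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    u1 = float(res.statistic)
    u_min = min(u1, a.size * b.size - u1)
    return TestResult(
        method="mann-whitney-u (min-U convention, "
               + ("exact)" if exact else "tie-corrected normal)"),
        statistic=u_min, p_value=float(res.pvalue), n=(int(a.size), int(b.size)),
    )


def anova_tukey(groups: dict) -> tuple[TestResult, pd.DataFrame]:
    """One-way ANOVA across named groups plus Tukey HSD pairwise p-values.

    Returns the ANOVA TestResult (F, p, df) and a DataFrame with one row per
    group pair (adjusted p from the studentized-range distribution,
    Tukey-Kramer for unbalanced groups).  All-identical data yield F = 0 and
    all adjusted p = 1.
    """
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if len(arrays) < 2:
        raise DataError("need >= 2 groups")
    if any(a.size < 2 for a in arrays):
        raise DataError("each group needs n >= 2")
    k = len(arrays)
    n_tot = sum(a.size for a in arrays)
    df1, df2 = k - 1, n_tot - k
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        pairs = pd.DataFrame([
            {"group1": names[i], "group2": names[j], "mean_diff": 0.0,
             "p_adjusted": 1.0}
            for i in range(k) for j in range(i + 1, k)])
        return (TestResult("one-way anova", 0.0, 1.0, (df1, df2)), pairs)
    F, p = sps.f_oneway(*arrays)
    tuk = sps.tukey_hsd(*arrays)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            rows.append({
                "group1": names[i], "group2": names[j],
                "mean_diff": float(np.mean(arrays[i]) - np.mean(arrays[j])),
                "p_adjusted": float(tuk.pvalue[i, j]),
            })
    return (TestResult("one-way anova", float(F), float(p), (df1, df2)),
            pd.DataFrame(rows))


def bartlett(groups: dict) -> TestResult:
    """Bartlett's test of variance homogeneity across named groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups.values()]
    if len(arrays) < 2:
        raise DataError("need >= 2 groups")
    if any(a.size < 2 for a in arrays):
        raise DataError("each group needs n >= 2")
    stat, p = sps.bartlett(*arrays)
    return TestResult("bartlett", float(stat), float(p),
                      tuple(int(a.size) for a in arrays))


def shapiro(values) -> TestResult:
    """Shapiro-Wilk normality test (delegated to the established routine)."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise DataError(f"need n >= 3, got {v.size}")
    stat, p = sps.shapiro(v)
    return TestResult("shapiro-wilk", float(stat), float(p), (int(v.size),))
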