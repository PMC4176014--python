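"""Seeded synthetic moult cohorts emulating the captive-seaduck study design.

Ten species-sex cohorts (5 seaduck species x 2 sexes) are parameterized from
the study's published cohort statistics: mean +/- SD of shedding date of the
old 9th primary, early-moult body mass, final P9 length and maximal P9 growth
rate.  Each simulated bird draws its true asymptote A, maximal rate mu,
shedding day and initial mass from the cohort distributions; the lag phase
lambda is set so the Gompertz curve crosses 1 mm exactly on the drawn
shedding day.  Birds are then "measured" on the study's occasion grid —
weekly P9 from 8 July to 8 October, body mass every fortnight — with
Gaussian measurement noise.  Body mass follows a rise-then-fall-then-recover
pattern expressed as a piecewise-linear function of fractional feather
growth, peaking during feather emergence and dipping during the period of
fastest growth.

P9 is recorded as missing (old feather still in place) on occasions before
the bird's shedding day, so downstream fitting must handle left-censored
starts.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import BirdSeries
from .errors import DataError, ParameterError
from .growth import gompertz_value

_E = math.e

#: Weekly P9 measurement days (day-of-year, 8 July - 8 October, leap year).
STUDY_START = _dt.date(2008, 7, 8).timetuple().tm_yday  # 190
STUDY_END = _dt.date(2008, 10, 8).timetuple().tm_yday  # 282
P9_DAYS = tuple(range(STUDY_START, STUDY_END + 1, 7))  # 14 occasions
MASS_DAYS = tuple(range(STUDY_START, STUDY_END + 1, 14))  # 7 occasions

#: Fractional-growth nodes of the piecewise-linear body-mass pattern:
#: initial -> peak during feather emergence -> trough during fastest growth
#: -> back to initial at curve completion.
MASS_PATTERN_NODES = (0.0, 0.25, 0.55, 1.0)


@dataclass(frozen=True)
class CohortTemplate:
    """Distributional description of one species-sex cohort.

    Mass fractions are relative to initial body mass: ``mass_rise_frac`` is
    the peak (>= 1) and ``mass_dip_frac`` the trough (<= 1) of the noise-free
    trajectory.
    """

    species: str
    sex: str
    n_birds: int
    mean_shed_day: float
    sd_shed_day: float
    mean_A: float
    sd_A: float
    mean_mu: float
    sd_mu: float
    mean_mass0: float
    sd_mass0: float
    mass_rise_frac: float = 1.05
    mass_dip_frac: float = 0.97
    noise_sd_p9: float = 2.0
    noise_sd_mass: float = 10.0
    pattern_nodes: tuple = MASS_PATTERN_NODES

    def __post_init__(self):
        if self.n_birds < 1:
            raise ParameterError("n_birds must be >= 1")
        if not (self.mean_A > 0 and self.mean_mu > 0 and self.mean_mass0 > 0):
            raise ParameterError("mean_A, mean_mu, mean_mass0 must be positive")
        for name in ("sd_shed_day", "sd_A", "sd_mu", "sd_mass0",
                     "noise_sd_p9", "noise_sd_mass"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not (0.0 < self.mass_dip_frac <= 1.0 <= self.mass_rise_frac):
            raise ParameterError("need 0 < mass_dip_frac <= 1 <= mass_rise_frac")


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth generating parameters for one simulated bird."""

    bird_id: str
    true_A: float
    true_mu: float
    true_lambda: float
    true_shed_day: float
    true_mass0: float


def _doy(month: int, day: int, year: int = 2008) -> int:
    return _dt.date(year, month, day).timetuple().tm_yday


def reference_cohorts() -> pd.DataFrame:
    """Published cohort statistics for the 5 captive seaduck species.

    One row per species-sex cohort: sample size, mean +/- SD shedding date of
    the old P9 (day-of-year), early-moult body mass (g), final P9 length
    (mm), delta P9 growth rate (mm/day, 5-90% window) and maximal P9 growth
    rate (mm/day).
    """
    cols = ["species", "sex", "n", "shed_doy", "shed_sd", "mass_g", "mass_sd",
            "p9_mm", "p9_sd", "delta_rate", "delta_sd", "max_rate", "max_sd"]
    rows = [
        ("HADU", "F", 6, _doy(8, 13), 3, 543.3, 24.2, 129.0, 3.3, 3.43, 0.10, 4.66, 0.13),
        ("HADU", "M", 13, _doy(8, 7), 5, 609.2, 29.0, 132.1, 3.6, 3.48, 0.14, 4.77, 0.22),
        ("LTDU", "F", 6, _doy(8, 1), 12, 563.3, 25.8, 137.7, 1.7, 4.20, 0.13, 5.91, 0.21),
        ("LTDU", "M", 3, _doy(7, 24), 8, 610.0, 85.4, 142.0, 4.0, 4.14, 0.28, 5.86, 0.38),
        ("SUSC", "F", 3, _doy(7, 22), 6, 756.0, 54.1, 147.7, 0.6, 3.71, 0.07, 5.18, 0.12),
        ("SUSC", "M", 5, _doy(7, 13), 11, 848.0, 31.1, 154.2, 2.6, 3.64, 0.10, 5.11, 0.23),
        ("WWSC", "F", 7, _doy(8, 2), 4, 1067.1, 111.8, 169.4, 3.3, 4.10, 0.17, 5.62, 0.28),
        ("WWSC", "M", 9, _doy(7, 23), 11, 1270.0, 93.8, 178.1, 3.0, 4.03, 0.12, 5.55, 0.19),
        ("COEI", "F", 5, _doy(8, 8), 8, 1905.6, 115.2, 180.5, 5.6, 3.82, 0.17, 5.39, 0.25),
        ("COEI", "M", 4, _doy(7, 28), 7, 1946.0, 86.7, 181.1, 5.5, 3.81, 0.30, 5.40, 0.44),
    ]
    return pd.DataFrame(rows, columns=cols)


def default_templates() -> list[CohortTemplate]:
    """The 10 species-sex cohort templates seeded from the published table."""
    out = []
    for r in reference_cohorts().itertuples():
        out.append(CohortTemplate(
            species=r.species, sex=r.sex, n_birds=int(r.n),
            mean_shed_day=float(r.shed_doy), sd_shed_day=float(r.shed_sd),
            mean_A=float(r.p9_mm), sd_A=float(r.p9_sd),
            mean_mu=float(r.max_rate), sd_mu=float(r.max_sd),
            mean_mass0=float(r.mass_g), sd_mass0=float(r.mass_sd),
        ))
    return out


def lambda_for_shed(A: float, mu: float, shed_day: float,
                    shed_length_mm: float = 1.0) -> float:
    """Lag phase placing the Gompertz 1-mm crossing on ``shed_day``."""
    f = shed_length_mm / A
    if not 0.0 < f < 1.0:
        raise ParameterError("shed length must be below the asymptote")
    return shed_day - (A / (mu * _E)) * (1.0 - math.log(-math.log(f)))


def mass_pattern(frac, rise_frac: float, dip_frac: float,
                 nodes=MASS_PATTERN_NODES):
    """Noise-free body mass (as a multiple of initial mass) at fractional
    feather growth ``frac``; piecewise linear through
    (nodes[0], 1) -> (nodes[1], rise) -> (nodes[2], dip) -> (nodes[3], 1)."""
    frac = np.clip(np.asarray(frac, dtype=float), 0.0, 1.0)
    out = np.interp(frac, nodes, [1.0, rise_frac, dip_frac, 1.0])
    return out if out.ndim else float(out)


def _truncated_normal(rng, mean, sd, low=0.0, max_retries=1000):
    """Rejection-sampled normal draw constrained to > low."""
    if sd == 0.0:
        if mean <= low:
            raise DataError(f"degenerate draw: mean {mean} not above {low}")
        return float(mean)
    for _ in range(max_retries):
        x = rng.normal(mean, sd)
        if x > low:
            return float(x)
    raise DataError(
        f"truncated-normal rejection failed after {max_retries} retries "
        f"(mean={mean}, sd={sd}, low={low})"
    )


def simulate_cohort(template: CohortTemplate, seed: int,
                    shed_length_mm: float = 1.0,
                    ) -> tuple[list[BirdSeries], list[TruthRecord]]:
    """Simulate one cohort of birds on the study's measurement grid.

    Per bird: truths (A, mu, shed day, initial mass) are drawn from the
    template's normal distributions (A, mu, mass truncated at 0); lambda is
    set so the curve crosses ``shed_length_mm`` on the shed day.  Weekly P9
    observations are curve value + Gaussian noise, clipped at 0, and missing
    before the shed day; fortnightly mass observations follow the
    rise-dip-recover pattern + Gaussian noise.  Identical (template, seed)
    pairs yield identical outputs.
    """
    rng = np.random.default_rng(seed)
    birds, truths = [], []
    for i in range(template.n_birds):
        A = _truncated_normal(rng, template.mean_A, template.sd_A)
        mu = _truncated_normal(rng, template.mean_mu, template.sd_mu)
        mass0 = _truncated_normal(rng, template.mean_mass0, template.sd_mass0)
        shed = rng.normal(template.mean_shed_day, template.sd_shed_day)
        lam = lambda_for_shed(A, mu, shed, shed_length_mm)
        bird_id = f"{template.species}-{template.sex}-{i + 1:02d}"

        days = np.array(sorted(set(P9_DAYS) | set(MASS_DAYS)), dtype=float)
        p9 = np.full_like(days, np.nan)
        mass = np.full_like(days, np.nan)

        is_p9_day = np.isin(days, np.asarray(P9_DAYS, dtype=float))
        post_shed = days >= shed
        take = is_p9_day & post_shed
        curve = gompertz_value(days, A, mu, lam)
        noise = rng.normal(0.0, template.noise_sd_p9, size=int(take.sum())) \
            if template.noise_sd_p9 > 0 else 0.0
        p9[take] = np.clip(curve[take] + noise, 0.0, None)

        is_mass_day = np.isin(days, np.asarray(MASS_DAYS, dtype=float))
        frac = np.where(post_shed, curve / A, 0.0)
        base = mass0 * mass_pattern(frac, template.mass_rise_frac,
                                    template.mass_dip_frac,
                                    template.pattern_nodes)
        mnoise = rng.normal(0.0, template.noise_sd_mass, size=int(is_mass_day.sum())) \
            if template.noise_sd_mass > 0 else 0.0
        mass[is_mass_day] = base[is_mass_day] + mnoise

        birds.append(BirdSeries(bird_id, template.species, template.sex,
                                days, p9, mass))
        truths.append(TruthRecord(bird_id, A, mu, lam, shed, mass0))
    return birds, truths


def simulate_templates(templates, seed: int,
                       ) -> tuple[list[BirdSeries], list[TruthRecord]]:
    """Simulate several cohorts with independent child seeds derived from
    ``seed`` (deterministic; cohort order follows ``templates``)."""
    children = np.random.SeedSequence(seed).spawn(len(templates))
    birds, truths = [], []
    for template, child in zip(templates, children):
        b, t = simulate_cohort(template, np.random.default_rng(child).integers(2**31))
        birds.extend(b)
        truths.extend(t)
    return birds, truths


def truths_to_frame(truths) -> pd.DataFrame:
    """Truth records as a tidy DataFrame (one row per simulated bird)."""
    return pd.DataFrame([t.__dict__ for t in truths])
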