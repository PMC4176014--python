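"""End-to-end orchestration: simulate/ingest -> fit -> timing -> allometry ->
body mass -> report.

Every stage is re-runnable from the previous stage's tabular output, and the
whole bundle is deterministic for a fixed (config, seed): the master seed is
split with a seed sequence into independent child streams for simulation,
per-cohort bootstraps and the Monte-Carlo many-to-one adjustment, and the
manifest records the configuration and library versions needed to reproduce
any bundle byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, allometry, bodymass, growth, io, stats, synthetic
from .errors import DataError, ParameterError

GENUS_OF = {
    "HADU": "Histrionicus",
    "LTDU": "Clangula",
    "SUSC": "Melanitta",
    "WWSC": "Melanitta",
    "COEI": "Somateria",
}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    input_path: str = None          # tidy CSV; None -> simulate from templates
    templates: list = None          # None -> synthetic.default_templates()
    seed: int = 0
    flight_threshold: float = 0.90
    delta_lo: float = 0.05
    delta_hi: float = 0.90
    shed_length_mm: float = 1.0
    phase_boundaries: tuple = (0.25, 0.60, 0.80, 0.95, 1.0)
    bootstrap_B: int = 10000
    alpha: float = 0.05
    dunnett_draws: int = 100_000
    delta_from_observations: bool = False
    outdir: str = None

    def __post_init__(self):
        for name in ("flight_threshold", "delta_lo", "delta_hi", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ParameterError(f"{name} must lie in (0, 1), got {v}")
        if not self.delta_lo < self.delta_hi:
            raise ParameterError("delta_lo must be below delta_hi")
        if self.bootstrap_B < 1000:
            raise ParameterError("bootstrap_B must be >= 1000")

    def phase_defs(self) -> bodymass.PhaseDefinition:
        return bodymass.PhaseDefinition(tuple(self.phase_boundaries))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.templates is not None:
            d["templates"] = [dataclasses.asdict(t) for t in self.templates]
        d["phase_boundaries"] = list(self.phase_boundaries)
        return d


def _child_seed(seed_seq: np.random.SeedSequence) -> int:
    return int(np.random.default_rng(seed_seq).integers(2**31))


def stage_simulate(config: RunConfig):
    """Simulate the configured cohorts; returns (series list, truth frame)."""
    templates = config.templates or synthetic.default_templates()
    birds, truths = synthetic.simulate_templates(templates, config.seed)
    return birds, synthetic.truths_to_frame(truths)


def stage_fit(series_list, config: RunConfig) -> pd.DataFrame:
    """Fit every bird and derive moult timing; one row per convergent bird."""
    rows = []
    for s in series_list:
        if s.n_p9 < 4:
            warnings.warn(f"bird {s.bird_id}: too few P9 points, skipped")
            continue
        fit = growth.fit_growth(s, "gompertz")
        if not fit.converged:
            warnings.warn(f"bird {s.bird_id}: fit did not converge "
                          f"({fit.message}), skipped")
            continue
        timing = growth.moult_timing(
            fit, shed_length_mm=config.shed_length_mm,
            flight_threshold=config.flight_threshold,
            lo=config.delta_lo, hi=config.delta_hi)
        delta = timing.delta_rate
        if config.delta_from_observations:
            try:
                delta = growth.delta_rate_observed(
                    s, fit.A, config.delta_lo, config.delta_hi)
            except DataError:
                warnings.warn(f"bird {s.bird_id}: observations do not bracket "
                              "the delta window; fitted-curve rate used")
        rows.append({
            "bird_id": s.bird_id, "species": s.species, "sex": s.sex,
            "A_mm": fit.A, "mu_mm_day": fit.mu, "lambda_day": fit.lambda_,
            "rss": fit.rss, "n_obs": fit.n_obs, "aicc": fit.aicc,
            "shed_day": timing.shed_day, "flight_day": timing.flight_day,
            "flightless_days": timing.flightless_days,
            "delta_rate": delta, "max_rate": timing.max_rate,
            "delta_rate_pct": growth.rate_percent(delta, fit.A),
            "max_rate_pct": timing.max_rate_pct,
            "initial_mass_g": growth.initial_mass(s, timing.shed_day),
        })
    if not rows:
        raise DataError("fit stage produced no convergent birds")
    return pd.DataFrame(rows)


def stage_summary(fits: pd.DataFrame) -> pd.DataFrame:
    """Cohort (species x sex) summary table from the per-bird fit table."""
    return growth.summarize_bird_table(
        fits.rename(columns={"A_mm": "p9_final_mm"}))


def stage_allometry(fits: pd.DataFrame, config: RunConfig) -> dict:
    """Inter-specific allometry (OLS/MA/RMA), genus ANCOVA, intra-specific
    correlations and the combined moult-duration exponent."""
    ok = fits.dropna(subset=["initial_mass_g", "delta_rate", "A_mm"])
    ok = ok[(ok["initial_mass_g"] > 0) & (ok["delta_rate"] > 0)]
    responses = {"delta_rate": ok["delta_rate"], "p9_length": ok["A_mm"]}
    results = []
    for resp, y in responses.items():
        for method in ("OLS", "MA", "RMA"):
            results.append(allometry.loglog_fit(
                ok["initial_mass_g"], y, method=method, response=resp,
                alpha=config.alpha, seed=config.seed))
    table = pd.DataFrame([dataclasses.asdict(r) for r in results])

    ols = {r.response: r for r in results if r.method == "OLS"}
    b_len, b_rate = ols["p9_length"], ols["delta_rate"]
    se_len = (b_len.ci_high - b_len.ci_low) / 2.0
    se_rate = (b_rate.ci_high - b_rate.ci_low) / 2.0
    half = float(np.hypot(se_len, se_rate))
    b_dur = allometry.duration_exponent(b_len.slope_b, b_rate.slope_b)
    duration = {
        "exponent": b_dur,
        "ci_low": b_dur - half,
        "ci_high": b_dur + half,
        "b_length": b_len.slope_b,
        "b_rate": b_rate.slope_b,
        "mass_doubling_rate_pct": allometry.mass_doubling_pct(b_rate.slope_b),
    }

    ancova = {}
    anc_tab = ok.assign(
        ln_mass=np.log(ok["initial_mass_g"]),
        genus=ok["species"].map(lambda s: GENUS_OF.get(s, s)),
    )
    for resp, y in responses.items():
        tab = anc_tab.assign(ln_y=np.log(y))
        counts = tab.groupby("genus").size()
        if len(counts) >= 2 and (counts >= 3).all():
            try:
                ancova[resp] = dataclasses.asdict(allometry.genus_ancova(tab))
            except DataError as exc:
                warnings.warn(f"genus ANCOVA for {resp} skipped: {exc}")

    intra = {}
    for species, g in ok.groupby("species"):
        if len(g) >= 3 and g["initial_mass_g"].nunique() > 1 \
                and g["delta_rate"].nunique() > 1:
            intra.update(allometry.intraspecific_correlations(
                {species: (g["initial_mass_g"], g["delta_rate"])}))
    intra = {k: {"r": v[0], "p": v[1]} for k, v in intra.items()}
    return {"table": table, "duration_exponent": duration,
            "ancova": ancova, "intraspecific": intra}


def stage_bodymass(series_list, fits: pd.DataFrame, config: RunConfig,
                   seed_seq: np.random.SeedSequence = None) -> dict:
    """Phase x %-of-initial-mass table, per-cohort studentized-bootstrap mass
    deltas (phase IV vs initial) and Dunnett-style per-phase comparisons."""
    defs = config.phase_defs()
    fit_by_bird = fits.set_index("bird_id")
    pct_rows, phase4 = [], {}
    phase_mass = {}
    for s in series_list:
        if s.bird_id not in fit_by_bird.index:
            continue
        row = fit_by_bird.loc[s.bird_id]
        fit = growth.GrowthFit("gompertz", row["A_mm"], row["mu_mm_day"],
                               row["lambda_day"], row["rss"],
                               int(row["n_obs"]), row["aicc"], True)
        timing = growth.moult_timing(
            fit, shed_length_mm=config.shed_length_mm,
            flight_threshold=config.flight_threshold,
            lo=config.delta_lo, hi=config.delta_hi)
        try:
            pct = bodymass.pct_initial_mass(s, fit, timing, defs)
        except DataError as exc:
            warnings.warn(str(exc))
            continue
        for r in pct.itertuples():
            pct_rows.append({"species": s.species, "sex": s.sex,
                             "bird_id": s.bird_id, "phase": r.phase,
                             "pct_initial": r.pct_initial, "mass_g": r.mass_g})
        phase_mass[s.bird_id] = dict(zip(pct["phase"], pct["mass_g"]))
    if not pct_rows:
        raise DataError("no birds with a phase-0 mass")
    pct_long = pd.DataFrame(pct_rows)
    fig4 = (pct_long.groupby(["species", "sex", "phase"])["pct_initial"]
            .agg(["mean", "std", "size"]).reset_index()
            .rename(columns={"mean": "pct_initial_mean",
                             "std": "pct_initial_sd", "size": "n_birds"}))

    seed_seq = seed_seq or np.random.SeedSequence(config.seed)
    cohorts = sorted({(r["species"], r["sex"]) for r in pct_rows})
    children = seed_seq.spawn(2 * len(cohorts))
    deltas, dunnett = [], []
    meta = pct_long[["bird_id", "species", "sex"]].drop_duplicates().set_index("bird_id")
    for i, (species, sex) in enumerate(cohorts):
        ids = [b for b in phase_mass
               if meta.loc[b, "species"] == species and meta.loc[b, "sex"] == sex]
        wide = pd.DataFrame.from_dict(
            {b: phase_mass[b] for b in ids}, orient="index")
        wide = wide.reindex(columns=[p for p in bodymass.PHASE_LABELS
                                     if p in wide.columns])
        pairs = wide.dropna(subset=[c for c in ("0", "IV") if c in wide.columns])
        if "0" in wide.columns and "IV" in wide.columns and len(pairs) >= 3:
            md = bodymass.studentized_bootstrap_delta(
                pairs["0"], pairs["IV"], B=config.bootstrap_B,
                seed=_child_seed(children[2 * i]), alpha=config.alpha,
                species=species, sex=sex)
            deltas.append(dataclasses.asdict(md))
        else:
            warnings.warn(f"cohort {species}-{sex}: too few paired phase-0/IV "
                          "masses for the bootstrap delta")
        try:
            dd = bodymass.dunnett_vs_initial(
                wide, n_draws=config.dunnett_draws,
                seed=_child_seed(children[2 * i + 1]))
            dd.insert(0, "species", species)
            dd.insert(1, "sex", sex)
            dunnett.append(dd)
        except DataError as exc:
            warnings.warn(f"cohort {species}-{sex}: {exc}")
    return {
        "phase_pct": fig4,
        "mass_delta": pd.DataFrame(deltas),
        "dunnett": pd.concat(dunnett, ignore_index=True) if dunnett
        else pd.DataFrame(),
    }


def stage_stats(fits: pd.DataFrame) -> dict:
    """Auxiliary comparisons: sexes (shed day, pooled Mann-Whitney) and
    species (delta growth rate: ANOVA + Tukey, Bartlett)."""
    out = {}
    males = fits.loc[fits["sex"] == "M", "shed_day"]
    females = fits.loc[fits["sex"] == "F", "shed_day"]
    if len(males) and len(females):
        res = stats.mann_whitney_u(males, females)
        out["shed_day_sex_mannwhitney"] = dataclasses.asdict(res)
    by_species = {sp: g["delta_rate"].to_numpy()
                  for sp, g in fits.groupby("species") if len(g) >= 2}
    if len(by_species) >= 2:
        anova, tukey = stats.anova_tukey(by_species)
        out["delta_rate_anova"] = dataclasses.asdict(anova)
        out["delta_rate_tukey"] = tukey.to_dict(orient="records")
        out["delta_rate_bartlett"] = dataclasses.asdict(
            stats.bartlett(by_species))
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the report bundle (tables + JSON-ables)."""
    truth = None
    if config.input_path:
        series_list = io.read_measurements(config.input_path)
    else:
        series_list, truth = stage_simulate(config)
    fits = stage_fit(series_list, config)
    bundle = {
        "measurements": io.measurements_frame(series_list),
        "truth": truth,
        "fits": fits,
        "summary": stage_summary(fits),
        "allometry": stage_allometry(fits, config),
        "bodymass": stage_bodymass(series_list, fits, config,
                                   np.random.SeedSequence([config.seed, 1])),
        "stats": stage_stats(fits),
        "manifest": _manifest(config),
    }
    if config.outdir:
        write_report(bundle, config.outdir)
    return bundle


def _manifest(config: RunConfig) -> dict:
    import scipy
    import statsmodels
    return {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {
            "moultfit": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_report(bundle: dict, outdir) -> None:
    """Write the bundle as CSV tables plus report.json and manifest.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    bundle["measurements"].to_csv(out / "measurements.csv", index=False,
                                  float_format=fmt)
    if bundle.get("truth") is not None:
        bundle["truth"].to_csv(out / "truth.csv", index=False, float_format=fmt)
    bundle["fits"].to_csv(out / "fits.csv", index=False, float_format=fmt)
    bundle["summary"].to_csv(out / "cohort_summary.csv", index=False,
                             float_format=fmt)
    bundle["allometry"]["table"].to_csv(out / "allometry.csv", index=False,
                                        float_format=fmt)
    bm = bundle["bodymass"]
    bm["phase_pct"].to_csv(out / "phase_pct_mass.csv", index=False,
                           float_format=fmt)
    bm["mass_delta"].to_csv(out / "mass_delta.csv", index=False,
                            float_format=fmt)
    bm["dunnett"].to_csv(out / "dunnett.csv", index=False, float_format=fmt)
    report = {
        "allometry": {k: _jsonable(v) for k, v in bundle["allometry"].items()},
        "bodymass": {k: _jsonable(v) for k, v in bm.items()},
        "stats": _jsonable(bundle["stats"]),
    }
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, allow_nan=True) + "\n")
    (out / "manifest.json").write_text(
        json.dumps(_jsonable(bundle["manifest"]), indent=2, sort_keys=True)
        + "\n")
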