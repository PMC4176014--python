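"""Tidy CSV interface for longitudinal moult measurements.

Schema: one row per bird per measurement day with header
``bird_id,species,sex,day,p9_mm,mass_g``; empty cells mean "not measured".
``day`` is either an integer/real day-of-year or an ISO date (normalized to
day-of-year at ingest, so both encodings yield identical downstream
results).  Duplicate (bird_id, day) rows are rejected with their row
numbers; unknown species codes are retained with a warning.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .datatypes import BirdSeries
from .errors import DataError

COLUMNS = ["bird_id", "species", "sex", "day", "p9_mm", "mass_g"]
KNOWN_SPECIES = {"HADU", "LTDU", "SUSC", "WWSC", "COEI"}


def _normalize_days(raw: pd.Series) -> pd.Series:
    """Parse the day column: real day-of-year, or ISO date -> day-of-year."""
    try:
        return raw.astype(float)
    except (TypeError, ValueError):
        pass
    parsed = pd.to_datetime(raw, format="ISO8601", errors="raise")
    return parsed.dt.dayofyear.astype(float)


def read_measurements(path) -> list[BirdSeries]:
    """Read the tidy measurement CSV into per-bird series."""
    df = pd.read_csv(path, dtype={"bird_id": str, "species": str, "sex": str})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    df["day"] = _normalize_days(df["day"])
    dup = df.duplicated(subset=["bird_id", "day"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()  # 1-based, counting the header
        raise DataError(f"{path}: duplicate (bird_id, day) rows at lines {rows}")
    unknown = sorted(set(df["species"]) - KNOWN_SPECIES)
    if unknown:
        warnings.warn(f"{path}: unknown species codes retained: {unknown}")
    series = []
    for bird_id, g in df.groupby("bird_id", sort=True):
        g = g.sort_values("day")
        series.append(BirdSeries(
            bird_id=str(bird_id),
            species=str(g["species"].iloc[0]),
            sex=str(g["sex"].iloc[0]),
            days=g["day"].to_numpy(float),
            p9_mm=g["p9_mm"].to_numpy(float),
            mass_g=g["mass_g"].to_numpy(float),
        ))
    return series


def measurements_frame(series_list) -> pd.DataFrame:
    """Per-bird series flattened back to the tidy one-row-per-day schema."""
    rows = []
    for s in series_list:
        for day, p9, mass in zip(s.days, s.p9_mm, s.mass_g):
            rows.append({"bird_id": s.bird_id, "species": s.species,
                         "sex": s.sex, "day": day, "p9_mm": p9, "mass_g": mass})
    return pd.DataFrame(rows, columns=COLUMNS)


def write_measurements(series_list, path) -> None:
    """Write per-bird series as the tidy CSV (NaN -> empty cell)."""
    measurements_frame(series_list).to_csv(path, index=False, float_format="%.10g")
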