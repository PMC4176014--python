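"""Core longitudinal container: one bird's moult-season measurement series.

A bird is measured on a common day grid (day-of-year of the study season);
9th-primary (P9) length is recorded weekly and body mass fortnightly, so both
vectors are aligned to ``days`` with NaN marking days on which that quantity
was not (or could not be) measured.  P9 is missing before the old feather is
shed — old-feather length is not new-feather growth and is never recorded
as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

#: Minimum number of non-missing P9 points required to fit a growth curve.
MIN_P9_POINTS = 4


@dataclass
class BirdSeries:
    """Longitudinal P9 and body-mass measurements for a single bird.

    Parameters
    ----------
    bird_id : str
        Unique bird identifier.
    species : str
        Species code (e.g. ``HADU``, ``LTDU``, ``SUSC``, ``WWSC``, ``COEI``).
    sex : str
        ``"F"`` or ``"M"``.
    days : ndarray
        Strictly increasing measurement days (real day-of-year).
    p9_mm : ndarray
        P9 length (mm) aligned to ``days``; NaN where not measured
        (including pre-shed occasions).
    mass_g : ndarray
        Body mass (g) aligned to ``days``; NaN where not weighed.
    """

    bird_id: str
    species: str
    sex: str
    days: np.ndarray
    p9_mm: np.ndarray
    mass_g: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.p9_mm = np.asarray(self.p9_mm, dtype=float)
        if self.mass_g is None:
            self.mass_g = np.full_like(self.days, np.nan)
        self.mass_g = np.asarray(self.mass_g, dtype=float)
        if self.days.ndim != 1:
            raise DataError(f"bird {self.bird_id}: days must be 1-D")
        if len(self.p9_mm) != len(self.days) or len(self.mass_g) != len(self.days):
            raise DataError(f"bird {self.bird_id}: measurement vectors misaligned")
        if len(self.days) > 1 and not np.all(np.diff(self.days) > 0):
            raise DataError(f"bird {self.bird_id}: days must be strictly increasing")
        finite = self.p9_mm[np.isfinite(self.p9_mm)]
        if np.any(finite < 0):
            raise DataError(f"bird {self.bird_id}: negative P9 length")

    @property
    def n_p9(self) -> int:
        """Number of non-missing P9 observations."""
        return int(np.isfinite(self.p9_mm).sum())

    def p9_observations(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (days, lengths) for the non-missing P9 measurements."""
        m = np.isfinite(self.p9_mm)
        return self.days[m], self.p9_mm[m]

    def mass_observations(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (days, masses) for the non-missing body-mass measurements."""
        m = np.isfinite(self.mass_g)
        return self.days[m], self.mass_g[m]
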