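"""Age-period conventions and the macro-indicator series container.

Ages are pure period differences (calendar year minus year of birth): the
census-style data this package emulates records only years of birth, so a
woman's exact age in year ``t`` lies between ``a - 1`` and ``a + 1``.  All
rates, survivor functions and indicators use the same convention, so the
pipeline is internally consistent on the Lexis rectangle delimited by ages
15-50 and the analysis window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import CoverageError, ValidationError

#: Reproductive age range (inclusive) for first-birth risk.
AGE_MIN = 15
AGE_MAX = 49

#: Education categories (ISCED97 groupings), lowest first.  The first entry
#: is the reference category in all hazard-model contrasts.
LEVELS = ["ISCED01", "ISCED2", "ISCED34", "ISCED5B", "ISCED5A6"]

#: Minimal plausible age at obtaining the highest certificate, per level.
MIN_LEAVING_AGE = {
    "ISCED01": 14,
    "ISCED2": 16,
    "ISCED34": 18,
    "ISCED5B": 21,
    "ISCED5A6": 23,
}

#: Five-year age groups partitioning ages 15-49.
AGE_GROUPS = ["15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49"]

#: Age groups 30+ through which the 10-year unemployment lag (recuperation
#: of postponed births) enters the hazard models.
OLD_AGE_GROUPS = ["30-34", "35-39", "40-44", "45-49"]

#: Calendar-period segmentation: post-war growth, the 1970s-80s recessions,
#: and the 1992-2010 era of milder downturns.
PERIODS = ["P1", "P2", "P3"]
PERIOD_RANGES = {"P1": (1960, 1973), "P2": (1974, 1991), "P3": (1992, 2010)}


def age_group(a):
    """Five-year age-group label(s) for age(s) ``a`` in 15..49."""
    a = np.asarray(a)
    if np.any((a < AGE_MIN) | (a > AGE_MAX)):
        raise ValidationError("age outside the 15-49 risk range")
    idx = (a - AGE_MIN) // 5
    labels = np.asarray(AGE_GROUPS, dtype=object)[idx]
    return labels if labels.ndim else labels.item()


def assign_period(t):
    """Map calendar year(s) to the period category P1/P2/P3.

    Years outside 1960-2010 raise a :class:`ValidationError`: the period
    segmentation is only defined on the analysis window.
    """
    t = np.asarray(t)
    if np.any((t < PERIOD_RANGES["P1"][0]) | (t > PERIOD_RANGES["P3"][1])):
        raise ValidationError("year outside the 1960-2010 period segmentation")
    out = np.full(t.shape, "P3", dtype=object)
    out[t <= PERIOD_RANGES["P1"][1]] = "P1"
    out[(t >= PERIOD_RANGES["P2"][0]) & (t <= PERIOD_RANGES["P2"][1])] = "P2"
    return out if out.ndim else out.item()


@dataclass
class MacroSeries:
    """An annual macro-level indicator series (e.g. unemployment rate, %).

    Years must be contiguous and values finite; unemployment-style series
    are non-negative.  The series must reach back at least 10 years before
    the first modelled year so that both the 1-year and the 10-year lag
    resolve.
    """

    series: pd.Series = field()

    def __post_init__(self):
        s = pd.Series(self.series).astype(float)
        s.index = s.index.astype(int)
        s = s.sort_index()
        years = s.index.to_numpy()
        if len(years) == 0:
            raise ValidationError("macro series is empty")
        if not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
            raise ValidationError("macro series years are not contiguous")
        if not np.all(np.isfinite(s.to_numpy())):
            raise ValidationError("macro series contains non-finite values")
        if (s.to_numpy() < 0).any():
            raise ValidationError("macro series contains negative values")
        self.series = s

    @property
    def years(self) -> np.ndarray:
        return self.series.index.to_numpy()

    def value(self, year):
        """Indicator level(s) at ``year`` (vectorised); missing years error."""
        year = np.asarray(year)
        lo, hi = self.years[0], self.years[-1]
        if np.any((year < lo) | (year > hi)):
            raise CoverageError(
                f"macro series covers {lo}-{hi}; requested year(s) outside"
            )
        vals = self.series.to_numpy()[year - lo]
        return vals if vals.ndim else vals.item()

    def require_coverage(self, window_start: int, window_end: int) -> None:
        """Check both lags resolve for every year of the analysis window."""
        need_lo, need_hi = window_start - 10, window_end - 1
        if self.years[0] > need_lo or self.years[-1] < need_hi:
            raise CoverageError(
                f"macro series must cover {need_lo}-{need_hi} for window "
                f"{window_start}-{window_end}; covers "
                f"{self.years[0]}-{self.years[-1]}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "value": self.series.to_numpy()})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MacroSeries":
        return cls(pd.Series(frame["value"].to_numpy(), index=frame["year"].to_numpy()))


def read_macro(path) -> MacroSeries:
    """Read a delimited macro file with columns ``year, value``."""
    return MacroSeries.from_frame(pd.read_csv(path))


def write_macro(macro: MacroSeries, path) -> None:
    macro.to_frame().to_csv(path, index=False)
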