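"""Retrospective synthetic-cohort indicators of first-birth tempo and quantum.

From decremental first-birth rates ``b(a, t)`` (events among nulliparous
women divided by nulliparous exposure, per Lexis cell) a period life table
is built for each calendar year:

* the survivor function ``S(a)`` with ``S(15) = 1`` and
  ``S(a+1) = S(a) * (1 - b(a, t))``,
* the synthetic parity progression ratio to a first birth
  ``SPPR1(t) = 1 - prod_{a=15..49} (1 - b(a, t)) = 1 - S(50)``,
* the synthetic mean age at first birth
  ``SMAC1(t) = sum_{a=15..49} a * (S(a) - S(a+1)) / SPPR1(t)``.

The multiplier is ``a`` itself (no half-year shift): with ages measured in
period difference, ``a`` is the centre of the birth parallelogram.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import DataError, ValidationError
from .lexis import AGE_MAX, AGE_MIN

logger = logging.getLogger(__name__)

AGES = np.arange(AGE_MIN, AGE_MAX + 1)


def rate_surface(cells: pd.DataFrame) -> pd.DataFrame:
    """Decremental rates per Lexis cell from event and exposure counts.

    ``cells`` has columns ``a, t, events, exposure``.  The result is a
    DataFrame indexed by age (15..49) with one column per year; cells with
    zero exposure are NaN (an explicit empty marker, never 0/0).
    """
    c = cells
    ev = c["events"].to_numpy(dtype=float)
    ex = c["exposure"].to_numpy(dtype=float)
    if (ex < 0).any() or (ev < 0).any():
        raise DataError("negative event or exposure counts")
    if (ev > ex).any():
        raise DataError("events exceed exposure in at least one Lexis cell")
    rate = np.divide(ev, ex, out=np.full(len(c), np.nan), where=ex > 0)
    surf = (
        pd.DataFrame({"a": c["a"].to_numpy(), "t": c["t"].to_numpy(), "rate": rate})
        .pivot(index="a", columns="t", values="rate")
        .reindex(AGES)
    )
    surf.index.name = "a"
    return surf


def tabulate_event_log(log: pd.DataFrame) -> pd.DataFrame:
    """Event/exposure counts per (a, t) cell from an event log or
    person-year table (any frame with columns ``a, t, b``)."""
    g = log.groupby(["a", "t"])["b"].agg(events="sum", exposure="size")
    return g.reset_index()


def _year_rates(surface: pd.DataFrame, t, empty: str = "zero") -> np.ndarray:
    if t not in surface.columns:
        raise ValidationError(f"year {t} not covered by the rate surface")
    rates = surface[t].reindex(AGES).to_numpy(dtype=float)
    n_empty = int(np.isnan(rates).sum())
    if n_empty:
        if empty == "drop":
            return np.full(len(AGES), np.nan)
        logger.warning(
            "year %s: %d empty Lexis cells treated as rate 0", t, n_empty
        )
        rates = np.nan_to_num(rates, nan=0.0)
    if ((rates < 0) | (rates > 1)).any():
        raise DataError("rates outside [0, 1]")
    return rates


def sppr1(surface: pd.DataFrame, t, empty: str = "zero") -> float:
    """Synthetic parity progression ratio to a first birth in year ``t``."""
    rates = _year_rates(surface, t, empty)
    if np.isnan(rates).any():
        return np.nan
    return float(1.0 - np.prod(1.0 - rates))


def survivor_function(surface: pd.DataFrame, t, empty: str = "zero") -> pd.Series:
    """Period survivor function S(a) for a = 15..50 in year ``t``."""
    rates = _year_rates(surface, t, empty)
    S = np.concatenate(([1.0], np.cumprod(1.0 - rates)))
    return pd.Series(S, index=np.arange(AGE_MIN, AGE_MAX + 2), name=t)


def smac1(surface: pd.DataFrame, t, empty: str = "zero") -> float:
    """Synthetic mean age at first birth in year ``t``.

    The weighted mean of ages 15..49 with weights ``S(a) - S(a+1)``,
    normalised by SPPR1.  Undefined (NaN) when SPPR1 is zero.
    """
    S = survivor_function(surface, t, empty).to_numpy()
    if np.isnan(S).any():
        return np.nan
    decrements = S[:-1] - S[1:]
    total = 1.0 - S[-1]
    if total <= 0.0:
        return np.nan
    return float(np.sum(AGES * decrements) / total)


def indicator_series(surface: pd.DataFrame, empty: str = "zero") -> pd.DataFrame:
    """Per-year SPPR1 and SMAC1 for every year the surface covers."""
    years = list(surface.columns)
    return pd.DataFrame(
        {
            "sppr1": [sppr1(surface, t, empty) for t in years],
            "smac1": [smac1(surface, t, empty) for t in years],
        },
        index=pd.Index(years, name="year"),
    )


def replicate_mean(series_list: list[pd.DataFrame]) -> pd.DataFrame:
    """Element-wise mean of per-replicate indicator series.

    Undefined (NaN) replicate values are excluded; the output records the
    replicate mean, standard deviation, and the count of defined
    replicates per indicator and year.  A year where every replicate is
    undefined stays undefined.
    """
    if len(series_list) < 1:
        raise ValidationError("need at least one replicate series")
    out = {}
    for col in ("sppr1", "smac1"):
        stack = pd.concat([s[col] for s in series_list], axis=1)
        out[col] = stack.mean(axis=1, skipna=True)
        out[f"{col}_sd"] = stack.std(axis=1, ddof=1, skipna=True)
        out[f"{col}_n"] = stack.notna().sum(axis=1)
    df = pd.DataFrame(out)
    df.index.name = "year"
    return df


def observed_indicators(
    life_courses: pd.DataFrame, window: tuple[int, int], empty: str = "zero"
) -> pd.DataFrame:
    """Observed SPPR1/SMAC1 series computed retrospectively from the
    recorded first-birth years, via the same rate-surface pipeline used
    for simulated event logs."""
    from .riskset import _expand_exposure

    rows, _ = _expand_exposure(life_courses, window)
    surf = rate_surface(tabulate_event_log(rows))
    return indicator_series(surf, empty=empty)


def observed_rate_surface(
    life_courses: pd.DataFrame, window: tuple[int, int]
) -> pd.DataFrame:
    """Observed decremental first-birth rate surface on the window."""
    from .riskset import _expand_exposure

    rows, _ = _expand_exposure(life_courses, window)
    return rate_surface(tabulate_event_log(rows))


def write_indicator_series(series: pd.DataFrame, path) -> None:
    series.to_csv(path)


def read_indicator_series(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="year")
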