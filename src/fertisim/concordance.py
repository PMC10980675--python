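"""Concordance between observed and simulated indicator time-series.

Three metrics quantify correspondence: the mean absolute deviation |e|,
the Pearson product-moment correlation r, and the Pearson correlation of
first differences r_dif (the correlation of year-to-year changes, which
discounts shared trends).  Each is reported over the whole window and
within the recession periods P1 (1960-1973), P2 (1974-1991) and P3
(1992-2010); per-period first differences are taken inside the period
only, so period rows are independent of the boundary years.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .lexis import PERIOD_RANGES, MacroSeries, assign_period


def _align(obs: pd.Series, sim: pd.Series) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    obs, sim = pd.Series(obs).dropna(), pd.Series(sim).dropna()
    years = obs.index.intersection(sim.index).sort_values()
    if len(years) == 0:
        raise ValidationError("observed and simulated series share no years")
    return (
        np.asarray(years),
        obs.loc[years].to_numpy(dtype=float),
        sim.loc[years].to_numpy(dtype=float),
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    # sample (n-1) normalisation; undefined under zero variance
    if len(x) < 2 or np.std(x, ddof=1) == 0 or np.std(y, ddof=1) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def mean_abs_deviation(obs: pd.Series, sim: pd.Series) -> float:
    """Mean of |obs_t - sim_t| over the years both series cover."""
    _, o, s = _align(obs, sim)
    return float(np.mean(np.abs(o - s)))


def correlation(obs: pd.Series, sim: pd.Series) -> float:
    """Pearson correlation over the common years."""
    _, o, s = _align(obs, sim)
    return _pearson(o, s)


def first_diff_correlation(obs: pd.Series, sim: pd.Series) -> float:
    """Pearson correlation of first differences over consecutive years.

    Differences are taken only between adjacent calendar years; gaps in
    the common support contribute no difference.  Undefined (NaN) when
    fewer than three consecutive common years exist or a difference
    series has zero variance.
    """
    years, o, s = _align(obs, sim)
    consec = np.diff(years) == 1
    do, ds = np.diff(o)[consec], np.diff(s)[consec]
    if len(do) < 2:
        return np.nan
    return _pearson(do, ds)


def per_period_breakdown(obs: pd.Series, sim: pd.Series) -> pd.DataFrame:
    """|e|, r and r_dif overall and within each recession period.

    Per-period first differences never straddle a period boundary.  A
    period with too few years for a metric gets an undefined (NaN) cell.
    """
    rows = {}
    segments = {
        p: (lambda y, rng=rng: (y >= rng[0]) & (y <= rng[1]))
        for p, rng in PERIOD_RANGES.items()
    }
    years, o, s = _align(obs, sim)
    for label, mask_fn in {**segments, "overall": lambda y: np.ones(len(y), bool)}.items():
        m = mask_fn(years)
        if m.sum() == 0:
            rows[label] = {"abs_e": np.nan, "r": np.nan, "r_dif": np.nan, "n_years": 0}
            continue
        ys, os_, ss = years[m], o[m], s[m]
        sub_o = pd.Series(os_, index=ys)
        sub_s = pd.Series(ss, index=ys)
        rows[label] = {
            "abs_e": mean_abs_deviation(sub_o, sub_s),
            "r": correlation(sub_o, sub_s),
            "r_dif": first_diff_correlation(sub_o, sub_s),
            "n_years": int(m.sum()),
        }
    out = pd.DataFrame(rows).T
    out.index.name = "period"
    out["n_years"] = out["n_years"].astype(int)
    return out


def concordance_report(
    obs: pd.DataFrame, sim: pd.DataFrame, indicators: tuple[str, ...] = ("sppr1", "smac1")
) -> pd.DataFrame:
    """Per-indicator, per-period concordance table (|e|, r, r_dif)."""
    parts = []
    for ind in indicators:
        part = per_period_breakdown(obs[ind], sim[ind])
        part.insert(0, "indicator", ind)
        parts.append(part.reset_index())
    return pd.concat(parts, ignore_index=True)


def cross_correlation(
    macro: MacroSeries,
    lag: int,
    indicator: pd.Series,
    differenced: bool = False,
) -> float:
    """Zero-order cross-correlation of a lagged macro series with an
    indicator series: corr(macro(t - lag), indicator(t)).

    With ``differenced=True`` the correlation is computed on first
    differences of both series (year-to-year change).
    """
    ind = pd.Series(indicator).dropna()
    years = np.asarray(ind.index, dtype=int)
    lagged_years = years - lag
    ok = (lagged_years >= macro.years[0]) & (lagged_years <= macro.years[-1])
    years = years[ok]
    if len(years) < 3:
        raise ValidationError("fewer than 3 overlapping years after lagging")
    x = np.asarray(macro.value(years - lag), dtype=float)
    y = ind.loc[years].to_numpy(dtype=float)
    if differenced:
        consec = np.diff(years) == 1
        x, y = np.diff(x)[consec], np.diff(y)[consec]
        if len(x) < 2:
            raise ValidationError("fewer than 2 consecutive differences after lagging")
    return _pearson(x, y)


def write_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, index=False)
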