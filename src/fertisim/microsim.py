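"""Microsimulation of first-birth event logs from a fitted hazard model.

Two modes are supported.  *Conditional* mode (the default) draws one
Bernoulli event per observed person-year against the fitted conditional
probability, holding the observed risk set fixed; its expectation equals
the direct calculation that averages the fitted probabilities over each
Lexis cell.  *Forward* mode regenerates each woman's risk trajectory on a
counterfactual full-exposure risk set, stopping at her first simulated
event, so post-event exposure never appears in the log.

Draws use one independent standard uniform per person-year, streamed in a
fixed (woman, year) order, so replicate streams are reproducible by seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np
import pandas as pd

from .exceptions import FertisimError, ValidationError

EVENT_LOG_COLUMNS = ["replicate", "woman_id", "t", "a", "r", "b"]


def predict_q(fitted, person_years: pd.DataFrame) -> np.ndarray:
    """Fitted conditional probability q = 1 - exp(-exp(eta)) per row.

    ``fitted`` is a :class:`~fertisim.hazard.FittedHazardModel`; its design
    is rebuilt on ``person_years``, so every covariate the specification
    needs must be present.
    """
    from .hazard import build_design

    X, _ = build_design(person_years, fitted.model_id, m10_split=fitted.m10_split)
    missing = [c for c in fitted.params.index if c not in X.columns]
    if missing:
        raise ValidationError(f"person-years lack design columns: {missing}")
    eta = X[list(fitted.params.index)].to_numpy() @ fitted.params.to_numpy()
    return -np.expm1(-np.exp(eta))


def _sorted_risk_set(person_years: pd.DataFrame, q) -> tuple[pd.DataFrame, np.ndarray]:
    py = person_years
    q = np.asarray(q, dtype=float)
    if len(q) != len(py):
        raise ValidationError("q must align with the person-year rows")
    order = np.lexsort((py["t"].to_numpy(), py["woman_id"].to_numpy()))
    return py.iloc[order].reset_index(drop=True), q[order]


def iter_event_logs(
    person_years: pd.DataFrame,
    q,
    replicates: int = 120,
    seed: int = 0,
    mode: str = "conditional",
) -> Iterator[pd.DataFrame]:
    """Yield one event-log DataFrame per replicate (memory-friendly).

    In conditional mode every observed person-year appears with its drawn
    uniform ``r`` and event flag ``b = (r <= q)``.  In forward mode,
    ``person_years`` should be the counterfactual full-exposure risk set
    (births ignored); rows of a woman after her first simulated event are
    dropped.
    """
    if mode not in ("conditional", "forward"):
        raise FertisimError(f"unknown microsimulation mode {mode!r}")
    if replicates < 1:
        raise FertisimError("replicates must be >= 1")
    py, q = _sorted_risk_set(person_years, q)
    woman = py["woman_id"].to_numpy()
    new_woman = np.empty(len(py), dtype=bool)
    if len(py):
        new_woman[0] = True
        new_woman[1:] = woman[1:] != woman[:-1]
    rng = np.random.default_rng(seed)
    for rep in range(replicates):
        r = rng.random(len(py))
        b = r <= q
        log = pd.DataFrame(
            {
                "replicate": rep,
                "woman_id": woman,
                "t": py["t"].to_numpy(),
                "a": py["a"].to_numpy(),
                "r": r,
                "b": b.astype(int),
            }
        )
        if mode == "forward":
            # keep rows up to and including each woman's first simulated event
            groups = np.cumsum(new_woman) - 1
            prior_events = np.concatenate(([0], np.cumsum(b)[:-1]))
            first_idx = np.where(new_woman)[0]
            events_before_group = prior_events[first_idx]
            had_event_before = (prior_events - events_before_group[groups]) > 0
            log = log.loc[~had_event_before].reset_index(drop=True)
        yield log


def simulate_event_log(
    person_years: pd.DataFrame,
    q,
    replicates: int = 120,
    seed: int = 0,
    mode: str = "conditional",
) -> pd.DataFrame:
    """All replicate event logs concatenated (columns: replicate, woman_id,
    t, a, r, b).  Reproducible by seed; see :func:`iter_event_logs`."""
    logs = list(iter_event_logs(person_years, q, replicates, seed, mode))
    return pd.concat(logs, ignore_index=True)


def direct_rate_surface(person_years: pd.DataFrame, q) -> pd.DataFrame:
    """Expected decremental rate per Lexis cell: the mean of q over the
    risk set in each (age, year) cell.  Cells with no exposure are NaN.

    This is the closed-form counterpart of conditional-mode simulation:
    averaging simulated event indicators over replicates converges to it.
    """
    py = person_years
    q = np.asarray(q, dtype=float)
    if len(q) != len(py):
        raise ValidationError("q must align with the person-year rows")
    df = pd.DataFrame({"a": py["a"].to_numpy(), "t": py["t"].to_numpy(), "q": q})
    cell = df.groupby(["a", "t"])["q"].mean().unstack("t")
    return cell


def write_event_log(log: pd.DataFrame, path) -> None:
    log.to_csv(path, index=False, columns=EVENT_LOG_COLUMNS)


def read_event_log(path) -> pd.DataFrame:
    return pd.read_csv(path)
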