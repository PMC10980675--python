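"""Person-year risk-set expansion on the Lexis rectangle.

Each childless woman contributes one row per calendar year from the later
of the window start and the year she turns 15, up to and including the
year of her first birth, the year she turns 49, or the window end —
whichever comes first.  Rows carry all hazard-model covariates: centred
age, enrolment, duration since leaving education, education level, lagged
unemployment rates, and the calendar period.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .lexis import (
    AGE_MAX,
    AGE_MIN,
    MacroSeries,
    age_group,
    assign_period,
)

PERSON_YEAR_COLUMNS = [
    "woman_id", "t", "a", "A", "E", "G", "L", "UR1", "UR10", "P", "b",
]


def derive_education_covariates(a, leaving_age):
    """Enrolment flag and duration since leaving education at age ``a``.

    A woman counts as enrolled (E = 1) up to and including the age at
    which she obtained her highest certificate; G is the number of whole
    years elapsed since that age (0 while enrolled).
    """
    a = np.asarray(a)
    leaving_age = np.asarray(leaving_age)
    E = (a <= leaving_age).astype(int)
    G = np.maximum(0, a - leaving_age).astype(int)
    if E.ndim == 0:
        return int(E), int(G)
    return E, G


def _exposure_spans(life_courses: pd.DataFrame, window: tuple[int, int]):
    """Entry/exit years and event flags per woman; drops the never-at-risk.

    Women whose first birth predates the window are already mothers at
    window start and are excluded from the nulliparous risk set.  Births
    implying an age outside 15-49 are a validation error.
    """
    start, end = window
    by = life_courses["birth_year"].to_numpy(dtype=int)
    fby = life_courses["first_birth_year"].to_numpy(dtype=float)
    has_birth = np.isfinite(fby)
    age_at_birth = fby - by
    if np.any(has_birth & ((age_at_birth < AGE_MIN) | (age_at_birth > AGE_MAX))):
        raise ValidationError("first birth at an age outside 15-49")

    entry = np.maximum(start, by + AGE_MIN)
    exit_ = np.minimum(by + AGE_MAX, end)
    exit_ = np.where(has_birth & (fby <= exit_), np.minimum(exit_, fby), exit_)
    # event counts only if the birth year itself lies inside the risk spell
    event = has_birth & (fby >= entry) & (fby <= exit_)
    at_risk = (entry <= exit_) & ~(has_birth & (fby < entry))
    return entry, exit_.astype(int), event, at_risk


def _expand_exposure(
    life_courses: pd.DataFrame, window: tuple[int, int]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Minimal expansion: woman_id, t, a, b rows (no macro covariates).

    Returns the row table and the filtered life-course frame its ``_i``
    column indexes into (women never at risk inside the window removed).
    """
    entry, exit_, event, at_risk = _exposure_spans(life_courses, window)
    lc = life_courses.loc[at_risk].reset_index(drop=True)
    entry, exit_, event = entry[at_risk], exit_[at_risk], event[at_risk]
    n_rows = exit_ - entry + 1
    idx = np.repeat(np.arange(len(lc)), n_rows)
    offsets = np.concatenate([np.arange(k) for k in n_rows]) if len(lc) else np.array([], dtype=int)
    t = entry[idx] + offsets
    a = t - lc["birth_year"].to_numpy(dtype=int)[idx]
    last_row = np.concatenate([np.arange(k) == k - 1 for k in n_rows]) if len(lc) else np.array([], dtype=bool)
    b = (last_row & event[idx]).astype(int)
    rows = pd.DataFrame(
        {
            "woman_id": lc["woman_id"].to_numpy()[idx],
            "t": t,
            "a": a,
            "b": b,
            "_i": idx,
        }
    )
    return rows, lc


def build_person_years(
    life_courses: pd.DataFrame,
    macro: MacroSeries,
    window: tuple[int, int],
    ignore_births: bool = False,
) -> pd.DataFrame:
    """Expand life courses into the person-year table with all covariates.

    ``ignore_births=True`` builds the counterfactual full-exposure risk set
    (every woman followed to 49 or the window end regardless of her
    observed birth), which forward-mode microsimulation consumes.
    """
    start, end = window
    macro.require_coverage(start, end)
    lc = life_courses
    if ignore_births:
        lc = lc.copy()
        lc["first_birth_year"] = np.nan
    rows, lc = _expand_exposure(lc, window)
    i = rows.pop("_i").to_numpy()
    a = rows["a"].to_numpy()
    t = rows["t"].to_numpy()
    leaving = lc["leaving_age"].to_numpy(dtype=int)[i]
    E, G = derive_education_covariates(a, leaving)
    rows["A"] = a - AGE_MIN
    rows["E"] = E
    rows["G"] = G
    rows["L"] = lc["level"].to_numpy(dtype=object)[i]
    rows["UR1"] = np.asarray(macro.value(t - 1), dtype=float)
    rows["UR10"] = np.asarray(macro.value(t - 10), dtype=float)
    rows["P"] = assign_period(t)
    rows["age_group"] = age_group(a)
    out = rows[PERSON_YEAR_COLUMNS + ["age_group"]]
    return out.sort_values(["woman_id", "t"], kind="stable").reset_index(drop=True)


def write_person_years(person_years: pd.DataFrame, path) -> None:
    person_years.to_csv(path, index=False, columns=PERSON_YEAR_COLUMNS)


def read_person_years(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PERSON_YEAR_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"person-year file missing columns: {sorted(missing)}")
    df["age_group"] = age_group(df["a"].to_numpy())
    return df
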