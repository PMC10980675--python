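import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import fertisim as fs

# empty-cell warnings from edge years are expected noise in tests
logging.getLogger("fertisim.indicators").setLevel(logging.ERROR)

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

WINDOW = (1960, 2010)


@pytest.fixture(scope="session")
def macro():
    """Unemployment-style series covering every lag the window needs."""
    return fs.generate_macro_series(1916, 2010, seed=11)


@pytest.fixture(scope="session")
def flat_macro():
    """Constant 4% series (degenerate macro: no cycles, no noise)."""
    return fs.generate_macro_series(1916, 2010, base=4.0, episodes=(), noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def population(macro):
    """A medium synthetic population with full Lexis coverage.

    Cohorts 1911-1995 x 60 women, first births drawn from the default
    true hazard; returns (life_courses, person_years).
    """
    cohorts = fs.generate_cohorts(1911, 1995, 60, seed=12)
    lc = fs.simulate_life_courses(cohorts, macro, fs.TrueHazardParams.default(), WINDOW, seed=13)
    py = fs.build_person_years(lc, macro, WINDOW)
    return lc, py


@pytest.fixture(scope="session")
def person_years(population):
    return population[1]


@pytest.fixture()
def three_women():
    """Hand-checkable life courses: one birth, one censored at 49, one
    right-censored by the window end."""
    return pd.DataFrame(
        {
            "woman_id": [1, 2, 3],
            "birth_year": [1960, 1950, 1990],
            "level": ["ISCED34", "ISCED01", "ISCED5A6"],
            "leaving_age": [18, 14, 23],
            "first_birth_year": [1985.0, np.nan, np.nan],
        }
    )


def constant_hazard_params(q: float) -> fs.TrueHazardParams:
    """True parameters that make the annual probability exactly ``q``
    for every woman-year (all covariate effects zero)."""
    eta = -np.inf if q == 0 else float(np.log(-np.log(1.0 - q)))
    return fs.TrueHazardParams(
        intercept=eta,
        baseline=(0.0, 0.0, 0.0),
        enrolment=0.0,
        duration=(0.0, 0.0),
        level_contrasts={lv: 0.0 for lv in fs.LEVELS[1:]},
        ur1_by_agegroup={g: 0.0 for g in fs.AGE_GROUPS},
        ur10_by_old_agegroup={g: 0.0 for g in fs.OLD_AGE_GROUPS},
    )
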