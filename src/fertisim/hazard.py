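"""Discrete-time complementary log-log hazard models of first birth.

Thirteen nested specifications (M0-M12) combine four blocks: a cubic age
baseline; educational-expansion covariates (enrolment, duration since
leaving education, level contrasts, age x level interactions); the
unemployment rate lagged one year entering through common, age-specific,
level-specific or age x level cell slopes; and the unemployment rate
lagged ten years entering for ages 30+ (recuperation of postponed
births), optionally crossed with level and/or calendar period.

Categorical main effects use reference-category contrasts (ISCED01 for
level, P1 for period, the continuous cubic for age); the unemployment
interaction blocks are cell-specific slopes with no reference cell.
"""

from __future__ import annotations

import gc
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from scipy import stats

from .exceptions import DataError, ModelSpecError, RankDeficiencyError
from .lexis import AGE_GROUPS, LEVELS, OLD_AGE_GROUPS, PERIODS

MODEL_IDS = [f"M{i}" for i in range(13)]

# ---------------------------------------------------------------------------
# Model specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """A named hazard-model specification: an ordered tuple of term blocks."""

    id: str
    blocks: tuple[str, ...]


_EDU = ("education",)
_AXL = ("age_by_level",)

_MODEL_BLOCKS: dict[str, tuple[str, ...]] = {
    "M0": ("baseline",),
    "M1": ("baseline",) + _EDU,
    "M2": ("baseline",) + _EDU + _AXL,
    "M3": ("baseline", "ur1_common"),
    "M4": ("baseline", "ur1_by_age"),
    "M5": ("baseline",) + _EDU + _AXL + ("ur1_by_age",),
    "M6": ("baseline",) + _EDU + _AXL + ("ur1_by_level",),
    "M7": ("baseline",) + _EDU + _AXL + ("ur1_by_age_level",),
    "M8": ("baseline",) + _EDU + _AXL + ("ur1_by_age", "ur10_by_oldage"),
    "M9": ("baseline",) + _EDU + _AXL + ("ur1_by_age_level", "ur10_by_oldage_level"),
    "M10": ("baseline",) + _EDU + _AXL + ("ur1_by_age", "ur10_by_oldage", "_m10_period"),
    "M11": ("baseline",) + _EDU + _AXL + ("ur1_by_age_period", "ur10_by_oldage_period"),
    "M12": ("baseline",) + _EDU + _AXL + ("ur1_by_age_level_period", "ur10_by_oldage_level_period"),
}

#: Identifiable split of the five period-interaction terms added by M10 on
#: top of M8 ("ur1_2_ur10_3", the default): UR1 x period as two contrasts
#: (P2, P3; the common UR1 slope per period is only identified relative to
#: the age-specific UR1 cells already present) plus UR10 x period as three
#: full all-age cells (not spanned by the 30+ UR10 block).  The alternative
#: "ur1_3_ur10_2" reading (three full UR1 x period cells, UR10 x period for
#: P2/P3 only) is offered for completeness but is collinear with the
#: age-specific UR1 cells and therefore fails at fit time.
M10_SPLITS = {
    "ur1_2_ur10_3": ("ur1_by_period_contrasts", "ur10_by_period_full"),
    "ur1_3_ur10_2": ("ur1_by_period_full", "ur10_by_period_contrasts"),
}


def model_spec(model_id: str, m10_split: str = "ur1_2_ur10_3") -> ModelSpec:
    """The :class:`ModelSpec` for ``model_id`` in M0..M12."""
    if model_id not in _MODEL_BLOCKS:
        raise ModelSpecError(f"unknown model id {model_id!r}; expected M0..M12")
    blocks = _MODEL_BLOCKS[model_id]
    if "_m10_period" in blocks:
        if m10_split not in M10_SPLITS:
            raise ModelSpecError(f"unknown m10_split {m10_split!r}")
        blocks = tuple(
            b for b in blocks if b != "_m10_period"
        ) + M10_SPLITS[m10_split]
    return ModelSpec(model_id, blocks)


# ---------------------------------------------------------------------------
# Design-matrix construction
# ---------------------------------------------------------------------------


def _level_dummies(py: pd.DataFrame) -> dict[str, np.ndarray]:
    L = py["L"].to_numpy(dtype=object)
    return {lv: (L == lv).astype(float) for lv in LEVELS}


def _age_dummies(py: pd.DataFrame) -> dict[str, np.ndarray]:
    g = py["age_group"].to_numpy(dtype=object)
    return {ag: (g == ag).astype(float) for ag in AGE_GROUPS}


def _period_dummies(py: pd.DataFrame) -> dict[str, np.ndarray]:
    p = py["P"].to_numpy(dtype=object)
    return {pp: (p == pp).astype(float) for pp in PERIODS}


def _block_columns(py: pd.DataFrame, block: str) -> dict[str, np.ndarray]:
    A = py["A"].to_numpy(dtype=float)
    if block == "baseline":
        return {
            "const": np.ones(len(py)),
            "A": A,
            "A2": A**2,
            "A3": A**3,
        }
    if block == "education":
        G = py["G"].to_numpy(dtype=float)
        lev = _level_dummies(py)
        cols = {
            "E": py["E"].to_numpy(dtype=float),
            "G": G,
            "G2": G**2,
        }
        cols.update({f"L[{lv}]": lev[lv] for lv in LEVELS[1:]})
        return cols
    if block == "age_by_level":
        lev = _level_dummies(py)
        cols = {}
        for lv in LEVELS[1:]:
            cols[f"A:L[{lv}]"] = A * lev[lv]
            cols[f"A2:L[{lv}]"] = A**2 * lev[lv]
        return cols

    ur1 = py["UR1"].to_numpy(dtype=float)
    ur10 = py["UR10"].to_numpy(dtype=float)
    if block == "ur1_common":
        return {"UR1": ur1}
    if block == "ur1_by_age":
        ag = _age_dummies(py)
        return {f"UR1:age[{g}]": ur1 * ag[g] for g in AGE_GROUPS}
    if block == "ur1_by_level":
        lev = _level_dummies(py)
        return {f"UR1:L[{lv}]": ur1 * lev[lv] for lv in LEVELS}
    if block == "ur1_by_age_level":
        ag, lev = _age_dummies(py), _level_dummies(py)
        return {
            f"UR1:age[{g}]:L[{lv}]": ur1 * ag[g] * lev[lv]
            for g in AGE_GROUPS
            for lv in LEVELS
        }
    if block == "ur10_by_oldage":
        ag = _age_dummies(py)
        return {f"UR10:age[{g}]": ur10 * ag[g] for g in OLD_AGE_GROUPS}
    if block == "ur10_by_oldage_level":
        ag, lev = _age_dummies(py), _level_dummies(py)
        return {
            f"UR10:age[{g}]:L[{lv}]": ur10 * ag[g] * lev[lv]
            for g in OLD_AGE_GROUPS
            for lv in LEVELS
        }
    if block == "ur1_by_period_contrasts":
        per = _period_dummies(py)
        return {f"UR1:P[{p}]": ur1 * per[p] for p in PERIODS[1:]}
    if block == "ur1_by_period_full":
        per = _period_dummies(py)
        return {f"UR1:P[{p}]": ur1 * per[p] for p in PERIODS}
    if block == "ur10_by_period_full":
        per = _period_dummies(py)
        return {f"UR10:P[{p}]": ur10 * per[p] for p in PERIODS}
    if block == "ur10_by_period_contrasts":
        per = _period_dummies(py)
        return {f"UR10:P[{p}]": ur10 * per[p] for p in PERIODS[1:]}
    if block == "ur1_by_age_period":
        ag, per = _age_dummies(py), _period_dummies(py)
        return {
            f"UR1:age[{g}]:P[{p}]": ur1 * ag[g] * per[p]
            for g in AGE_GROUPS
            for p in PERIODS
        }
    if block == "ur10_by_oldage_period":
        ag, per = _age_dummies(py), _period_dummies(py)
        return {
            f"UR10:age[{g}]:P[{p}]": ur10 * ag[g] * per[p]
            for g in OLD_AGE_GROUPS
            for p in PERIODS
        }
    if block == "ur1_by_age_level_period":
        ag, lev, per = _age_dummies(py), _level_dummies(py), _period_dummies(py)
        return {
            f"UR1:age[{g}]:L[{lv}]:P[{p}]": ur1 * ag[g] * lev[lv] * per[p]
            for g in AGE_GROUPS
            for lv in LEVELS
            for p in PERIODS
        }
    if block == "ur10_by_oldage_level_period":
        ag, lev, per = _age_dummies(py), _level_dummies(py), _period_dummies(py)
        return {
            f"UR10:age[{g}]:L[{lv}]:P[{p}]": ur10 * ag[g] * lev[lv] * per[p]
            for g in OLD_AGE_GROUPS
            for lv in LEVELS
            for p in PERIODS
        }
    raise ModelSpecError(f"unknown term block {block!r}")


def build_design(
    person_years: pd.DataFrame,
    spec: str | ModelSpec,
    m10_split: str = "ur1_2_ur10_3",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Named design matrix (including intercept) and response for ``spec``.

    The column count equals the specification's parameter count ``k``.
    """
    if isinstance(spec, str):
        spec = model_spec(spec, m10_split=m10_split)
    py = person_years
    if "age_group" not in py.columns:
        from .lexis import age_group

        py = py.copy()
        py["age_group"] = age_group(py["a"].to_numpy())
    cols: dict[str, np.ndarray] = {}
    for block in spec.blocks:
        cols.update(_block_columns(py, block))
    X = pd.DataFrame(cols, index=py.index)
    y = py["b"].to_numpy(dtype=float)
    return X, y


def model_k(model_id: str, m10_split: str = "ur1_2_ur10_3") -> int:
    """Parameter count of a specification (column count of its design)."""
    sizes = {
        "baseline": 4,
        "education": 3 + (len(LEVELS) - 1),
        "age_by_level": 2 * (len(LEVELS) - 1),
        "ur1_common": 1,
        "ur1_by_age": len(AGE_GROUPS),
        "ur1_by_level": len(LEVELS),
        "ur1_by_age_level": len(AGE_GROUPS) * len(LEVELS),
        "ur10_by_oldage": len(OLD_AGE_GROUPS),
        "ur10_by_oldage_level": len(OLD_AGE_GROUPS) * len(LEVELS),
        "ur1_by_period_contrasts": len(PERIODS) - 1,
        "ur1_by_period_full": len(PERIODS),
        "ur10_by_period_full": len(PERIODS),
        "ur10_by_period_contrasts": len(PERIODS) - 1,
        "ur1_by_age_period": len(AGE_GROUPS) * len(PERIODS),
        "ur10_by_oldage_period": len(OLD_AGE_GROUPS) * len(PERIODS),
        "ur1_by_age_level_period": len(AGE_GROUPS) * len(LEVELS) * len(PERIODS),
        "ur10_by_oldage_level_period": len(OLD_AGE_GROUPS) * len(LEVELS) * len(PERIODS),
    }
    return sum(sizes[b] for b in model_spec(model_id, m10_split).blocks)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class FitStats:
    """Bare fit statistics (deviance, k, optionally N) for LR arithmetic."""

    deviance: float
    k: int
    n: int | None = None


@dataclass
class FittedHazardModel:
    """A fitted cloglog hazard model with its fit statistics."""

    model_id: str
    params: pd.Series
    bse: pd.Series
    deviance: float
    k: int
    n: int
    aic: float
    bic: float
    converged: bool
    m10_split: str = "ur1_2_ur10_3"

    def to_frame(self) -> pd.DataFrame:
        """Per-term table: estimate, hazard ratio, standard error."""
        return pd.DataFrame(
            {
                "term": self.params.index,
                "estimate": self.params.to_numpy(),
                "exp_estimate": np.exp(self.params.to_numpy()),
                "se": self.bse.to_numpy(),
            }
        )


def _check_rank(X: pd.DataFrame) -> None:
    """Raise :class:`RankDeficiencyError` naming collinear columns."""
    arr = X.to_numpy(dtype=float)
    gram = arr.T @ arr
    # scale columns so the tolerance is unit-free
    d = np.sqrt(np.diag(gram))
    d[d == 0] = 1.0
    gram_n = gram / np.outer(d, d)
    _, r, piv = scipy.linalg.qr(gram_n, pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(gram_n.shape) * np.finfo(float).eps * (diag[0] if len(diag) else 1.0)
    rank = int((diag > max(tol, 1e-10)).sum())
    if rank < X.shape[1]:
        bad = [X.columns[j] for j in piv[rank:]]
        raise RankDeficiencyError(bad)


def fit_cloglog(
    X: pd.DataFrame,
    y: np.ndarray,
    model_id: str = "custom",
    m10_split: str = "ur1_2_ur10_3",
    start_params: np.ndarray | pd.Series | None = None,
) -> FittedHazardModel:
    """Maximise the Bernoulli likelihood under q = 1 - exp(-exp(eta)).

    Exponentiated coefficients act multiplicatively on the cumulative
    hazard.  Requires at least one event and one non-event and a
    full-column-rank design; non-convergence is flagged, not silent.
    """
    y = np.asarray(y, dtype=float)
    if y.sum() == 0:
        raise DataError("no events in the response; hazard model undefined")
    if y.sum() == len(y):
        raise DataError("no non-events in the response; hazard model undefined")
    _check_rank(X)
    model = sm.GLM(y, X, family=sm.families.Binomial(link=sm.families.links.CLogLog()))
    if isinstance(start_params, pd.Series):
        start_params = start_params.reindex(X.columns).to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = model.fit(maxiter=200, start_params=start_params)
    converged = bool(getattr(res, "converged", True))
    if not converged:
        warnings.warn(f"cloglog fit for {model_id} did not converge", stacklevel=2)
    # for a binary response the GLM deviance equals -2 log-likelihood
    # (saturated log-likelihood is zero) and is numerically safe when
    # fitted probabilities underflow to 0 or 1
    deviance = float(res.deviance)
    k, n = X.shape[1], len(y)
    aic, bic = information_criteria(deviance, k, n)
    params = np.array(res.params, dtype=float, copy=True)
    bse = np.array(res.bse, dtype=float, copy=True)
    # the result object carries O(n x k) work arrays in reference cycles;
    # reclaim them now so repeated refits stay within a flat footprint
    del res, model
    gc.collect()
    return FittedHazardModel(
        model_id=model_id,
        params=pd.Series(params, index=X.columns),
        bse=pd.Series(bse, index=X.columns),
        deviance=deviance,
        k=k,
        n=n,
        aic=aic,
        bic=bic,
        converged=converged,
        m10_split=m10_split,
    )


def fit_model(
    person_years: pd.DataFrame,
    model_id: str,
    m10_split: str = "ur1_2_ur10_3",
    start_params: np.ndarray | pd.Series | None = None,
) -> FittedHazardModel:
    """Build the design for ``model_id`` and fit it in one step."""
    X, y = build_design(person_years, model_id, m10_split=m10_split)
    return fit_cloglog(
        X, y, model_id=model_id, m10_split=m10_split, start_params=start_params
    )


# ---------------------------------------------------------------------------
# Fit statistics
# ---------------------------------------------------------------------------


def information_criteria(deviance: float, k: int, n: int) -> tuple[float, float]:
    """AIC = deviance + 2k and BIC = deviance + k ln(N)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    return deviance + 2.0 * k, deviance + k * float(np.log(n))


def lr_test(nested, full, tol: float = 1e-6) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested against a fuller specification.

    Returns (delta deviance, delta df, chi-square upper-tail p).  Both
    arguments need ``deviance`` and ``k`` attributes (fitted models or
    :class:`FitStats`).  A negative delta deviance beyond numerical
    tolerance indicates a convergence problem and triggers a warning.
    """
    ddev = float(nested.deviance - full.deviance)
    ddf = int(full.k - nested.k)
    if ddf < 0:
        raise ValueError("nested model must have fewer parameters than full")
    n0, n1 = getattr(nested, "n", None), getattr(full, "n", None)
    if n0 is not None and n1 is not None and n0 != n1:
        raise ValueError("LR test requires both fits on the same person-years")
    scale = max(1.0, abs(float(full.deviance)))
    if ddev < -tol * scale:
        warnings.warn(
            f"negative deviance difference ({ddev:.6g}): convergence suspect",
            stacklevel=2,
        )
    ddev_c = max(ddev, 0.0)
    p = 1.0 if ddf == 0 else float(stats.chi2.sf(ddev_c, ddf))
    return ddev, ddf, p


def hazard_ratio_summary(fitted: FittedHazardModel) -> pd.DataFrame:
    """Exponentiated coefficients and percent change per covariate unit."""
    est = fitted.params.to_numpy()
    hr = np.exp(est)
    return pd.DataFrame(
        {
            "term": fitted.params.index,
            "estimate": est,
            "exp_estimate": hr,
            "pct_change": (hr - 1.0) * 100.0,
            "se": fitted.bse.to_numpy(),
        }
    )


#: Genuinely nested specification pairs (the nested model's column span is
#: contained in the full model's): on any dataset the full model's deviance
#: cannot exceed the nested one's.
NESTED_PAIRS = [
    ("M0", "M1"), ("M1", "M2"), ("M0", "M3"), ("M3", "M4"), ("M4", "M5"),
    ("M2", "M5"), ("M2", "M6"), ("M5", "M7"), ("M6", "M7"), ("M7", "M9"),
    ("M5", "M8"), ("M8", "M9"), ("M8", "M10"), ("M2", "M11"), ("M4", "M11"),
    ("M11", "M12"),
]


# ---------------------------------------------------------------------------
# Text serialisation
# ---------------------------------------------------------------------------


def save_model(fitted: FittedHazardModel, path) -> None:
    """Write a fitted model as a text table with a fit-stats header."""
    with open(path, "w") as fh:
        fh.write(
            f"# model={fitted.model_id} deviance={fitted.deviance!r} "
            f"k={fitted.k} n={fitted.n} aic={fitted.aic!r} bic={fitted.bic!r} "
            f"converged={fitted.converged} m10_split={fitted.m10_split}\n"
        )
        fitted.to_frame().to_csv(fh, sep="\t", index=False)


def load_model(path) -> FittedHazardModel:
    with open(path) as fh:
        header = fh.readline()
        meta = dict(
            item.split("=", 1) for item in header.lstrip("# ").strip().split()
        )
        table = pd.read_csv(fh, sep="\t")
    params = pd.Series(table["estimate"].to_numpy(), index=table["term"])
    bse = pd.Series(table["se"].to_numpy(), index=table["term"])
    return FittedHazardModel(
        model_id=meta["model"],
        params=params,
        bse=bse,
        deviance=float(meta["deviance"]),
        k=int(meta["k"]),
        n=int(meta["n"]),
        aic=float(meta["aic"]),
        bic=float(meta["bic"]),
        converged=meta["converged"] == "True",
        m10_split=meta.get("m10_split", "ur1_2_ur10_3"),
    )
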