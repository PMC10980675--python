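"""End-to-end runs: generate -> expand -> fit -> simulate -> indicate -> concord.

A :class:`RunConfig` (readable from YAML) fixes the window, the cohort and
macro generators, the true hazard, the model ladder, the replicate count
and all seeds; :func:`run_pipeline` executes the stages, writes every
artefact as delimited text into the run directory, and returns a summary
grid with one row per model (deviance, k, AIC, BIC, and the concordance
of simulated against observed SPPR1/SMAC1 series).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import concordance as conc
from . import hazard, indicators, microsim, riskset, synthetic
from .exceptions import ConfigError, CoverageError, FertisimError, ValidationError
from .lexis import MIN_LEAVING_AGE, MacroSeries, read_macro, write_macro

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "model", "deviance", "k", "aic", "bic",
    "sppr1_abs_e", "sppr1_r", "sppr1_r_dif",
    "smac1_abs_e", "smac1_r", "smac1_r_dif",
]


@dataclass
class RunConfig:
    """Everything a reproducible run needs."""

    window: tuple[int, int] = (1960, 2010)
    cohort_start: int = 1911
    cohort_end: int = 1995
    women_per_cohort: int = 500
    expansion_slope: float = 0.02
    macro_path: str | None = None
    macro_base: float = 4.0
    macro_episodes: tuple[tuple[int, float, float], ...] = (
        (1975, 5.0, 0.75),
        (1981, 6.0, 0.75),
        (1993, 4.5, 0.70),
        (2003, 2.5, 0.65),
        (2009, 3.0, 0.70),
    )
    macro_noise_sd: float = 0.4
    life_course_path: str | None = None
    true_params: synthetic.TrueHazardParams = field(
        default_factory=synthetic.TrueHazardParams.default
    )
    models: tuple[str, ...] = ("M0", "M1", "M2", "M3", "M4", "M5")
    replicates: int = 120
    m10_split: str = "ur1_2_ur10_3"
    macro_seed: int = 11
    cohort_seed: int = 12
    event_seed: int = 13
    sim_seed: int = 14
    mode: str = "conditional"
    write_event_logs: bool = False
    output_dir: str = "run"

    def __post_init__(self):
        bad = [m for m in self.models if m not in hazard.MODEL_IDS]
        if bad:
            raise ConfigError(f"unknown model ids: {bad}")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "true_params" in raw and isinstance(raw["true_params"], dict):
            tp = raw["true_params"]
            tp.setdefault("period_deviations", {})
            tp["baseline"] = tuple(tp["baseline"])
            tp["duration"] = tuple(tp["duration"])
            raw["true_params"] = synthetic.TrueHazardParams(**tp)
        for key in ("window",):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        if "macro_episodes" in raw:
            raw["macro_episodes"] = tuple(tuple(e) for e in raw["macro_episodes"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        d = plain(dataclasses.asdict(self))
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _replicate_series(py, q, replicates, seed, mode, empty="zero"):
    """Per-replicate indicator series; fast bincount path in conditional mode."""
    if mode == "forward":
        out = []
        for log in microsim.iter_event_logs(py, q, replicates, seed, mode):
            surf = indicators.rate_surface(indicators.tabulate_event_log(log))
            out.append(indicators.indicator_series(surf, empty=empty))
        return out
    py_sorted, q_sorted = microsim._sorted_risk_set(py, q)
    cell = pd.MultiIndex.from_arrays(
        [py_sorted["a"].to_numpy(), py_sorted["t"].to_numpy()]
    )
    codes, uniques = pd.factorize(cell)
    exposure = np.bincount(codes, minlength=len(uniques)).astype(float)
    a_cell = np.asarray([u[0] for u in uniques])
    t_cell = np.asarray([u[1] for u in uniques])
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(replicates):
        u = rng.random(len(py_sorted))
        ev = np.bincount(codes, weights=(u <= q_sorted), minlength=len(uniques))
        cells = pd.DataFrame(
            {"a": a_cell, "t": t_cell, "events": ev, "exposure": exposure}
        )
        surf = indicators.rate_surface(cells)
        out.append(indicators.indicator_series(surf, empty=empty))
    return out


def simulated_indicators(
    fitted: hazard.FittedHazardModel,
    person_years: pd.DataFrame,
    replicates: int = 120,
    seed: int = 0,
    mode: str = "conditional",
) -> pd.DataFrame:
    """Replicate-mean SPPR1/SMAC1 series simulated under a fitted model."""
    q = microsim.predict_q(fitted, person_years)
    series = _replicate_series(person_years, q, replicates, seed, mode)
    return indicators.replicate_mean(series)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; write artefacts; return them in a dict.

    Deterministic given the config's seeds: rerunning the same config
    yields a byte-identical summary grid.
    """
    cfg = config
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    start, end = cfg.window

    stage = "macro"
    try:
        if cfg.macro_path:
            macro = read_macro(cfg.macro_path)
        else:
            # reach back far enough for the oldest cohort's full history
            macro_start = min(start, cfg.cohort_start + 15) - 10
            macro = synthetic.generate_macro_series(
                macro_start,
                end,
                base=cfg.macro_base,
                episodes=cfg.macro_episodes,
                noise_sd=cfg.macro_noise_sd,
                seed=cfg.macro_seed,
            )
        macro.require_coverage(start, end)
        write_macro(macro, out / "macro.csv")

        stage = "life-courses"
        if cfg.life_course_path:
            life_courses = synthetic.read_life_courses(cfg.life_course_path)
        else:
            cohorts = synthetic.generate_cohorts(
                cfg.cohort_start,
                cfg.cohort_end,
                cfg.women_per_cohort,
                expansion_slope=cfg.expansion_slope,
                seed=cfg.cohort_seed,
            )
            life_courses = synthetic.simulate_life_courses(
                cohorts, macro, cfg.true_params, cfg.window, seed=cfg.event_seed
            )
        synthetic.write_life_courses(life_courses, out / "life_courses.csv")
        logger.info("life courses: %d women, %d with a first birth",
                    len(life_courses),
                    int(life_courses["first_birth_year"].notna().sum()))

        stage = "riskset"
        py = riskset.build_person_years(life_courses, macro, cfg.window)
        logger.info("person-years: %d rows, %d events", len(py), int(py["b"].sum()))
        riskset.write_person_years(py, out / "person_years.csv")

        stage = "observed-indicators"
        obs = indicators.observed_indicators(life_courses, cfg.window)
        indicators.write_indicator_series(obs, out / "observed_indicators.csv")

        rows = []
        fits: dict[str, hazard.FittedHazardModel] = {}
        sims: dict[str, pd.DataFrame] = {}
        reports: dict[str, pd.DataFrame] = {}
        for mid in cfg.models:
            stage = f"fit {mid}"
            fitted = hazard.fit_model(py, mid, m10_split=cfg.m10_split)
            logger.info("%s: deviance=%.2f k=%d converged=%s",
                        mid, fitted.deviance, fitted.k, fitted.converged)
            fits[mid] = fitted
            hazard.save_model(fitted, out / f"model_{mid}.tsv")

            stage = f"microsim {mid}"
            q = microsim.predict_q(fitted, py)
            if cfg.write_event_logs:
                log = microsim.simulate_event_log(
                    py, q, cfg.replicates, cfg.sim_seed, cfg.mode
                )
                microsim.write_event_log(log, out / f"event_log_{mid}.csv")
            series = _replicate_series(py, q, cfg.replicates, cfg.sim_seed, cfg.mode)
            sim = indicators.replicate_mean(series)
            sims[mid] = sim
            indicators.write_indicator_series(sim, out / f"simulated_{mid}.csv")

            stage = f"concordance {mid}"
            report = conc.concordance_report(obs, sim)
            reports[mid] = report
            conc.write_report(report, out / f"concordance_{mid}.csv")
            overall = report[report["period"] == "overall"].set_index("indicator")
            rows.append(
                {
                    "model": mid,
                    "deviance": fitted.deviance,
                    "k": fitted.k,
                    "aic": fitted.aic,
                    "bic": fitted.bic,
                    "sppr1_abs_e": overall.loc["sppr1", "abs_e"],
                    "sppr1_r": overall.loc["sppr1", "r"],
                    "sppr1_r_dif": overall.loc["sppr1", "r_dif"],
                    "smac1_abs_e": overall.loc["smac1", "abs_e"],
                    "smac1_r": overall.loc["smac1", "r"],
                    "smac1_r_dif": overall.loc["smac1", "r_dif"],
                }
            )
        summary = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
        summary.to_csv(out / "summary.csv", index=False)
    except FertisimError as err:
        raise FertisimError(f"pipeline stage {stage!r} failed: {err}") from err

    return {
        "macro": macro,
        "life_courses": life_courses,
        "person_years": py,
        "observed": obs,
        "fits": fits,
        "simulated": sims,
        "concordance": reports,
        "summary": summary,
    }


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    fatal: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal

    @property
    def empty(self) -> bool:
        return not self.fatal and not self.warnings


def validate_inputs(life_course_path, macro_path, window) -> ValidationReport:
    """Check a life-course file and a macro file against a window.

    Fatal findings (coverage gaps, out-of-range births, leaving ages below
    the level minimum) are distinguished from non-fatal warnings.
    """
    report = ValidationReport()
    start, end = window
    try:
        macro = read_macro(macro_path)
        try:
            macro.require_coverage(start, end)
        except CoverageError as err:
            report.fatal.append(str(err))
    except (OSError, ValidationError) as err:
        report.fatal.append(f"macro file: {err}")
        macro = None

    try:
        lc = synthetic.read_life_courses(life_course_path)
    except (OSError, ValidationError) as err:
        report.fatal.append(f"life-course file: {err}")
        return report

    age_at_birth = lc["first_birth_year"] - lc["birth_year"]
    bad = age_at_birth.dropna()
    n_out = int(((bad < 15) | (bad > 49)).sum())
    if n_out:
        report.fatal.append(f"{n_out} first births at ages outside 15-49")
    min_age = lc["level"].map(MIN_LEAVING_AGE)
    n_young = int((lc["leaving_age"] < min_age).sum())
    if n_young:
        report.fatal.append(
            f"{n_young} leaving ages below the level-specific minimum"
        )
    n_before = int((lc["first_birth_year"] < start).sum())
    if n_before:
        report.warnings.append(
            f"{n_before} women with a first birth before {start} "
            "will be excluded from the nulliparous risk set"
        )
    n_never = int((lc["birth_year"] + 15 > end).sum())
    if n_never:
        report.warnings.append(
            f"{n_never} women never reach age 15 inside the window"
        )
    return report
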