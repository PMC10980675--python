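# Methods

## The hazard model

The unit of analysis is the woman-year. A nulliparous woman enters the
risk set in the later of the window's first year and the year she turns
15, and leaves it with her first birth, in the year she turns 49, or at
the window end. Ages are period differences (calendar year minus birth
year), as in register or census data that record only years of birth:
true ages at an event lie between `a − 1` and `a + 1`, and all rates and
indicators share the convention, so internal comparisons are exact even
though ages are coarse. No half-year correction is applied anywhere —
with period-difference ages, `a` is already the centre of the birth
parallelogram, which is why SMAC1 multiplies by `a` rather than
`a + 0.5`.

The annual probability of a first birth follows a Bernoulli GLM with the
complementary log-log link, `q = 1 − exp(−exp(η))`, so that exponentiated
coefficients act multiplicatively on the cumulative hazard and the model
is the discrete-time counterpart of a proportional-hazards model.
Fitting is delegated to statsmodels' IRLS (`GLM` with the `CLogLog`
link); the deviance of a binary-response GLM equals −2 log-likelihood
and is used directly for AIC (`deviance + 2k`), BIC (`deviance +
k·ln N`) and likelihood-ratio tests (chi-square upper tail, no
small-sample correction — person-year tables in this design are large).

### The specification ladder

Thirteen specifications M0–M12 are built from term blocks:

| block | columns |
|---|---|
| cubic age baseline (+ intercept) | 4 |
| education: E, G, G², 4 level contrasts | 7 |
| age × level: {A, A²} × 4 contrasts | 8 |
| UR1: common / 7 age cells / 5 level cells / 35 age × level cells | 1 / 7 / 5 / 35 |
| UR10 (ages 30+ only): 4 age cells / 20 age × level cells | 4 / 20 |
| period crosses of the UR cells (× 3 periods) | 21+12 or 105+60 |

Categorical main effects use reference categories (no/primary education,
period P1); the unemployment interaction blocks are cell-specific slopes
with no reference cell, which reproduces the parameter counts 4, 11, 19,
5, 11, 26, 24, 54, 30, 74, 35, 52 and 184 across the ladder. The age ×
level interaction uses linear and quadratic age only: with the cubic
included the eight columns are what the 19-parameter specification
requires.

M10 adds five period-interaction terms on top of the 30-parameter model.
Two decompositions are offered behind the `m10_split` switch. The
default (`ur1_2_ur10_3`) is the only identifiable one: UR1 × period as
two contrasts (P2, P3) — a full three-cell block would be exactly
collinear with the seven UR1 × age cells, as both sum to the UR1 column —
plus UR10 × period as three full all-age cells, which are not spanned by
the 30+-only UR10 block. The alternative (`ur1_3_ur10_2`) is retained
for completeness and fails at fit time with an error naming the
collinear columns, which the rank check (pivoted QR on the normalised
Gram matrix, tolerance `max(dim)·eps`) reports for any deficient design.

Fitted models free their IRLS work arrays eagerly: a design of several
hundred thousand rows leaves ~GB-scale temporaries in reference cycles,
and explicit collection keeps repeated refits (replicate experiments)
within a flat memory footprint.

## Microsimulation

Two modes turn a fitted model into event logs. *Conditional* mode (the
default) draws one Bernoulli event per observed person-year against q̂,
holding the observed risk set fixed; its expectation per Lexis cell is
exactly the mean of q̂ over that cell, so the direct-calculation series
(`direct_rate_surface` → life-table arithmetic) is the closed-form
oracle of the random-generator procedure, and replicate means converge
to it at the binomial rate. *Forward* mode regenerates each woman's
trajectory on the counterfactual full-exposure risk set, stopping at her
first simulated event; logs then contain no post-event exposure. Draws
use one independent uniform per person-year streamed in a fixed (woman,
year) order, so every replicate is reproducible from its seed. The
default replicate count is 120, and reported simulated series are
replicate means (with standard deviations and defined-replicate counts).

## Indicators

Decremental first-birth rates per Lexis cell (events among nulliparous
women / nulliparous exposure) feed a period life table per year: survivor
function `S(15) = 1`, `S(a+1) = S(a)(1 − b̄(a))`; `SPPR1 = 1 − S(50)`;
`SMAC1` the `S`-decrement-weighted mean age, undefined when `SPPR1 = 0`
(no division by zero — an explicit NaN marker). Cells with no exposure
are NaN in the rate surface; when a year's indicator is computed they are
treated as rate 0 with a logged warning (the full product over ages
15–49 must be evaluated), or the year can be dropped via
`empty="drop"`.

## Concordance

Mean absolute deviation, Pearson r, and Pearson r on first differences
(consecutive years only), overall and within the three recession periods.
Per-period first differences are computed inside the period, so period
rows do not share boundary years; the overall |e| is then exactly the
year-count-weighted mean of the period values. Correlations use the
sample (n−1) normalisation and return NaN under zero variance or fewer
than two usable differences. Zero-order cross-correlations between a
lagged macro series and an indicator series (optionally on first
differences) use the same conventions.

## The synthetic-data generator

The generator emulates the study design the pipeline targets, not any
particular country's series.

* **Macro series**: base level 4% plus recession episodes
  `(onset, amplitude, decay)` contributing `amplitude · decay^(t−onset)`
  from onset onward — defaults place episodes in 1975, 1981, 1993, 2003
  and 2009 with amplitudes 2.5–6 points and decays 0.65–0.75 — plus
  Gaussian noise (sd 0.4) clipped at zero. The geometric-decay shape is
  the simplest that produces multi-year recession spells.
* **Cohorts**: education levels follow a multinomial-logit trend (slope
  0.02/year on a level score) that moves the tertiary share from ~15% in
  the earliest cohorts to ~60% in the latest — a stylised educational
  expansion. Ages at leaving education are the level-specific minimum
  (14 / 16 / 18 / 21 / 23 for ISCED 0–1 / 2 / 3–4 / 5B / 5A–6,
  conventional certificate ages in a Belgian-style system) plus an
  integer jitter of 0–2 years, cohort-invariant.
* **True hazard**: enrolment, duration and level effects and the
  age-specific 1-year-lag unemployment effects default to published
  estimates of this model family (0.235; 1.190/0.989;
  0.794/0.611/0.567/0.472; 0.882 … 0.988, 1.030, 1.005, 0.792), with the
  unprinted 20–24 and 25–29 unemployment slopes interpolated
  monotonically (0.915, 0.952) and mild recuperation defaults
  (1.020/1.030/1.015/1.005) on the 10-year lag. The intercept (−4.75)
  and cubic baseline (0.573, −0.0366, 0.0007 on A, A², A³) were
  calibrated once so that simulated SPPR1 fluctuates in the empirically
  observed 0.77–0.87 band; the cubic's late upturn deliberately offsets
  part of the strong quadratic duration decline so that ages 45–49
  retain a small but estimable hazard (~10⁻³) at desk-scale sample
  sizes — real late-age first-birth hazards are lower, which only a
  population-scale risk set could inform.
* **Event draws**: by default the full pre-window history is simulated
  (back to the oldest cohort's 15th birthday, macro coverage
  permitting), so women who enter motherhood before the window start are
  excluded from the window risk set exactly as in retrospective census
  data; a window-only mode exists for designs whose cohorts all come of
  age inside the window. Cohort composition and event draws use separate
  seeds so risk sets can be held fixed across replicate event
  simulations.

What the generator does not emulate: within-level secular change in
leaving ages, school re-entry (one leaving age per woman), migration,
unobserved heterogeneity in fecundity, and any matching of the actual
Belgian unemployment or cohort series. Passing tests therefore
demonstrate the correctness and internal consistency of the estimation
and simulation machinery under a known data-generating process, not the
substantive accuracy of any particular coefficient for real populations.

## Problem sizes and numerical choices

The test suite exercises the pipeline at sizes chosen to make its
statistical checks sharp: parameter recovery refits the 26-parameter
specification on 20 replicates of ~50,000 women (~536,000 person-years),
requiring ≥95% of coefficient-replicate pairs within 3 standard errors
of truth; the microsimulation/direct-calculation equivalence uses 20,000
women in four adjacent cohorts — concentrating exposure so each
populated Lexis cell keeps at least ~700 nulliparous women, the regime
in which the 0.005-per-year Monte-Carlo band is attainable with 120
replicates — and the acceptance script runs the full ladder pipeline on
85 cohorts × 400 women. Replicate refits warm-start IRLS from the
previous replicate's estimates (the MLE is unchanged; only iteration
count drops). Deviance-based oracle checks compare against an
independent BFGS optimisation of the hand-written Bernoulli
log-likelihood.

## Known limitations

* The education level `L` is the eventual attainment also in rows before
  leaving education (the enrolment flag carries the in-school state);
  multi-state educational trajectories are out of scope.
* Conditional-mode logs keep drawing after a simulated event (the
  observed risk set is fixed); forward mode is the reading in which
  women exit at their first simulated event.
* Standard errors are model-based (no clustering); with one spell per
  woman and a correctly specified hazard this is the appropriate
  likelihood, but misspecification-robust errors are not provided.
* Very sparse interaction cells (e.g. the 184-parameter specification on
  small synthetic populations) can separate; non-convergence is flagged
  on the fitted object rather than raised.
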