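# fertisim

Discrete-time first-birth hazard models, demographic microsimulation, and
synthetic-cohort fertility indicators.

`fertisim` is built for demographers and epidemiologists who study how
macro-level fertility trends — the annual proportion of women entering
parenthood and the mean age at first birth — emerge from individual birth
hazards shaped by educational careers and economic cycles. It implements
the full micro-to-macro loop: expand life courses into a person-year risk
set on the Lexis rectangle (ages 15–50, a calendar window), fit a ladder
of complementary log-log hazard regressions, simulate event logs from the
fitted hazards, compute retrospective period indicators from observed and
simulated events, and quantify the concordance of the two time-series.

## The model

For a nulliparous woman *i* of age *a* (period difference, `t − birth
year`) in year *t*, the conditional probability *q(a)ᵗᵢ* of a first birth
follows a discrete-time hazard model with a complementary log-log link:

    −ln[1 − q̂(a)ᵗᵢ] = exp(α) · exp(F(A)) · exp(F(E) + F(G) + F(L) + F(A·L))
                      · exp(F(UR1 · …) + F(UR10 · …))

where `A = a − 15` is centred age (cubic baseline), `E` flags enrolment in
education (1 up to and including the age the highest certificate was
obtained), `G` is duration since leaving education (quadratic), `L` the
ISCED education level (reference: no/primary education), and `UR1`/`UR10`
the unemployment rate lagged 1 and 10 years — the short lag capturing
recession-induced postponement, the 10-year lag recuperation of postponed
births at ages 30+. Thirteen specifications M0–M12 (4 to 184 parameters)
combine these blocks, up to four-way unemployment × age × education ×
period interactions. Exponentiated coefficients act multiplicatively on
the cumulative hazard.

From fitted hazards, event logs are simulated by evaluating each
person-year's q̂ against a standard-uniform draw (`b = 1` iff `r ≤ q̂`;
120 replicates by default). Decremental first-birth rates b̄(a)ₜ per Lexis
cell then yield, for each year,

* **SPPR1ₜ** `= 1 − ∏ₐ₌₁₅⁴⁹ [1 − b̄(a)ₜ]` — the synthetic parity
  progression ratio to a first birth (period life-table probability of
  ever entering motherhood), and
* **SMAC1ₜ** `= Σₐ a·(Sₐ − Sₐ₊₁) / SPPR1ₜ` — the synthetic mean age at
  first birth, with `Sₐ` the period survivor function.

Observed and simulated series are compared by the mean absolute deviation
|e|, the Pearson correlation r, and the correlation of first differences
r_dif (year-to-year change), overall and within the recession periods
1960–1973, 1974–1991 and 1992–2010.

Because the population-register microdata such analyses require are
access-restricted, the package ships a first-class synthetic-data
generator: cohorts under gradual educational expansion, a cyclical
unemployment series with geometrically decaying recession episodes, and
first births drawn from a known hazard whose education and unemployment
effects default to published estimates — so every stage of the pipeline
is testable end to end against a known truth.

## Worked example

```python
import fertisim as fs

macro   = fs.generate_macro_series(1916, 2010, seed=11)
cohorts = fs.generate_cohorts(1911, 1995, 400, seed=12)
life    = fs.simulate_life_courses(cohorts, macro,
                                   fs.TrueHazardParams.default(),
                                   (1960, 2010), seed=13)
py = fs.build_person_years(life, macro, (1960, 2010))

m1, m5 = fs.fit_model(py, "M1"), fs.fit_model(py, "M5")
ddev, ddf, p = fs.lr_test(m1, m5)

obs = fs.observed_indicators(life, (1960, 2010))
sim = fs.simulated_indicators(m5, py, replicates=120, seed=14)
```

Output of the session above:

```
34000 women -> 357181 person-years, 16207 first births
M1 deviance 112153.1 (k=11), M5 deviance 111847.9 (k=26)
LR test M1 vs M5: delta deviance 305.2, df 15, p 4.66e-56
enrolment hazard ratio 0.240 (-76.0% while enrolled)
UR1 x age 15-19 hazard ratio 0.887
observed SPPR1 mean 0.827, simulated 0.827
SPPR1 |e| = 0.0152, r_dif = 0.261
SMAC1 |e| = 0.214 years
```

Reading the numbers: adding age-specific unemployment effects to the
education-only model M1 improves fit decisively (Δ−2LL = 305.2 on 15 df).
The fitted enrolment effect (hazard ratio 0.240) and the teenage
unemployment effect (0.887 per percentage point) recover the generator's
truth (0.235 and 0.882). Simulated SPPR1 tracks the observed series to
1.5 percentage points per year on average, and the simulated mean age at
first birth to 0.21 years.

A `fertisim` command exposes the same pipeline as replayable shell
stages (`simulate-data`, `build-riskset`, `fit`, `microsim`,
`indicators`, `concord`, `run-all`, `validate`), all reading and writing
delimited text.

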