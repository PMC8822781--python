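# Methods

`comosim` estimates remaining life expectancy for men aged 65+ from
(age, CCI, DCI) by combining annual GLM transition models with a
per-individual state-transition microsimulation. This note documents the
models, the default parameters and why they were chosen, the numerical
decisions, and what the synthetic-data tests do and do not demonstrate.

## State and time

The state of one man is (age in whole years, CCI, DCI, alive). CCI is a
cumulative integer ≥ 0 — it never decreases, because it accumulates
diagnosed events. DCI is real-valued on a 0.25 grid with floor −0.75 and
may rise or fall, because it is recomputed each year from the previous
year's filled prescriptions. Time advances in annual cycles; transition
probabilities always use the start-of-year state (a discrete life-table
convention). The process is Markov in the current state: duration at a
level and the path that led there carry no information (a known
limitation, see below).

## Mortality: person-year logistic with a QCS design

Each person-year contributes one Bernoulli observation of death. The
quadratic-constant spline (QCS)

    g(x; c) = (min(x, c) − c)²

is a half parabola with its extremum at the cut point c, joined C¹ to a
constant (zero) above it. It encodes two facts: a unit of comorbidity
matters most at low levels, and beyond some level additional units add
no further information. The linear predictor is

    η = β₀ + β_age·age + β_c·g(CCI; 7) + β_d·g(DCI; 14)
        + γ_c·g(age; 100)·g(CCI; 7) + γ_d·g(age; 100)·g(DCI; 14)

with fixed cut points 7 (CCI), 14 (DCI) and 100 (age). The age
interactions make the comorbidity effect attenuate as age approaches
100: ∂η/∂g(CCI) = β_c + γ_c·g(age; 100) shrinks in magnitude with age
and collapses to β_c from age 100 on. The form g was fixed as the
minimal one-parameter choice satisfying these properties; any scale or
offset is absorbed by the GLM coefficients. Sign convention: g decreases
in x, so covariates whose higher values raise mortality carry negative
weights — the test suite states monotonicity in these terms. The model
includes a free linear age main effect alongside the interactions;
whether the interaction basis alone should carry the age effect is
genuinely open, and the linear term lets the data decide.

Cut points are configuration, not estimates: the package fits only the
six coefficients (statsmodels GLM, binomial family). Degenerate input
(a single outcome level) raises a dedicated error rather than returning
a boundary fit.

## CCI change: occurrence + (1 + Poisson) size

A two-step model on categorised covariates (defaults: CCI {0, 1, 2, ≥3},
DCI {≤0, (0,1], (1,3], >3}, age {65–74, 75–84, ≥85}; all configurable,
since the original categorisation of such registries is not canonical):

1. logistic occurrence of any CCI increase during the year;
2. given an increase, size = 1 + Poisson(exp η), with two separate
   Poisson models for current CCI = 0 and CCI > 0.

The 1 + Poisson form is forced by coherence: step 1 already decides
change vs no change, so the size distribution must exclude zero. The
two-model split by CCI = 0 vs > 0 is the natural reading of "two size
models" for a cumulative index (newly morbid vs already morbid men).
Within a stratum, void design columns (e.g. the CCI dummies when
CCI = 0) and linearly dependent dummies are pruned greedily before
fitting; coefficient tables carry explicit column names so predictions
are basis-independent. If every observed change has size exactly 1 the
Poisson log-mean lies on the −∞ boundary; the fit flags this with a
RuntimeWarning and returns intercept −30 (fitted mean ≈ 1e−13), which
reproduces the data to numerical precision.

## DCI change: occurrence + direction + rounded Gamma sizes

Four steps: logistic any-change; logistic direction (increase vs
decrease) given change; and a log-link Gamma size model per direction.
Sampled sizes are rounded to the nearest 0.25 with a minimum step of
0.25, and a decrease is truncated so DCI never falls below −0.75 (at the
floor itself a drawn decrease truncates to no movement rather than being
re-weighted into the other outcomes).

Two estimation consequences follow from these semantics and are handled
exactly rather than ignored:

* **Interval-censored Gamma likelihood.** Observed steps live on the
  grid, so a recorded step v contributes P(v − 0.125 < X ≤ v + 0.125)
  (for v = 0.25, the whole interval (0, 0.375] because of the
  minimum-step clamp), and a decrease that lands on the floor
  contributes the upper tail. Mean coefficients and the shape are
  maximised jointly (scipy L-BFGS-B over (β, log k), initialised from a
  statsmodels Gamma GLM on the recorded values; standard errors from the
  numerical Hessian). A naive Gamma fit on the recorded values is biased
  by the package's own rounding and truncation — enough to break 3-SE
  parameter recovery at 200k person-years — while the interval
  likelihood recovers the generating parameters without bias.
* **Floor-row exclusion.** For person-years with current DCI = −0.75 a
  drawn decrease is indistinguishable from no change, so the occurrence
  and direction indicators are not cleanly observable there. Those rows
  are excluded from the occurrence and direction fits (and from the
  matching calibration); size fits keep them, because an observed
  increase from the floor is a clean size observation.

## Microsimulation

Per annual cycle, in order: death draw (on death the update stops and
the covariates are left untouched); CCI occurrence and, on change, size
draw; DCI occurrence, direction and size draws; age + 1. Runs continue
until death or age 105 — men alive at the 105th-birthday anniversary
count as alive there and are then terminated, so the survival curve is
forced to zero one step later.

Randomness uses three named, independent generator sub-streams per
cohort run — mortality, cci, dci — keyed by (seed, combination, stream)
through numpy `SeedSequence`. Because both comorbidity blocks read
start-of-year covariates and consume disjoint streams, performing the
DCI block before the CCI block yields bit-identical output, an exact
(not merely distributional) property that the tests assert on 1,000
individual-years. Cohort runs are vectorised over individuals; the
scalar `advance_one_year` and the vectorised path share one engine.

Life expectancy is the trapezoidal area under the survival curve on
annual knots — equivalently, half-year credit in the year of death; this
is the standard actuarial reading of "area under the curve", and the
quadrature is a documented package convention. The Monte-Carlo standard
error follows from the death-time distribution encoded by the curve
(each death in year t contributes t − 0.5 years, individuals are
independent). Default cohort size is 10,000 identical men per start
combination over the grid ages 65–90 × CCI 0–10 × DCI −0.75…13.5
(26 × 11 × 58 = 16,588 combinations); combinations use independent RNG
keys, so they can be run in any order or subset.

### Exact finite-chain oracle

With degenerate sizes (CCI increment fixed at 1, DCI step fixed at one
grid unit) the annual process is a finite Markov chain over
(age, CCI, DCI). `exact_survival_oracle` propagates the full state
distribution forward — no sampling — and returns exact survival and
state means. It shares only the probability functions with the
simulator, not the sampling path, so agreement between the two (checked
on randomized model sets within 3 binomial SEs pointwise) is a genuine
cross-validation of the engine.

## Synthetic cohorts

`generate_cohort` emulates the structure of a population-based cohort of
prostate-cancer-free Swedish men: entry ages 65–90, six exchangeable
health-care regions (uniform assignment), up to 11 years of follow-up,
annual emigration-style censoring (default 2%/year) plus administrative
censoring at the follow-up cap, evolving under a known ground-truth
model set via the same engine as the microsimulation. Entry
distributions are age-shifted so that the share of men with CCI = 0
falls from ~80% at 65 toward ~45% at 90 and the share with DCI > 0
rises from ~70% to ~85% — the qualitative gradient of such registries,
not any registry's exact marginals. Calendar time is not modelled
(calendar effects are outside the transition models anyway).

The default ground truth (`default_truth`) was chosen once to give
realistic elderly-male demography: annual mortality ≈ 1.3% at (65,
CCI 0, DCI 0) rising to ≈ 13% at 90, comorbidity effects that attenuate
with age, CCI events in roughly 6–15% of person-years, DCI changes in
roughly 35–55% with mean step sizes below one unit (Gamma shape 2).
Under these conditions 26,600 individuals yield ≈ 200,000 person-years,
the scale used for the parameter-recovery checks; smaller cohorts are
used where only structure is exercised.

What passing tests show — and don't. The generator and simulator share
transition mechanics, so round-trip recovery and validation-loop closure
demonstrate internal consistency of estimation, simulation and
validation at realistic sample sizes. They cannot demonstrate that the
GLM forms match any real registry: real data may hold duration effects,
calendar trends, frailty heterogeneity and region differences that the
synthetic world excludes by construction.

## Validation battery

* **Observed vs simulated survival** — product-limit (Kaplan–Meier)
  curves (lifelines) on annual follow-up with Greenwood pointwise SEs,
  compared with simulated curves from the observed entry states;
  reported as pointwise differences, maximum absolute difference, and
  restricted years lost (horizon minus trapezoidal area, default
  10-year horizon). Years lost plus restricted area equals the horizon
  identically, and swapping the curves negates every difference.
* **Mean CCI/DCI trajectories** — per-year means among men still under
  follow-up, by entry stratum, against the simulated panel.
* **Calibration** — equal-frequency bins (default 10) of predicted
  probability vs observed event fraction, for the death model and the
  DCI change model (with the floor-row exclusion mirrored).
* **Leave-one-region-out cross-validation** — refit the full model set
  on five regions, simulate from the held-out region's entry states,
  compare with its Kaplan–Meier curve. Per-region simulation seeds are
  derived from the content of the held-out entry states rather than the
  region label, so permuting labels permutes the reports exactly.

Self-consistency tests compare these quantities between a cohort
generated from a fitted model's own parameters and the matching
simulation. Single comparisons use 3-SE Monte-Carlo bounds; check
families that aggregate many pointwise comparisons (e.g. 6 regions × 10
time points) use Bonferroni-adjusted thresholds holding the family-wise
error rate of a single 3-SE check, since a raw pointwise bound applied
60 times rejects a correct model with double-digit probability.

## Numerical choices

* Logistic/Poisson point fits: statsmodels IRLS; non-convergence or
  perfect separation raise `EstimationError` naming the design columns.
* Gamma interval ML: L-BFGS-B on (β, log k); likelihood floored at
  1e−300 before the log; covariance from `approx_hess1`.
* Design pruning: greedy rank-increasing column selection in a fixed
  order (intercept, age, CCI, DCI dummies), so the dropped dummy of a
  saturated factor is deterministic.
* DCI values are re-snapped to the 0.25 grid after every arithmetic
  update to prevent float drift; grid membership tests use a 1e−9
  tolerance.
* Probabilities of exactly 0 or 1 arise only from the infinite
  intercepts of `constant_models` (used for closed-form checks); fitted
  models keep probabilities strictly inside (0, 1).

## Problem sizes

Default test and script scales were chosen to make every Monte-Carlo
bound sharp at desk scale: 10,000 men per simulated cohort (the default
configuration), 26,600 individuals (~200k person-years) for parameter
recovery, 15,000 individuals for the validation loop, and reduced start
grids (e.g. 3 ages × 4 CCI × 4 DCI at n = 5,000) where a full
16,588-combination life table is not needed to test the property.

## Known limitations

* Markov in the current state: no duration dependence, no memory of
  previous DCI levels — a DCI of 2.0 reached from 10 carries the same
  risk as a stable 2.0, and consecutive DCI decreases are more common in
  simulation than in real prescription data.
* Population-level estimates: the validation design supports life
  tables and guideline work, not individual-level prediction.
* Male cohorts only; the machinery is sex-agnostic but every default was
  chosen for male demography.
* Non-comorbidity mortality (accidents, violence) is absorbed into the
  baseline, which limits accuracy for the youngest, healthiest men with
  the longest horizons.
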