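# Methods

This note documents the modelling choices behind `wbvm`: what each stage
assumes, which parameters matter, what the synthetic generator does and does
not emulate, and where the design was genuinely open.

## Study design the pipeline assumes

Two consecutive annual observations of the same members: a well-being
assessment (binary risk items grouped into eight factors — Current Health
Status, Health Maintenance, Mental Health, Negative Affect, Positive
Affect, Financial Support, Financial Status, Strengths; a member is at risk
for a factor if **any** constituent item is at risk) joined with claims-
derived annual cost, enrollment months, and flags for five chronic
conditions (diabetes, COPD, asthma, CAD, heart failure).  Eligibility:
both assessments completed, age under 65 at both (claims visibility ends at
Medicare eligibility), at least six eligible enrollment months per year.
Exclusions are applied in a fixed precedence (assessments → age →
enrollment) so logged counts are reproducible; a member failing several
rules is counted under the first.  The age rule excludes members who turn
65 *between* assessments — the strictest reading consistent with the
Medicare rationale; the boundary is configurable (`age_limit`).

Observed claims-based disease flags supersede self-report; an absent claims
observation (blank in the input CSV, three-valued internally) leaves the
self-report standing.  Costs are deflated to base-year dollars by a
supplied medical-CPI factor per year rather than fetched from an external
series, so runs have no network dependency.

## Counterfactual trend: correlation input–output model

- **Correlations.**  A[i, j] is the Spearman rank correlation (midranks for
  ties) between input *i*'s baseline distribution and input *j*'s
  follow-up distribution over members.  Zero-variance inputs get zeroed
  rows/columns with a warning.  The default input roster is factor-level
  (8 factors + 5 conditions + age = 14 inputs); an item-level roster
  (47 items + 5 conditions + age = 53 inputs) is available via
  `build_roster(level="item")`.  The exact roster composition is
  config-driven because no canonical list exists.
- **ZIP trend.**  Follow-up total risk count regressed on baseline
  per-factor risk counts, condition flags, age and gender, with logit
  zero-inflation over the same covariates.  The population trend is the
  mean fitted count over the mean baseline count (ratio of means) by
  default.  The per-member mean-of-ratios statistic is available
  (`trend_statistic="mean_of_ratios"`, zero-baseline members excluded, or
  treated as their estimate under `zero_baseline_rule="estimate"`), but it
  is upward-biased whenever many members carry one or two baseline risks:
  a member predicted to regress from one risk toward the population mean
  contributes a ratio of 2 or more, and on the calibrated default
  population the statistic exceeds 1.29 even though counts fall year over
  year.  The aggregate ratio (≈0.95 on the default) is the better estimate
  of the population-level trend the final-demand vector needs.
- **Solve.**  `x = (I − αA)⁻¹ d` with the diagonal of A zeroed (no
  self-feedback).  Two final-demand vectors are supported: the
  expected-trend vector (default for valuation: trend × observed baseline
  for risk inputs, observed baseline for conditions and age) and the
  actual follow-up distribution.  Because d mixes prevalences with age in
  years, the solve runs in baseline-normalized units by default
  (`normalize=True`): d is divided elementwise by the observed baseline
  and estimates are rescaled afterwards, which keeps the rank-correlation
  matrix's unitless entries from coupling incommensurable scales.
- **Damping.**  α is resolved automatically so the spectral radius of αA
  is 0.13 (α = 1 when A is already that contracting); a near-singular
  system falls back to a logged ridge.  The 0.13 target is a calibration
  choice: on the calibrated default population it yields expected one-year
  factor risk growth of roughly 10–16 %, the range typical of
  non-intervened working-age populations, and it guarantees Neumann-series
  convergence.  Both α and the multiplier normalization
  (`growth`: m = x/obs − 1, vs raw `ratio`) are config-exposed so
  alternative readings of the method can be tested.

## Incidence models

Per-disease logistic regression on baseline non-diseased members with the
year-2 new-onset flag as response; covariates: intercept, natural-log age,
gender, the other four condition flags, the eight factor flags.  Plain
maximum likelihood with a convergence guard: complete or quasi separation
raises an error naming the covariate (no automatic penalization — rare
events such as heart-failure onset legitimately fail and are skipped with a
warning at the pipeline level).  Before fitting, the pipeline drops binary
covariates with fewer than 10 carriers or no event variation among carriers
(warned per disease); at realistic cohort sizes the rare co-morbidity flags
otherwise make the information matrix singular.

Scenario evaluation replaces the binary factor flags with scenario
prevalences in the linear predictor — the expectation of the predictor over
independent Bernoulli flags — holding each member's demographics and
co-morbidities at observed values.  This matches operating on aggregate
risk prevalences by category; an exact Bernoulli-mixture evaluation
(averaging predicted probability over all 2^k flag patterns) is available
via `mode="bernoulli"` and differs only through the nonlinearity of the
logistic, which is small at incidence-scale probabilities.

A published reference coefficient set for a diabetes-onset model of this
form ships in `wbvm.incidence.REFERENCE_DIABETES_COEFFICIENTS` for
prediction-path tests.  Note its source table prints an odds ratio of 2.89
beside the asthma beta of 0.227, which is internally inconsistent
(exp(0.227) = 1.25); this package always derives odds ratios from betas.

## Monetization

Dollar totals are carried as integer cents; display rounding is half-up to
whole dollars for totals, cents for per-person-per-year (PPPY) figures.

- **Non-diseased.**  Factor marginal cost = (mean cost of members with ≥1
  risk in the factor / mean cost of members with no risks and no disease)
  − 1, times the reference mean.  Component population: members
  non-diseased at baseline and not newly diseased.  Avoided count per
  factor = expected follow-up at-risk count (observed × (1 + m)) minus the
  observed follow-up count; negative values (dissavings) keep their sign.
  The "weighted summation" over members is under-determined in the source
  method; the default down-weights each member's share by 1/(number of
  at-risk factors) so one member's cost basis is not counted once per
  factor, with an equal-weight mode for sensitivity.  The component PPPY
  is total over the applied population (the reported-row convention); the
  per-factor detail table also reports each factor's total over the full
  cohort.
- **Incidence.**  Dollars per disease = unrounded avoided count × (mean
  baseline cost of the diseased − mean cost of the non-diseased).  The
  applied population is the rounded total avoided count; when less than
  one whole onset is avoided only the total is reported.
- **Newly diseased.**  For each disease × factor cell among new onsets,
  the percent cost difference (with-risk vs without-risk, follow-up
  costs) × the average diseased annual cost accrues to members whose
  factor risk resolved.  Cells with fewer than 5 members on either side
  (configurable) fall back to the pooled all-onset difference, logged.
- **Diseased.**  US$294.07 per engaged diseased member per year, an
  external matching-based estimate (taken as authoritative even though the
  also-published US$24.67/month × 12 = 296.04 differs slightly); the
  component PPPY is reported over the full diseased population.  Both the
  rate and a direct PPPY override are configurable.

One savings component per member, by precedence diseased > newly diseased >
non-diseased (the incidence component is population-level and never
member-assigned); overlap is an assembly error, and the grand total is the
exact cent sum of the components.

## Regression comparator

Eight cross-sectional logistic models (linear-probability mode available),
one per factor, on the remaining seven factors, age, gender and disease
burden (count of the five condition flags — the covariate is otherwise
undefined); next-year risk forecast by advancing age one year.  A
cross-sectional OLS of annual cost on demographics, burden and the
forecasted risks prices the change: per factor, (mean predicted follow-up
cost − mean baseline cost) among observed movers in the direction of the
expected prevalence change, × the prevalence change × cohort size.  Whether
baseline costs are observed or model-predicted for movers is ambiguous in
the source; the default predicts both years from the cost model
(symmetric), with an observed-baseline mode.  No interaction terms: with
five diseases × eight factors × two years they would consume 80 degrees of
freedom.

## Coarsened exact matching

Left-closed right-open bins (last bin closed) from explicit cut points, or
category groupings; out-of-range values go to the boundary bin with a
warning (strict mode errors).  Weights follow the canonical CEM
definition: treated members in matched strata weight 1; comparison members
in stratum s weight (treated_s/comparison_s) × (matched comparison total /
matched treated total); unmatched strata weight 0, making the weighted
comparison stratum distribution exactly equal to the treated distribution.
Automatic Sturges binning is provided as a non-canonical convenience when
no spec is given.  No propensity-score methods and no variance estimation.

## Synthetic generator

Defaults emulate the marginal profile of a mid-size employer cohort
(n = 6,170) observed for two years under a well-being program: mean age
44.6 (SD 10.23, truncated to 18–65 with the location solved so the
truncated mean is exact), 68.7 % female, factor at-risk prevalences from
17.1 % (Strengths) to 72.9 % (Health Maintenance) with year-2 targets set
by the observed under-program trends, condition prevalences from 0.2 %
(heart failure) to 9.5 % (asthma) with incidence rates matching observed
newly-diseased shares, enrollment months ≈ N(9.7, 4.39) clipped to 0–12,
and heavy-tailed annual costs (lognormal, σ = 1.6, 10 % point mass at
zero, location solved so the mean hits US$2,113 in year 1 and US$2,243 in
year 2 before deflation).

Construction: Gaussian copula.  Eight factor latents with compound-
symmetric cross-factor correlation 0.25; year-2 latents are an AR(1) step
(persistence 0.6); items load on their factor latent with within-factor
correlation 0.5 and are thresholded at the quantile solved (Gauss–Hermite
quadrature + root finding) so the factor-level "any item" prevalence hits
its target exactly in expectation.  Disease prevalence and incidence are
logistic in the at-risk factor count (slope 0.25 on the log-odds, intercept
solved numerically per condition), giving incidence-model recovery tests a
known truth; year-2 disease is monotone (prevalent never reverts).  Costs
multiply disease effects (1.5–4×) and at-risk factor effects (1.02–1.25×)
chosen so diseased-vs-non-diseased and at-risk-vs-reference cost ratios
are of realistic magnitude.  Self-report disease has a 15 % false-negative
rate against the (default fully observed) claims flags, exercising the
reconciliation rule.  A single master seed spawns per-stage substreams;
identical (config, seed) pairs are byte-identical.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: no claims-line/transaction structure (only the
annual aggregate), no cost persistence across years within member, no
intervention-assignment or causal structure (the "effect" is simply the
configured year-2 risk-trend targets), no item-level heterogeneity within a
factor, no seasonality or enrollment churn correlated with health.  All
joint-distribution choices beyond the stated marginals are stand-ins.

Note on the null configuration: with flat risk trends, no damping and no
engagement, the trend-driven components (non-diseased, incidence) collapse
to sampling noise, but the newly-diseased component stays positive because
risk *churn* — members resolving a risk while others acquire one — exists
even without improvement.  That component measures resolution, not net
population change.

## Problem sizes and determinism

The test suite generates its populations at n = 800–6,170 members and fits
recovery simulations at n = 5,000 (ZIP), 20,000 (cost model) and 50,000
(logistic betas); the full suite and the acceptance script each run in
well under a minute on one CPU.  All randomness flows through explicit
seeds (NumPy `SeedSequence` substreams); hypothesis property tests are
derandomized.

## Known limitations

- The input–output reading of the method is a reconstruction: the source
  describes inverting a correlation matrix and multiplying a final-demand
  vector through it without writing the system, so the open-Leontief form,
  the diagonal zeroing, the normalization and the damping target are this
  package's design choices (each config-exposed).
- Multipliers inherit sampling noise from the Spearman matrix; no
  uncertainty is propagated into the dollar totals.
- Logistic incidence models are cross-sectional one-year forecasts; no
  time-to-event structure, no multi-year projection, no out-of-sample use.
- Program ROI is out of scope: intervention costs are not modeled, and the
  diseased-member savings rate is imported, not re-derived.
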