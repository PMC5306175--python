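# wbvm — monetizing population well-being improvement

`wbvm` implements a well-being valuation pipeline for health-economics and
population-health-management research.  Given two consecutive years of
person-level data that join a well-being assessment (50+ binary risk items
aggregated into eight factors) with administrative-claims outcomes (annual
cost, enrollment, chronic-condition flags for diabetes, COPD, asthma,
coronary artery disease and heart failure), it estimates the dollar value of
a population's well-being improvement as the monetized difference between
the *expected* (non-intervened) and *actual* trends in risks and disease.

Because real assessment + claims panels are proprietary, the package ships a
first-class synthetic-data generator calibrated to the marginal profile of a
mid-size employer cohort, so the full pipeline is runnable and testable out
of the box.

## The model

**Counterfactual risk trend.**  Risks, chronic conditions and age
(collectively *inputs*) are interdependent.  The pipeline borrows the open
input–output model of regional economics: with A the matrix of cross-year
Spearman correlations between inputs (input *i* at baseline vs input *j* at
follow-up, diagonal zeroed) and *d* a final-demand vector of expected
follow-up levels, it solves

```
x = (I − αA)⁻¹ d
```

for the final-demand estimates *x* (α is a damping factor keeping the
system contracting; the solve runs in baseline-normalized units so
prevalences and age are commensurable).  The expected follow-up level in
*d* comes from a zero-inflated Poisson (ZIP) forecast of each member's
follow-up risk count on baseline covariates.  Per-input multipliers

```
m_i = x_i / observed_i − 1
```

are the expected one-year *growth* in each risk absent intervention, so the
expected follow-up at-risk count is `observed × (1 + m)`.

**Monetization.**  Four components, each member counted in at most one:

1. **Non-diseased** — expected-minus-actual at-risk counts per factor,
   valued at the factor's marginal cost (excess annual cost of at-risk
   members over members with no risks and no disease), with multi-risk
   members down-weighted by 1/(number of at-risk factors).
2. **Incidence** — per-disease logistic models (intercept, ln age, gender,
   co-morbidities, the eight factor flags) fit on baseline non-diseased
   members predict new onset; the drop in mean predicted incidence between
   the expected and actual factor-prevalence scenarios, times the
   non-diseased count, gives onsets avoided, valued at the net annual cost
   of the disease.
3. **Newly diseased** — risk resolution among members who became diseased,
   valued through within-disease percent cost differences by risk presence.
4. **Diseased** — a published matching-based estimate of US$294.07 per
   engaged diseased member per year.

A regression-only comparator (eight cross-sectional risk models with age
advanced one year, feeding a cross-sectional cost regression) reproduces the
traditional valuation approach for side-by-side comparison, and a coarsened
exact matching (CEM) module supplies weights when an external training
population must be matched.

## Worked example

```
$ wbvm value          # default calibrated synthetic population, seed 0
source_of_value  pppy_savings       sd  n_applied    total
    nondiseased        158.73   43.051       3451 547783.0
      incidence       2632.08 1498.971         19  50010.0
 newly_diseased       2170.01 4733.463        118 256061.0
       diseased         66.20  122.915        653  43228.0
Total savings: US$897,082
Total savings PPPY: US$212.48 (n=4222)
```

Reading the report: 3,451 non-diseased members saved US$158.73 per person
per year through avoided and reduced risks; 19 disease onsets were avoided
at US$2,632 each; 118 newly diseased members saved through risk resolution;
and 653 prevalent-disease members accrued the published engaged-member
savings rate.  The grand total divides by the full 4,222-member cohort for
the headline per-person-per-year value.  (Synthetic populations are noisier
and smaller than real employer cohorts after eligibility filtering, so
component magnitudes differ from published real-data studies; the structure
and audit identities are what carry over.)

Other entry points: `wbvm simulate --n 6170 --seed 1 --out panel.csv`
writes a panel (with a generating-truth JSON sidecar); `wbvm compare` runs
the valuation and the regression comparator side by side; every run accepts
`--config cfg.yaml` (see `wbvm.pipeline.RunConfig`) and writes artifacts —
correlation matrix, multipliers, incidence models, component tables, report
and manifest — when an output directory is set.

## Layout

- `wbvm.synthetic_data` — calibrated Gaussian-copula panel generator
- `wbvm.cohort_prep` — eligibility, factor aggregation, disease
  reconciliation, CPI deflation
- `wbvm.io_trend` — Spearman matrix, ZIP trend, Leontief solve, multipliers
- `wbvm.incidence` — logistic onset models and scenario deltas
- `wbvm.monetization` — the four components and report assembly
- `wbvm.regression_comparator` — the regression-only alternative
- `wbvm.cem` — coarsened exact matching utilities
- `wbvm.pipeline` / `wbvm.cli` — orchestration and the `wbvm` command

See `docs/methods.md` for modelling assumptions, calibration targets,
numerical choices and limitations.
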