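# Methods

## Scope and perspective

`carecost` estimates the annual economic cost of informal care from a
societal perspective with a bottom-up, prevalence-based design: quantities of
resources used (care time, out-of-pocket spending) and of lost paid work are
measured per survey respondent, valued at unit costs, and expanded to the
population with survey weights. The time horizon is one year, so no
discounting is applied. Intangible costs (caregiver well-being), health-care
utilisation effects, and transaction costs of care-related transfers are out
of scope; weights are consumed as given, never constructed.

Two valuation choices are crossed, giving four reported cells:

* **Care-time valuation** — *opportunity cost* (OC): an hour of care is an
  hour of forgone leisure, priced at a conservative leisure shadow price (the
  non-business travel-time-saving value); *proxy good* (PG): an hour of care
  is priced at the market wage of a professional household-care substitute.
* **Productivity-loss horizon** — *human capital* (HCA): losses run over the
  whole work year; *friction cost* (FCA): losses stop once an employer could
  replace the worker, i.e. at the friction period.

## Direct costs

Annual care-time cost per caregiver = capped weekly hours × weeks of care ×
hourly rate. The cap embodies a minimum of 6 h/day of leisure: work + care
may not exceed (24 − 6) × 7 = 126 h/week, and any surplus is subtracted from
*care* time only (work hours are taken as reported). With the leisure floor
set to 0 the cap is 168 h and capping is the identity on valid inputs.

Out-of-pocket costs are recorded as monthly brackets; we use range midpoints
(€0, 25, 75, 150, 250) and value the open-ended top bracket at its €300 lower
bound. Missing brackets are imputed as the lowest non-zero bracket (€25), the
conservative reading of "minimum value of less than €50"; a config switch
(`oop_missing_as_zero`) gives the literal-zero alternative. Months of care =
weeks × 12/52, kept continuous rather than rounded — the survey records
weeks, and rounding would introduce bracket artifacts.

## Indirect (productivity) costs

Assessed only for ages 16–75, valued at gender-specific hourly labour costs.
Three absenteeism forms plus presenteeism:

* **PTO** — prolonged cessation (asked of the currently non-employed): since
  no work hours are observed, weekly hours are imputed from an age-band ×
  gender table of national average working hours (decadal bands 16–25 …
  66–75; the table is configuration because no national table is bundled).
  Annualised over 46 work weeks (HCA) or min(46, 12) friction weeks (FCA).
* **TTO** — temporary cessation (asked of the currently employed): reported
  weekly hours × absence duration × rate. The absence duration is not
  surveyed; it is assumed to be half the weeks of care in the year (mirroring
  the median unemployment spell of half a working year). FCA caps the
  duration at 12 weeks.
* **RHW** — reduced hours: a *population-level* weekly hours gap — the
  survey-weighted mean work hours of non-caregivers who worked in the past
  year minus that of caregivers who reduced hours, floored at 0 — applied
  uniformly to every reducer. Annualisation deducts any TTO absence from the
  46 work weeks (double-counting deduction); under FCA the result is further
  capped at 12 weeks. The TTO duration used in the deduction matches the
  approach in force (HCA uses the uncapped duration, FCA the capped one) for
  internal consistency.
* **Presenteeism** — two items are converted to shares: impaired
  concentration (none 0%, a bit 25%, very much 50%) and distracted working
  days (daily 100%, weekly 20%, monthly 5%, rarely/never 0%; a 4-week,
  5-day-week month). Weekly presenteeism hours = impairment × distraction ×
  reported work hours, annualised and monetised like RHW. Missing items mean
  zero presenteeism. Only an HCA variant is defined, and the component is
  computed always but *included in totals only when a scenario enables it* —
  the items are not a standardised instrument, so the base case omits them.

FCA applies the friction cap per component (PTO annualisation weeks, TTO
duration, RHW/presenteeism effective weeks); this is the standard reading of
"losses confined to a friction period" and guarantees FCA ≤ HCA pointwise,
with equality exactly when the relevant duration fits inside the friction
period.

## Totals, netting, aggregation

Per caregiver and cell, total = direct + indirect subtotal. Under PG, the
indirect subtotal is netted: max(0, productivity costs − PG value of that
caregiver's care time), because reallocating time from market work to care
produces offsetting output of value under the proxy-good view. The floor is
applied *per caregiver* (config `net_floor`): an unfloored deduction would
drive most caregivers' net indirect cost far below zero and the population
subtotal negative, contradicting the positive net productivity losses such
analyses report; the floored reading treats each caregiver's production gain
as offsetting at most their own loss. OC cells use unadjusted indirect costs
in the base case (leisure, unlike market work, produces no goods to net
against).

National totals are Σ weightᵢ × costᵢ over all respondents (non-caregivers
contribute zero but stay in the file — the RHW gap needs them); the mean is
total / weighted caregiver count (the convention is stated because a weighted
mean of per-caregiver costs differs in the last euro). Shares are component /
cell total; gender ratios divide female by male weighted component totals.
Context metrics: FTE-equivalents = total care hours / 1836; GDP share,
per-adult contribution, and a per-worker tax equivalent (total / weighted
count of past-year workers).

## Sensitivity scenarios

Deterministic one-way re-runs of the full pipeline: (i) leisure shadow price
replaced by contingent-valuation willingness-to-pay or willingness-to-accept
values (affects OC care time only, hence the total moves linearly in the
rate); (ii) no weekly time cap; (iii) adjusted care time — annual lost
paid-work hours under the cell's approach, prorated per care week, deducted
from reported care hours (floored at 0) before OC valuation, then capped as
usual; the proration is the minimal bridge between per-week care time and
per-year lost time, and an override can force one approach's lost-hours
measure; (iv) presenteeism included. A scenario with all-base settings
reproduces the base case bit-for-bit.

## Synthetic survey generator

Because the source microdata are restricted, testing and the shipped results
use a calibrated generator. Its defaults are the study conditions: 12 348
respondents expanding to ≈ 14.2 M adults (mean weight 1151.8, lognormal,
CV 0.5, outcome-independent unless `informative_weights`); caregiver
prevalence 36%; caregivers 55% female (non-caregivers 48%); care hours = a
lognormal body with median 3 h (σ = 1.17, calibrated by simulation so the
weighted mean of *capped* hours ≈ 7.37 under the default employment mixture)
plus a 1.5% point mass at 168 h that exercises the cap; care weeks = 52 with
probability 0.574 else uniform 1–51 (mean 40.93, median 52); OOP bracket
probabilities (0.59, 0.20, 0.12, 0.05, 0.02, 0.02) with 1.2% missing;
employment ≈ 76% worked past year (none above 75), 95% of those currently
employed, work hours ≈ N(31.1, 13) for non-caregivers and N(30.4, 13) for
caregivers, with hour-reducers centred 2.15 h below the non-caregiver mean;
impact-flag rates PTO 7%, TTO 6%, RHW 10% within their eligible bases;
presenteeism item distributions (77/8/10/5% distraction, 77/21/2%
concentration, 0.3% missing). A standard-normal latent severity links care
hours (loading 0.5) and the impact flags (loading 0.35) through a Gaussian
copula, so heavier caregiving co-occurs with work impact while marginal rates
are preserved; the loadings are free parameters with no empirical anchor.

What the generator does *not* emulate: the real joint distribution of the
survey (only published marginals are targeted), item non-response patterns
beyond simple missingness, household clustering, and calibrated/raked
weights. Passing tests therefore demonstrate correctness of the costing
arithmetic and its invariants on realistic marginals, not agreement with the
restricted microdata; weighted national totals from synthetic data are
of realistic magnitude but are not estimates.

## Numerical choices and edge cases

Money is float64 euros in the configured price year; CPI adjustment is
multiplicative and exactly invertible. Clipped (not truncated) normals are
used for ages and work hours; the small mean shift is absorbed by the
calibration. Degenerate inputs: cap surplus larger than care time floors
capped hours at 0; a dataset with no hour-reducers yields RHW delta 0 with a
warning; zero caregiver weight-sum is an error; unknown brackets, missing
imputation cells, and missing work hours on a TTO record are record- or
config-level errors. Problem sizes: tests run the full pipeline at
n = 100 000 and the generator calibration checks at the same n; the shipped
costing examples use the study-scale n = 12 348.

## Known limitations

Point estimates only (no standard errors for weighted totals); no long-term
earnings losses after workforce exit; presenteeism rests on two
non-standardised items; the OOP top bracket is censored at €300/month; the
published component ratios of real FCA/HCA tables reflect microdata
heterogeneity that synthetic data cannot reproduce exactly — the stated rules
are implemented and their synthetic consequences reported instead.
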