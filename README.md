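# carecost

Societal cost-of-illness analysis of **informal care** — the unpaid help that
family and friends give to people with health problems — from respondent-level
survey microdata. The package implements a bottom-up, prevalence-based costing
pipeline of the kind used to value informal care nationally (the reference
setting is the Netherlands in 2019): each caregiver's annual cost is built
from reported quantities times unit costs, and survey expansion weights turn
the sample into national totals.

It is a library first (import `carecost`), with narrative scripts under
`examples/` and a thin `carecost` CLI (`simulate`, `cost`, `sensitivity`).

## The model

For caregiver *i* with weekly care hours *h<sub>i</sub>* (capped so that work
plus care never exceeds (24 − 6) × 7 = 126 h/week — a 6 h/day leisure floor;
any surplus is deducted from care time only), care weeks *w<sub>i</sub>*, and
survey weight *s<sub>i</sub>*:

**Direct costs**

- care time: *h<sub>i</sub><sup>cap</sup> · w<sub>i</sub> · c*, where the
  hourly shadow price *c* is either the value of forgone leisure
  (**opportunity cost** method, OC) or the market rate of a professional
  household-care substitute (**proxy good** method, PG);
- out-of-pocket: bracket midpoint per month (€0/25/75/150/250/300; missing
  imputed as the lowest non-zero bracket) × months of care
  (*w<sub>i</sub>* · 12/52).

**Indirect (productivity) costs** — ages 16–75 only, valued at
gender-specific hourly labour costs, under the **human capital** (HCA) and
**friction cost** (FCA, losses capped at a 12-week friction period)
approaches:

- **PTO** (prolonged time off, workforce exit): imputed age×gender average
  weekly work hours × 46 work weeks (HCA) or 12 friction weeks (FCA);
- **TTO** (temporary time off): reported work hours × absence duration,
  taken as half the care weeks (FCA: capped at 12);
- **RHW** (reduced hours): the weighted mean work-hours gap between
  non-caregivers and hour-reducers × work weeks net of TTO absence
  (double-counting deduction);
- **presenteeism** (HCA only, off the base case): impairment share
  (0/25/50%) × share of distracted working days (0/5/20/100%) × work hours,
  annualised like RHW.

Under the PG method the indirect subtotal is **netted**: per caregiver,
max(0, productivity costs − PG value of the care supplied), since care time
is itself productive work under that view. National totals are
Σ *s<sub>i</sub>* × cost<sub>i</sub>; means divide by the weighted caregiver
count.

Because the real survey microdata are restricted, the package ships a
calibrated synthetic generator (`GeneratorSpec`/`generate`) reproducing the
published weighted marginals (36% caregiver prevalence, capped care hours
mean ≈ 7.4/week, care weeks mean ≈ 40.9, 59% with no out-of-pocket costs,
impact-flag rates 7/6/10%), with a latent severity variable linking care
intensity to the impact flags.

## Worked example

```python
from carecost import (GeneratorSpec, generate, default_unit_costs,
                      compute_breakdowns, aggregate)

costs = default_unit_costs()            # illustrative rates; or load_unit_costs("examples/unit_costs.yaml")
df = generate(GeneratorSpec(n_respondents=12_348, seed=1))
report = aggregate(compute_breakdowns(df, costs), df)
```

Running `python examples/national_costs.py` prints:

```
OCxHCA: total €22.33bn, mean €4410/caregiver, F:M 1.06, {'care_time': '54%', 'oop': '7%', 'rhw': '4%', 'tto': '19%', 'pto': '17%'}
OCxFCA: total €16.97bn, mean €3352/caregiver, F:M 1.20, {'care_time': '71%', 'oop': '9%', 'rhw': '1%', 'tto': '13%', 'pto': '6%'}
PGxHCA: total €30.84bn, mean €6092/caregiver, F:M 1.14, {'care_time': '74%', 'oop': '5%', 'indirect_net': '22%'}
PGxFCA: total €26.18bn, mean €5172/caregiver, F:M 1.26, {'care_time': '87%', 'oop': '6%', 'indirect_net': '8%'}

care supplied: 1.50bn hours = 815,548 FTE-years
lower-bound total = 2.09% of GDP, €1193 per adult, €1715 per worker
```

Each line is one valuation cell: the survey-weighted national total, the mean
annual cost per caregiver, the female-to-male cost ratio and the component
shares. The FCA columns are lower because absenteeism losses stop at the
12-week friction period; the PG cells value care time at the higher
substitute wage but net the productivity losses against it.
`examples/sensitivity_analysis.py` re-runs the pipeline under one-way
scenarios (willingness-to-pay/-accept leisure values, no time cap, care time
net of lost work time, presenteeism included) and prints a tornado-ordered
table; `examples/simulate_survey.py` shows the generator's calibration
report.

## Microdata schema

One CSV row per respondent (caregivers **and** non-caregivers — the RHW gap
needs both), UTF-8, mandatory header, columns:
`id, weight, is_caregiver, gender (male/female), age, age_band,
care_hours_week (1–168), care_weeks_year (1–52), oop_bracket
(none/lt50/50_100/100_200/200_300/gt300/missing), employed_now,
worked_past_year, work_hours_week, stopped_work_prolonged,
stopped_work_temporary, reduced_hours, distraction_freq
(daily/weekly/monthly/rarely_never/missing), concentration_loss
(none/a_bit/very_much/missing)`. Booleans are 1/0; not-applicable cells are
empty; a skipped item on an eligible caregiver is the literal `missing`.
Unit costs come from a YAML/JSON file (see `examples/unit_costs.yaml`, whose
rates are illustrative placeholders).

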