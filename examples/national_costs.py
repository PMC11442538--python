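"""National cost of informal care on a synthetic survey.

Runs the full costing pipeline and prints, for each valuation method
(opportunity cost / proxy good) crossed with each productivity-loss approach
(human capital / friction cost): the survey-weighted national total, the mean
annual cost per caregiver, component shares and the female-to-male cost
ratio, followed by macro context (share of GDP, FTE-equivalents of the care
provided, per-adult contribution).
"""

from carecost import (
    GeneratorSpec,
    aggregate,
    compute_breakdowns,
    default_unit_costs,
    generate,
)

costs = default_unit_costs()  # illustrative rates; real analyses load YAML
df = generate(GeneratorSpec(n_respondents=12_348, seed=1))

breakdowns = compute_breakdowns(df, costs)
report = aggregate(breakdowns, df)

for (method, approach), cell in report.cells.items():
    shares = {k: f"{v:.0f}%" for k, v in cell.shares.items()}
    print(
        f"{method.upper()}x{approach.upper()}: total €{cell.total/1e9:.2f}bn, "
        f"mean €{cell.mean:.0f}/caregiver, F:M {cell.fm_ratio_total:.2f}, {shares}"
    )

ctx = report.context(costs, "oc", "fca")
print(
    f"\ncare supplied: {report.total_care_hours/1e9:.2f}bn hours "
    f"= {ctx.fte_equivalents:,.0f} FTE-years"
)
print(
    f"lower-bound total = {ctx.pct_of_gdp:.2f}% of GDP, "
    f"€{ctx.per_adult_contribution:.0f} per adult, "
    f"€{ctx.per_worker_tax_equivalent:.0f} per worker"
)
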