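"""One-way sensitivity analysis of the opportunity-cost x human-capital cell.

Re-runs the pipeline under each standard scenario -- willingness-to-pay /
willingness-to-accept leisure values, no weekly time cap, care time net of
lost paid-work time, presenteeism included -- and prints the tornado-ordered
table of totals and percent changes against the base case.  Positive changes
mean the base-case assumption is conservative for that parameter.
"""

from carecost import (
    GeneratorSpec,
    default_unit_costs,
    generate,
    run_scenario,
    scenario_table,
    standard_scenarios,
)

costs = default_unit_costs()
df = generate(GeneratorSpec(n_respondents=12_348, seed=1))

scenarios = standard_scenarios(method="oc", approach="hca")
base = run_scenario(df, costs, scenarios[0])
results = [base] + [
    run_scenario(df, costs, s, base_total=base.total) for s in scenarios[1:]
]

table = scenario_table(results)
table["total"] = (table["total"] / 1e9).round(2)
print(table.rename(columns={"total": "total_bn_eur"}).to_string(index=False))
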