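# Illustrative unit-cost configuration (2019 euros).
# The rates below are placeholders of realistic magnitude for the Dutch
# setting; substitute your own registry values for real analyses.
leisure_value: 8.02      # €/h, opportunity-cost shadow price (non-business travel-time saving)
leisure_wtp: 10.34       # €/h, contingent-valuation willingness-to-pay variant
leisure_wta: 17.15       # €/h, willingness-to-accept variant
proxy_rate: 15.14        # €/h, standard household-care hourly rate (proxy good)

labour_cost_by_gender:   # €/h of forgone paid work
  male: 39.6
  female: 33.0

imputed_workhours:       # national average weekly work hours, age band x gender
  "16_25": {male: 26.0, female: 22.0}
  "26_35": {male: 36.0, female: 28.0}
  "36_45": {male: 37.0, female: 26.0}
  "46_55": {male: 36.0, female: 25.0}
  "56_65": {male: 33.0, female: 23.0}
  "66_75": {male: 12.0, female: 8.0}

# Structural constants (these are also the built-in defaults):
work_weeks_per_year: 46
friction_weeks: 12
leisure_floor_hours_per_day: 6
fte_hours_per_year: 1836

price_year: 2019
cpi_index:
  2014: 96.4
  2018: 98.3
  2019: 100.0

macro:
  gdp: 813.0e9
  adult_population_weighted: 14222458
  mean_gross_income: 36500
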