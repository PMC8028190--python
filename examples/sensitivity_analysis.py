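"""One-way sensitivity analysis of the lifetime cost model.

Runs the default scenario set — lifelong oral DFX, transfusion volume and
frequency ranges, drug prices +/-20% — against the synthetic base case and
prints the tornado ranking of TC2 (provider cost) changes.
"""

import tdtcost as t

params = t.default_parameters()
life_table = t.make_life_table(t.LifeTableSpec())
transitions = t.make_transitions()
survey, _ = t.make_survey(t.SurveySpec(seed=7))
weight_model = t.fit_weight_model(survey)
mean_monthly = t.mean_monthly_expenditure(survey).mean_total_monthly

trace = t.run_cohort(params, life_table, transitions)
base = t.lifetime_costs(trace, weight_model, params, mean_monthly)

results = [
    t.run_scenario(params, scenario, life_table, transitions, weight_model,
                   mean_monthly, base_result=base)
    for scenario in t.default_scenarios(params)
]
report = t.tornado(results, endpoint="tc2")
print(report.round(2).to_string(index=False))
print()
print("Bars are % change of the lifetime provider cost (TC2) from base"
      "\ncase. Prescribing DFX for life is by far the largest driver (the"
      "\npublished analysis reports roughly +65%); transfusion volume and"
      "\nfrequency move the total by only a few percent.")
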