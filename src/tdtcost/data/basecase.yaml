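# Base-case inputs for the Malaysian TDT lifetime cost model, 2019 prices.
# All monetary values are MYR; the published USD column equals MYR / 4.07.
currency: MYR
myr_per_usd: 4.07
entry_age: 2
horizon_age: 58
# Drug acquisition cost is scaled by compliance (consumed rather than
# dispensed doses); set false to price the full prescribed dose.
compliance_scales_cost: true
agents:
  DFO:
    unit_price_per_g: 44.00
    dose_mg_per_kg_day: 47.4
    compliance: 0.773
    admin_monthly_cost: 393.98   # infusion pump consumables, per month
    route: subcutaneous
    dose_days_per_week: 5        # five weekly subcutaneous infusions
  DFX:
    unit_price_per_g: 149.00
    dose_mg_per_kg_day: 24.6
    compliance: 0.981
    admin_monthly_cost: 0.0
    route: oral
    dose_days_per_week: 7
  DFP:
    unit_price_per_g: 2.00
    dose_mg_per_kg_day: 75.0
    compliance: 0.903
    admin_monthly_cost: 0.0
    route: oral
    dose_days_per_week: 7
regimen_policy:
  child:
    DFX: 1.0
  adult:                         # DFO-based regimens from switch_age onwards
    DFO: 0.5
    DFO+DFP: 0.5
  switch_age: 16
monitoring:
  monthly_under10: 225.42
  monthly_10plus: 433.33
  age_cutoff: 10
transfusion:
  per_ml: 0.67                   # filtered red cells, per millilitre
  crossmatch_per_transfusion: 11.0
  equipment_per_transfusion: 4.64
  ml_per_kg: 15.0
  transfusions_per_year: 12
complications:
  # year2plus for cardiac and diabetes defaults to the year-1 figure
  # (both sources are annual ambulatory-care cost estimates).
  cardiac:            {year1: 2183.00, year2plus: 2183.00}
  diabetes:           {year1: 1315.00, year2plus: 1315.00}
  hypogonadism:       {year1: 713.88,  year2plus: 2888.42}
  hypoparathyroidism: {year1: 523.88,  year2plus: 2362.27}
  hypothyroidism:     {year1: 164.57,  year2plus: 177.40}
mortality:
  relative_risk: 3.9
  cardiac_excess_annual_prob: 0.0062
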