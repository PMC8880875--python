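schema_version: 1
cohort_size: 1000
severity_at_intake:
  asymptomatic: 0
  mild: 0
  moderate: 0
  severe: 714
  extreme: 286
severity_at_followup:
  asymptomatic: 333
  mild: 262
  moderate: 262
  severe: 119
  extreme: 24
intervention_cost:
  therapists: 9828
  screening_lab: 909
  tests_pharmacy: 800
  relative_range: 0.3
annual_medical_cost:
  mean:
    asymptomatic: 5032
    mild: 10118
    moderate: 15177
    severe: 20236
    extreme: 24283
  sd:
    asymptomatic: 712
    mild: 1431
    moderate: 2146
    severe: 2862
    extreme: 3434
mortality_relative_risk:
  mean:
    asymptomatic: 1.0
    mild: 1.74
    moderate: 2.05
    severe: 2.51
    extreme: 2.76
  sd:
    asymptomatic: 0.0
    mild: 0.7
    moderate: 0.8
    severe: 1.1
    extreme: 1.25
utilities:
  value:
    asymptomatic: 0.9
    mild: 0.83
    moderate: 0.74
    severe: 0.61
    extreme: 0.37
  relative_range: 0.1
mean_age: 41.0
age_sd: 11.9
discount_rate: 0.03
discount_rate_sd: 0.0034
horizon_years: 30
cost_offset_ramp:
- 0.0
- 0.25
- 0.5
- 0.75
- 1.0
progression_rate: 0.1
progression_rate_range:
- 0.05
- 0.15
progression_start_year: 5
life_table: null
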