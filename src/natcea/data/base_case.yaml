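# Base-case model inputs: natalizumab in pregnancy, UK healthcare perspective,
# GBP 2024 prices, originator (Tysabri) drug acquisition cost.
schedule:
  pre_conception_months: 12
  pregnancy_months: 9
  post_pregnancy_months: 12
relapse_rates:
  stop_at_conception:
    pre_conception: 0.29
    pregnancy:
    - 0.5
    - 0.6
    post_pregnancy:
    - 0.4
    - 0.9
  stop_after_first_trimester:
    pre_conception: 0.29
    pregnancy:
    - 0.2
    - 0.5
    post_pregnancy:
    - 0.3
    - 1.0
  continue_through_pregnancy:
    pre_conception: 0.21
    pregnancy: 0.2
    post_pregnancy:
    - 0.2
    - 0.6
progression:
  proportions:
    stop_at_conception: 0.21
    stop_after_first_trimester: 0.16
    continue_through_pregnancy: 0.12
  interpolation_slope: -4.58
  interpolation_intercept: 25.63
edss:
  baseline_occupancy:
  - 0.539
  - 0.356
  - 0.059
  band_utility:
  - 0.88
  - 0.75
  - 0.43
  level_costs:
  - 488.0
  - 887.0
  - 4611.0
  - 3656.0
  - 3474.0
  - 4850.0
  - 9602.0
  - 15412.0
  - 27786.0
  - 35545.0
  band_level_ranges:
  - - 0
    - 1
  - - 2
    - 3
  - - 4
    - 9
  renormalise: false
relapse_economics:
  disutility_per_relapse: 0.07
  cost_per_relapse: 1623.0
drug:
  price_variant: originator
  acquisition_cost_per_cycle: 1130.0
  administration_cost_per_cycle: 223.0
  total_drug_cycles:
    stop_at_conception: 6.0
    stop_after_first_trimester: 6.75
    continue_through_pregnancy: 8.25
settings:
  annual_discount_rate: 0.035
  wtp_threshold: 20000.0
  psa_draws: 1000
  psa_range: 0.2
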