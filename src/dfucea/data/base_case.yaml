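strategies:
  rhEGF:
    name: rhEGF
    p_closure_week: 0.0398
    p_amputation_week: 0.0164
    treatment_duration_weeks: 8
    weekly_drug_cost: 2288.61
    vials_per_week: 3
    closure_onset_week: 1
  conventional:
    name: conventional
    p_closure_week: 0.0129
    p_amputation_week: 0.0308
    treatment_duration_weeks: 260
    weekly_drug_cost: 0.0
    vials_per_week: 0
    closure_onset_week: 1
shared:
  p_death_disease_week: 0.0003
  p_death_amputation_event: 0.0029
  annual_discount_rate: 0.05
  horizon_weeks: 260
  gdp_per_capita_usd: 17696.0
  threshold_multiplier: 3.0
  cop_per_usd: 2951.35
  frac_prosthesis_over_knee: 1.0
  frac_prosthesis_under_knee: 0.15
  frac_amputations_over_knee: 0.5
  healed_disease_death: true
costs:
  rhegf_vial_with_application: 762.87
  conventional_weekly_components:
    wound_care_room: 40.36
    wound_care_procedure: 121.33
    sodium_chloride_solution: 13.54
    gauze: 135.39
    elastic_bandages: 26.91
    specialist_counselling: 5.51
  prosthesis_under_knee: 1965.22
  prosthesis_over_knee: 3049.48
  amputation_procedure: 1488.53
  rehabilitation_after_closure: 408.8
utilities:
  u_open_ulcer: 0.5319
  u_healed: 0.95
  u_post_amputation: 0.6047
ranges:
  strategies.rhEGF.p_closure_week:
    base: 0.0398
    low: 0.03184
    high: 0.047760000000000004
    distribution: uniform
  strategies.rhEGF.p_amputation_week:
    base: 0.0164
    low: 0.013120000000000001
    high: 0.01968
    distribution: uniform
  strategies.conventional.p_closure_week:
    base: 0.0129
    low: 0.010320000000000001
    high: 0.015479999999999999
    distribution: uniform
  strategies.conventional.p_amputation_week:
    base: 0.0308
    low: 0.024640000000000002
    high: 0.03696
    distribution: uniform
  shared.p_death_disease_week:
    base: 0.0003
    low: 0.00023999999999999998
    high: 0.00035999999999999997
    distribution: uniform
  shared.p_death_amputation_event:
    base: 0.0029
    low: 0.00232
    high: 0.0034799999999999996
    distribution: uniform
  costs.rhegf_vial_with_application:
    base: 762.87
    low: 610.296
    high: 915.444
    distribution: uniform
  costs.prosthesis_under_knee:
    base: 1965.22
    low: 1572.1760000000002
    high: 2358.264
    distribution: uniform
  costs.prosthesis_over_knee:
    base: 3049.48
    low: 2439.5840000000003
    high: 3659.3759999999997
    distribution: uniform
  costs.amputation_procedure:
    base: 1488.53
    low: 1190.824
    high: 1786.2359999999999
    distribution: uniform
  costs.rehabilitation_after_closure:
    base: 408.8
    low: 327.04
    high: 490.56
    distribution: uniform
  costs.conventional_weekly_components.wound_care_room:
    base: 40.36
    low: 32.288000000000004
    high: 48.431999999999995
    distribution: uniform
  costs.conventional_weekly_components.wound_care_procedure:
    base: 121.33
    low: 97.06400000000001
    high: 145.596
    distribution: uniform
  costs.conventional_weekly_components.sodium_chloride_solution:
    base: 13.54
    low: 10.832
    high: 16.247999999999998
    distribution: uniform
  costs.conventional_weekly_components.gauze:
    base: 135.39
    low: 108.312
    high: 162.468
    distribution: uniform
  costs.conventional_weekly_components.elastic_bandages:
    base: 26.91
    low: 21.528000000000002
    high: 32.292
    distribution: uniform
  costs.conventional_weekly_components.specialist_counselling:
    base: 5.51
    low: 4.408
    high: 6.611999999999999
    distribution: uniform
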