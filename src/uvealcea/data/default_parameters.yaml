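transitions:
  enucleation:
    p_post_to_lr:
    - 0.002
    - 0.001
    - 0.03
    p_post_to_met:
    - 0.047
    - 0.001
    - 0.083
    p_lr_to_met:
    - 0.074
    - 0.001
    - 0.202
  plaque_brachytherapy:
    p_post_to_lr:
    - 0.021
    - 0.001
    - 0.03
    p_post_to_met:
    - 0.029
    - 0.001
    - 0.083
    p_lr_to_met:
    - 0.045
    - 0.001
    - 0.202
  proton_beam_therapy:
    p_post_to_lr:
    - 0.009
    - 0.001
    - 0.03
    p_post_to_met:
    - 0.039
    - 0.001
    - 0.083
    p_lr_to_met:
    - 0.061
    - 0.001
    - 0.202
costs:
  enucleation:
    treatment_cost:
    - 8678
    - 6075
    - 13364
    local_recurrence_cost:
    - 8678
    - 6075
    - 13364
    eol_disease_cost:
    - 76645
    - 53652
    - 118035
    eol_other_cost:
    - 42787
    - 29952
    - 65894
  plaque_brachytherapy:
    treatment_cost:
    - 18222
    - 13376
    - 29426
    local_recurrence_cost:
    - 8678
    - 6075
    - 13364
    eol_disease_cost:
    - 76645
    - 53652
    - 118035
    eol_other_cost:
    - 42787
    - 29952
    - 65894
  proton_beam_therapy:
    treatment_cost:
    - 12438
    - 8707
    - 19155
    local_recurrence_cost:
    - 8678
    - 6075
    - 13364
    eol_disease_cost:
    - 76645
    - 53652
    - 118035
    eol_other_cost:
    - 42787
    - 29952
    - 65894
utilities:
  enucleation:
    u_post_treatment:
    - 0.71
    - 0.66
    - 0.76
    u_local_recurrence:
    - 0.52
    - 0.47
    - 0.57
    u_metastasis:
    - 0.23
    - 0.18
    - 0.28
  plaque_brachytherapy:
    u_post_treatment:
    - 0.71
    - 0.66
    - 0.76
    u_local_recurrence:
    - 0.52
    - 0.47
    - 0.57
    u_metastasis:
    - 0.23
    - 0.18
    - 0.28
  proton_beam_therapy:
    u_post_treatment:
    - 0.706
    - 0.656
    - 0.756
    u_local_recurrence:
    - 0.52
    - 0.47
    - 0.57
    u_metastasis:
    - 0.23
    - 0.18
    - 0.28
config:
  start_age: 59
  horizon: 5
  cycle_length: 1.0
  discount_rate: 0.03
  wtp_threshold: 50000.0
  cohort_size: 10000
  n_replications: 1000
  rng_seed: 0
  engine: cohort
  half_cycle: true
  cost_timing: mid_cycle
  interval_method: percentile
metadata:
  currency: 2011 USD
  plaque_brachytherapy_cost_components:
    hospital: 16444
    physician: 1778
    printed_total: 19108
  lr_to_met_relative_risk: 1.5
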