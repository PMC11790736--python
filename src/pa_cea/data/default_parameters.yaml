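screening_tests:
  value: 17920
  category: cost_initial
  units: JPY
  dsa_low: 14336.0
  dsa_high: 21504.0
  psa_family: gamma
ct_avs:
  value: 570620
  category: cost_initial
  units: JPY
  dsa_low: 456496.0
  dsa_high: 684744.0
  psa_family: gamma
hf_initial:
  value: 3463446
  category: cost_initial
  units: JPY
  dsa_low: 2770756.8000000003
  dsa_high: 4156135.1999999997
  psa_family: gamma
stroke_initial:
  value: 298855
  category: cost_initial
  units: JPY
  dsa_low: 239084.0
  dsa_high: 358626.0
  psa_family: gamma
surgery:
  value: 996710
  category: cost_initial
  units: JPY
  dsa_low: 797368.0
  dsa_high: 1196052.0
  psa_family: gamma
rfa:
  value: 677030
  category: cost_initial
  units: JPY
  dsa_low: 541624.0
  dsa_high: 812436.0
  psa_family: gamma
drug_eht:
  value: 60656
  category: cost_annual
  units: JPY_per_year
  dsa_low: 48524.8
  dsa_high: 72787.2
  psa_family: gamma
drug_success:
  value: 23276
  category: cost_annual
  units: JPY_per_year
  dsa_low: 18620.8
  dsa_high: 27931.2
  psa_family: gamma
drug_pa_unoperated:
  value: 61144
  category: cost_annual
  units: JPY_per_year
  dsa_low: 48915.200000000004
  dsa_high: 73372.8
  psa_family: gamma
drug_partial_success:
  value: 61144
  category: cost_annual
  units: JPY_per_year
  dsa_low: 48915.200000000004
  dsa_high: 73372.8
  psa_family: gamma
hf_followup:
  value: 80755
  category: cost_annual
  units: JPY_per_year
  dsa_low: 64604.0
  dsa_high: 96906.0
  psa_family: gamma
stroke_followup:
  value: 191200
  category: cost_annual
  units: JPY_per_year
  dsa_low: 152960.0
  dsa_high: 229440.0
  psa_family: gamma
u_eht:
  value: 1.0
  category: utility
  units: utility
  dsa_low: 0.92
  dsa_high: 1.0
  psa_family: fixed
u_hf:
  value: 0.9
  category: utility
  units: utility
  dsa_low: 0.8280000000000001
  dsa_high: 0.9720000000000001
  psa_family: beta
u_stroke:
  value: 0.9
  category: utility
  units: utility
  dsa_low: 0.8280000000000001
  dsa_high: 0.9720000000000001
  psa_family: beta
prev_pa:
  value: 0.1
  category: tree_probability
  units: probability_per_year
  dsa_low: 0.06999999999999999
  dsa_high: 0.13
  psa_family: beta
avs_success:
  value: 1.0
  category: tree_probability
  units: probability_per_year
  dsa_low: 0.7
  dsa_high: 1.0
  psa_family: fixed
prev_apa_savs:
  value: 0.48
  category: tree_probability
  units: probability_per_year
  dsa_low: 0.33599999999999997
  dsa_high: 0.624
  psa_family: beta
prev_apa_cavs:
  value: 0.461
  category: tree_probability
  units: probability_per_year
  dsa_low: 0.3227
  dsa_high: 0.5993
  psa_family: beta
p_rfa_given_apa:
  value: 0.085
  category: tree_probability
  units: probability_per_year
  dsa_low: 0.0595
  dsa_high: 0.11050000000000001
  psa_family: beta
surg_success_savs:
  value: 0.84
  category: tree_probability
  units: probability_per_year
  dsa_low: 0.588
  dsa_high: 1.0
  psa_family: beta
surg_success_cavs:
  value: 0.802
  category: tree_probability
  units: probability_per_year
  dsa_low: 0.5614
  dsa_high: 1.0
  psa_family: beta
rfa_success:
  value: 1.0
  category: tree_probability
  units: probability_per_year
  dsa_low: 0.7
  dsa_high: 1.0
  psa_family: fixed
drugfree_surgery:
  value: 0.44
  category: tree_probability
  units: probability_per_year
  dsa_low: 0.308
  dsa_high: 0.5720000000000001
  psa_family: beta
drugfree_rfa:
  value: 1.0
  category: tree_probability
  units: probability_per_year
  dsa_low: 0.7
  dsa_high: 1.0
  psa_family: fixed
cured_death:
  value: 0.00416
  category: transition_probability
  units: probability_per_year
  dsa_low: 0.0029119999999999997
  dsa_high: 0.005408
  psa_family: beta
cured_hf:
  value: 0.0266
  category: transition_probability
  units: probability_per_year
  dsa_low: 0.018619999999999998
  dsa_high: 0.03458
  psa_family: beta
cured_stroke:
  value: 0.0011
  category: transition_probability
  units: probability_per_year
  dsa_low: 0.00077
  dsa_high: 0.00143
  psa_family: beta
pa_death:
  value: 0.0042
  category: transition_probability
  units: probability_per_year
  dsa_low: 0.0029399999999999995
  dsa_high: 0.00546
  psa_family: beta
pa_hf:
  value: 0.0563
  category: transition_probability
  units: probability_per_year
  dsa_low: 0.03941
  dsa_high: 0.07319
  psa_family: beta
pa_stroke:
  value: 0.129
  category: transition_probability
  units: probability_per_year
  dsa_low: 0.09029999999999999
  dsa_high: 0.16770000000000002
  psa_family: beta
eht_death:
  value: 0.0042
  category: transition_probability
  units: probability_per_year
  dsa_low: 0.0029399999999999995
  dsa_high: 0.00546
  psa_family: beta
eht_hf:
  value: 0.0266
  category: transition_probability
  units: probability_per_year
  dsa_low: 0.018619999999999998
  dsa_high: 0.03458
  psa_family: beta
eht_stroke:
  value: 0.034
  category: transition_probability
  units: probability_per_year
  dsa_low: 0.0238
  dsa_high: 0.0442
  psa_family: beta
hf_death:
  value: 0.0154
  category: transition_probability
  units: probability_per_year
  dsa_low: 0.01078
  dsa_high: 0.02002
  psa_family: beta
stroke_death:
  value: 0.00505
  category: transition_probability
  units: probability_per_year
  dsa_low: 0.0035349999999999995
  dsa_high: 0.006565
  psa_family: beta
discount_rate:
  value: 0.02
  category: discount
  units: percent
  dsa_low: 0.0
  dsa_high: 0.04
  psa_family: fixed
cycles_male:
  value: 32
  category: cycles
  units: years
  dsa_low: 32
  dsa_high: 32
  psa_family: fixed
cycles_female:
  value: 38
  category: cycles
  units: years
  dsa_low: 38
  dsa_high: 38
  psa_family: fixed
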