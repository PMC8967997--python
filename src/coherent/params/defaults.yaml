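hospitalized:
  pHF:
    n: 1029
    p_inhosp_death: 0.064
    p_death_30d: 0.067
    p_death_1y: 0.258
    los_median: 8.0
    los_iqr:
    - 6.0
    - 12.0
    readmit_p30: 0.134
    readmit_p365: 0.474
    reed_p30: 0.168
    reed_p365: 0.614
    outpatient_mean: 12.6
    outpatient_sd: 11.1
    day_hospital_rate: 0.41496598639455784
    p_no_ed_hf_code: 0.13022351797862003
    ed_extra_day_p: 0.33
    cost_ed:
    - 343.2
    - 141.8
    cost_day_hospital:
    - 543.4
    - 944.9
    cost_index_hosp:
    - 3907.7
    - 6323.2
    cost_readmission:
    - 4465.1
    - 7057.2
  sHF:
    n: 1257
    p_inhosp_death: 0.109
    p_death_30d: 0.121
    p_death_1y: 0.32
    los_median: 8.0
    los_iqr:
    - 6.0
    - 12.0
    readmit_p30: 0.133
    readmit_p365: 0.436
    reed_p30: 0.156
    reed_p365: 0.564
    outpatient_mean: 11.4
    outpatient_sd: 11.7
    day_hospital_rate: 0.6459824980111376
    p_no_ed_hf_code: 0.46857597454256167
    ed_extra_day_p: 0.33
    cost_ed:
    - 343.5
    - 141.7
    cost_day_hospital:
    - 737.5
    - 1298.1
    cost_index_hosp:
    - 4656.1
    - 6532.3
    cost_readmission:
    - 4700.6
    - 7440.7
ed_home:
  pHF:
    n: 434
    p_inhosp_death: 0.0
    p_death_30d: 0.018
    p_death_1y: 0.166
    los_median: 8.0
    los_iqr:
    - 6.0
    - 12.0
    readmit_p30: 0.118
    readmit_p365: 0.509
    reed_p30: 0.242
    reed_p365: 0.739
    outpatient_mean: 12.6
    outpatient_sd: 11.1
    day_hospital_rate: 0.2
    p_no_ed_hf_code: 0.0
    ed_extra_day_p: 0.33
    cost_ed:
    - 343.2
    - 141.8
    cost_day_hospital:
    - 543.4
    - 944.9
    cost_index_hosp:
    - 3907.7
    - 6323.2
    cost_readmission:
    - 4465.1
    - 7057.2
  sHF:
    n: 363
    p_inhosp_death: 0.0
    p_death_30d: 0.033
    p_death_1y: 0.204
    los_median: 8.0
    los_iqr:
    - 6.0
    - 12.0
    readmit_p30: 0.088
    readmit_p365: 0.407
    reed_p30: 0.212
    reed_p365: 0.652
    outpatient_mean: 11.4
    outpatient_sd: 11.7
    day_hospital_rate: 0.2
    p_no_ed_hf_code: 0.0
    ed_extra_day_p: 0.33
    cost_ed:
    - 343.2
    - 141.8
    cost_day_hospital:
    - 543.4
    - 944.9
    cost_index_hosp:
    - 3907.7
    - 6323.2
    cost_readmission:
    - 4465.1
    - 7057.2
n_died_in_ed:
  pHF: 8
  sHF: 7
year: 2018
horizon: 365
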