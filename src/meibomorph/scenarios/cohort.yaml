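n_per_group:
  allergy: 252
  control: 200
sex_ratio:
  allergy: 0.607143
  control: 0.605
marginals:
  age_years:
    allergy:
    - 11.78
    - 6.77
    - 5
    - 77
    control:
    - 11.65
    - 9.0
    - 7
    - 58
  tmh_mm:
    allergy:
    - 0.26
    - 0.1
    - 0.05
    - .inf
    control:
    - 0.44
    - 0.08
    - 0.05
    - .inf
  nibut_first_s:
    allergy:
    - 8.65
    - 6.31
    - 1.0
    - .inf
    control:
    - 10.48
    - 2.58
    - 1.0
    - .inf
  nibut_avg_s:
    allergy:
    - 10.53
    - 6.26
    - 1.0
    - .inf
    control:
    - 11.56
    - 3.67
    - 1.0
    - .inf
  congestion:
    allergy:
    - 1.1
    - 0.52
    - 0.0
    - .inf
    control:
    - 0.97
    - 0.3
    - 0.0
    - .inf
  osdi:
    allergy:
    - 8.33
    - 7.6
    - 0.0
    - 100.0
    control:
    - 4.0
    - 0.5
    - 0.0
    - 100.0
  gland_count:
    allergy:
    - 24
    - 5
    - 6
    - .inf
    control:
    - 22
    - 5
    - 6
    - .inf
  dropout_ratio:
    allergy:
    - 0.35
    - 0.12
    - 0.0
    - 1.0
    control:
    - 0.33
    - 0.12
    - 0.0
    - 1.0
  avg_length_mm:
    allergy:
    - 4.48
    - 1.04
    - 0.5
    - .inf
    control:
    - 4.72
    - 0.94
    - 0.5
    - .inf
  avg_width_mm:
    allergy:
    - 0.32
    - 0.06
    - 0.05
    - .inf
    control:
    - 0.32
    - 0.06
    - 0.05
    - .inf
  avg_area_mm2:
    allergy:
    - 1.45
    - 0.55
    - 0.1
    - .inf
    control:
    - 1.55
    - 0.55
    - 0.1
    - .inf
  avg_deformation:
    allergy:
    - 1.35
    - 0.25
    - 1.0
    - .inf
    control:
    - 1.32
    - 0.25
    - 1.0
    - .inf
  central5_length_mm:
    allergy:
    - 4.94
    - 1.67
    - 0.5
    - .inf
    control:
    - 5.38
    - 1.42
    - 0.5
    - .inf
  central5_width_mm:
    allergy:
    - 0.33
    - 0.07
    - 0.05
    - .inf
    control:
    - 0.33
    - 0.07
    - 0.05
    - .inf
  central5_area_mm2:
    allergy:
    - 1.61
    - 0.64
    - 0.1
    - .inf
    control:
    - 1.79
    - 0.62
    - 0.1
    - .inf
  central5_deformation:
    allergy:
    - 1.35
    - 0.25
    - 1.0
    - .inf
    control:
    - 1.33
    - 0.25
    - 1.0
    - .inf
correlations:
- - dropout_ratio
  - sex
  - 0.19
- - dropout_ratio
  - osdi
  - -0.24
- - dropout_ratio
  - age_years
  - -0.19
- - gland_count
  - nibut_first_s
  - -0.21
- - gland_count
  - nibut_avg_s
  - -0.21
- - avg_area_mm2
  - nibut_first_s
  - 0.17
- - avg_area_mm2
  - nibut_avg_s
  - 0.17
- - congestion
  - osdi
  - 0.19
seed: 0
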