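n_electrodes: 5
freq_lo: 2.0
freq_hi: 40.0
freq_step: 0.25
param_means:
  offset: 0.8
  exponent: 1.5
  iaf: 9.5
  alpha_level: 0.6
  alpha_width: 1.2
  theta_level: 0.35
param_sds:
  offset: 0.4
  exponent: 0.3
  iaf: 0.8
  alpha_level: 0.25
  alpha_width: 0.2
  theta_level: 0.25
effect_matrix:
  age_z:
    offset: -0.5125126417411606
    exponent: -0.44431491700967507
    iaf: 0.32771373295051165
    alpha_level: 0.36823390272142076
    alpha_width: 0.0547287502515934
    theta_level: -0.5627338236607609
  gender:
    offset: -0.41237429188912555
    exponent: -0.35768434544945527
    iaf: 0.25956815007702155
    alpha_level: -0.6566314388606593
    alpha_width: 0.6646291599580165
    theta_level: 0.6796654347842385
  fa_z:
    offset: 0.0
    exponent: 0.0
    iaf: 0.0
    alpha_level: 0.12780685017418933
    alpha_width: 0.0
    theta_level: 0.0
  score_z:
    offset: 0.0
    exponent: 0.0
    iaf: 0.0
    alpha_level: 0.06338972858057501
    alpha_width: 0.0
    theta_level: 0.0
residual_corr:
- - 1.0
  - 0.65
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.65
  - 1.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 1.0
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.0
  - 1.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 1.0
  - 0.0
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 1.0
noise_sd: 0.03
artifact_rate: 0.0
theta_center: 4.0
theta_width: 1.0
age_range:
- 5.0
- 22.0
age_mean: 10.8
age_sd: 3.4
female_fraction: 0.357
fa_age_corr: 0.45
fa_lr_corr: 0.9
score_age_corr: 0.0
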