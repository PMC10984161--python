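# Six-cell judo cohort calibration: published group means and SDs for
# 16 athletes per sex x weight cell (VM cpm, axis shares %, peak contest
# HR, post-contest blood lactate, Borg RPE, age).
# Axis order everywhere: vertical, mediolateral, anteroposterior.
groups:
  - sex: male
    weight_class: light
    n_athletes: 16
    vm_mean: 9075.5
    vm_sd: 915.4
    axis_share_means: [29.3, 31.1, 39.6]
    axis_share_sds: [4.3, 3.5, 2.2]
    hr_mean: 170.0
    hr_sd: 9.0
    bla_mean: 11.8
    bla_sd: 3.1
    rpe_mean: 15.9
    rpe_sd: 2.1
    age_mean: 22.0
    age_sd: 3.0
  - sex: male
    weight_class: middle
    n_athletes: 16
    vm_mean: 8970.3
    vm_sd: 791.3
    axis_share_means: [30.2, 32.1, 37.7]
    axis_share_sds: [1.7, 1.0, 2.1]
    hr_mean: 173.0
    hr_sd: 14.0
    bla_mean: 14.3
    bla_sd: 4.1
    rpe_mean: 16.7
    rpe_sd: 1.8
    age_mean: 26.0
    age_sd: 6.0
  - sex: male
    weight_class: heavy
    n_athletes: 16
    vm_mean: 7519.6
    vm_sd: 478.6
    axis_share_means: [30.8, 33.7, 35.5]
    axis_share_sds: [2.4, 2.1, 1.2]
    hr_mean: 177.0
    hr_sd: 14.0
    bla_mean: 12.4
    bla_sd: 2.5
    rpe_mean: 17.1
    rpe_sd: 1.4
    age_mean: 24.0
    age_sd: 4.0
  - sex: female
    weight_class: light
    n_athletes: 16
    vm_mean: 7908.6
    vm_sd: 354.7
    axis_share_means: [30.5, 32.6, 36.9]
    axis_share_sds: [2.3, 1.4, 1.8]
    hr_mean: 177.0
    hr_sd: 13.0
    bla_mean: 8.9
    bla_sd: 1.8
    rpe_mean: 16.6
    rpe_sd: 1.9
    age_mean: 22.0
    age_sd: 2.0
  - sex: female
    weight_class: middle
    n_athletes: 16
    vm_mean: 7894.7
    vm_sd: 497.7
    axis_share_means: [31.4, 33.7, 34.9]
    axis_share_sds: [2.5, 1.7, 1.7]
    hr_mean: 180.0
    hr_sd: 12.0
    bla_mean: 10.6
    bla_sd: 3.1
    rpe_mean: 16.7
    rpe_sd: 2.5
    age_mean: 22.0
    age_sd: 3.0
  - sex: female
    weight_class: heavy
    n_athletes: 16
    vm_mean: 7240.3
    vm_sd: 411.7
    axis_share_means: [31.5, 33.2, 35.3]
    axis_share_sds: [2.5, 1.6, 3.1]
    hr_mean: 182.0
    hr_sd: 5.0
    bla_mean: 10.2
    bla_sd: 1.6
    rpe_mean: 17.8
    rpe_sd: 1.5
    age_mean: 23.0
    age_sd: 2.0
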