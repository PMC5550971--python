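# Default calibration of the synthetic cohort generator.
#
# Group marginals are the published cohort statistics (mean, SD) of the
# case-control study the generator emulates: 27 healthy controls and 11
# acute-MI patients.  Stresses in kPa, pressures mmHg, volumes ml,
# normalized tensions kPa/mmHg, strains dimensionless fractions.
# The inter-feature correlation structure is an assumption of this
# generator (the study's full correlation tables are not published) and
# may be overridden; see docs/methods.md.
n_healthy: 27
n_mi: 11
groups:
  healthy:
    edp: 8.0
    features:
      T_req: [157.0, 25.0]
      T_a: [65.1, 9.0]
      SBP: [144.6, 31.2]
      EDV: [127.0, 21.0]
      C_s: [0.42, 0.04]
      T_a_norm: [0.45, 0.06]
      sigma_f: [50.6, 9.0]
      sigma_f_norm: [0.35, 0.05]
    extra:
      age: [44.5, 15.4]
      DBP: [83.0, 15.0]
      LVEF: [57.0, 5.0]
      GLS: [-21.4, 4.1]
      CS: [-0.18, 0.02]
  mi:
    edp: 16.0
    features:
      T_req: [156.0, 27.0]
      T_a: [65.2, 10.0]
      SBP: [118.6, 16.4]
      EDV: [145.5, 28.0]
      C_s: [0.44, 0.13]
      T_a_norm: [0.55, 0.07]
      sigma_f: [55.7, 11.0]
      sigma_f_norm: [0.47, 0.09]
    extra:
      age: [57.2, 10.0]
      DBP: [73.0, 14.0]
      LVEF: [43.0, 6.0]
      GLS: [-11.5, 3.9]
      CS: [-0.16, 0.01]
      infarct_size: [39.0, 6.0]
      MVO: [10.6, 5.0]
# Within-group feature correlations: listed pairs, all others take
# `default`.  The matrix is checked for positive semi-definiteness.
correlations:
  default: 0.2
  pairs:
    - [T_a, T_a_norm, 0.7]
    - [T_a_norm, SBP, -0.4]
    - [C_s, T_a, 0.5]
    - [T_req, C_s, -0.4]
    - [sigma_f, T_a, 0.5]
    - [sigma_f_norm, sigma_f, 0.4]
    - [sigma_f_norm, T_a_norm, 0.3]
# Six-month surrogate outcomes (MI group): population correlation targets.
outcomes:
  dLVEF6:
    mean: 5.0
    sd: 6.0
    corr_T_req: -0.79
    corr_C_s: 0.70
  GLS6:
    mean: -14.0
    sd: 4.0
    corr_GLS: 0.73
remote_segments:
  mean: 13.0
  sd: 3.0
  min: 6
  max: 24
truncation_sd: 4.0
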