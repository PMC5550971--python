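# Cohort-average Holzapfel-Ogden passive parameters, remote (functional)
# myocardium of MI subjects.  a-type coefficients in kPa, b-type dimensionless.
a: 0.09
b: 4.05
a_f: 6.8
b_f: 5.53
a_s: 1.5
b_s: 1.93
a_fs: 0.16
b_fs: 4.22
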