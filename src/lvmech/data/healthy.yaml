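# Cohort-average Holzapfel-Ogden passive parameters, healthy controls.
# a-type coefficients in kPa, b-type dimensionless.
a: 0.18
b: 2.6
a_f: 3.34
b_f: 2.73
a_s: 0.69
b_s: 1.11
a_fs: 0.31
b_fs: 2.58
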