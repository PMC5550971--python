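# Default constants of the active tension / myofilament kinetics model.
# Rates in 1/ms, times in ms, T_req in kPa.  See lvmech.activation for the
# meaning of each constant; these are model inputs, not fitted results.
T_req: 157.0
beta_0: 4.9
alpha_fv: 0.5
A: [1.5, 1.0, 0.5]
alpha_q: [0.03, 0.13, 0.625]
r_on: 0.08
r_off: 0.001
beta_len: 0.5
z_floor: 0.05
ca_tau: 60.0
ca_amp: 1.0
t_end_systole: 325.0
dt: 0.5
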