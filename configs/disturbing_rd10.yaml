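# single restriction pulse of severity r_d=10 after steady state
n_o: 100
p_c_oo: 0.1
a_over_b: 100
p_m: 0.01
r_d: 10
pulse_phase: 100
n_phases: 1500
n_reps: 50
seed: 0
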