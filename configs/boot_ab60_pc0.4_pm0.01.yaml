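# self-boot demonstration: n=100 society from a single self-supporting seed
n_o: 100
p_c_oo: 0.4
a_over_b: 60
p_m: 0.01
n_phases: 2500
n_reps: 50
seed: 0
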