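# intact invading society competing through the shared environment
n_o: 100
p_c_oo: 0.1
n_i: 100
p_c_ii: 0.125
a_over_b: 100
p_m: 0.01
n_phases: 200
n_reps: 50
seed: 0
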