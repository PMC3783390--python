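# parasitic derived society, combination 3: self-supportable parasite
n_o: 100
p_c_oo: 0.1
n_d: 200
p_c_od: 0.2
p_c_dd: 0.05
a_over_b: 100
p_m: 0.01
n_phases: 3000
n_reps: 50
seed: 0
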