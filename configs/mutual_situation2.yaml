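# mutually supporting derived society, strong coupling
# (probabilities above 1 are capped to 1 with a warning on load)
n_o: 100
p_c_oo: 0.1
n_d: 100
p_c_od: 1.5
p_c_do: 1.5
p_c_dd: 1.5
a_over_b: 100
p_m: 0.01
n_phases: 2000
n_reps: 50
seed: 0
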