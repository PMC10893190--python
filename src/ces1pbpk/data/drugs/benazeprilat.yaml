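schema: ces1pbpk-drug-v1
name: benazeprilat
is_metabolite: true
parent: benazepril
logp: 0.56
pka: 1.97
binding_protein: albumin
rb: 1.0
fu_b: 0.05
k_lp: 0.093
k_gp: 0.088
k_kp: 0.101
v_sys_l: 1.204
k12_per_min: 0.0438
k21_per_min: 0.00837
clint_k_ml_min: 447.9
pathways: []
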