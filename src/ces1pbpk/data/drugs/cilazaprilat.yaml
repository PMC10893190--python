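schema: ces1pbpk-drug-v1
name: cilazaprilat
is_metabolite: true
parent: cilazapril
logp: -0.48
pka: 3.17
binding_protein: albumin
rb: 1.0
fu_b: 0.76
k_lp: 1.28
k_gp: 1.22
k_kp: 1.42
v_sys_l: 10.3517
k12_per_min: 0.00084
k21_per_min: 0.008
clint_k_ml_min: 75.48
pathways: []
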