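schema: ces1pbpk-drug-v1
name: perindoprilat
is_metabolite: true
parent: perindopril
logp: -0.08
pka: 3.08
binding_protein: albumin
rb: 1.0
fu_b: 0.85
k_lp: 1.45
k_gp: 1.38
k_kp: 1.61
v_sys_l: 53.44
k12_per_min: 0.271
k21_per_min: 0.0996
clint_k_ml_min: 231.78
pathways: []
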