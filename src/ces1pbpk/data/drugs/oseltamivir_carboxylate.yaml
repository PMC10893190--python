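schema: ces1pbpk-drug-v1
name: oseltamivir_carboxylate
is_metabolite: true
parent: oseltamivir
logp: -1.3
pka: 4.19
binding_protein: albumin
rb: 1.0
fu_b: 0.97
k_lp: 1.71
k_gp: 1.89
k_kp: 1.91
v_sys_l: 160.729
clint_k_ml_min: 438.5
pathways: []
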