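schema: ces1pbpk-drug-v1
name: enalaprilat
is_metabolite: true
parent: enalapril
logp: -0.74
pka: 2.03
binding_protein: albumin
rb: 0.73
fu_b: 0.68
k_lp: 1.12
k_gp: 1.04
k_kp: 1.25
v_sys_l: 46.1
k12_per_min: 0.001
k21_per_min: 0.0009
clint_k_ml_min: 186.4
pathways: []
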