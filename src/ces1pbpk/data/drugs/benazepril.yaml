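schema: ces1pbpk-drug-v1
name: benazepril
is_metabolite: false
logp: 1.11
pka: 4.74
binding_protein: albumin
rb: 1.0
fu_b: 0.03
k_lp: 0.087
k_gp: 0.122
k_kp: 0.088
cl_b_ml_min: 385.8
v_sys_l: 4.8
k12_per_min: 0.0215
k21_per_min: 0.0238
peff_1e-4_cm_s: 1.21
clint_k_ml_min: 8391.6
f: 0.35
pathways:
  - enzyme: CES1
    clint_ml_min: 6696
    produces: benazeprilat
metabolite: benazeprilat
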