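schema: ces1pbpk-drug-v1
name: enalapril
is_metabolite: false
logp: 0.59
pka: 5.20
binding_protein: albumin
rb: 0.74
fu_b: 0.74
k_lp: 1.66
k_gp: 2.29
k_kp: 1.79
v_sys_l: 40
peff_1e-4_cm_s: 1.60
clint_k_ml_min: 624.6
pathways:
  - enzyme: CES1
    clint_ml_min: 784
    produces: enalaprilat
metabolite: enalaprilat
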