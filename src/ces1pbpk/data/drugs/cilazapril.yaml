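schema: ces1pbpk-drug-v1
name: cilazapril
is_metabolite: false
logp: 0.55
pka: 3.3
binding_protein: albumin
rb: 1.0
fu_b: 0.7
k_lp: 1.32
k_gp: 1.31
k_kp: 1.43
cl_b_ml_min: 205
v_sys_l: 18.23
k12_per_min: 0.00325
k21_per_min: 0.00155
ka_per_min: 0.099
clint_k_ml_min: 118.095
pathways:
  - enzyme: CES1
    clint_ml_min: 199.7
    produces: cilazaprilat
metabolite: cilazaprilat
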