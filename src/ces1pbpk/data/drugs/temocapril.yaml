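schema: ces1pbpk-drug-v1
name: temocapril
is_metabolite: false
logp: 2.102
pka: 2.8
binding_protein: albumin
rb: 1.0
fu_b: 0.3
k_lp: 2.82
k_gp: 3.17
k_kp: 2.47
v_sys_l: 15.398
ka_per_min: 0.065
clint_k_ml_min: 110.2
f: 0.65
pathways:
  - enzyme: CES1
    clint_ml_min: 5359.7
    produces: temocaprilat
metabolite: temocaprilat
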