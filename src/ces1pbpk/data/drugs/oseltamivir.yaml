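schema: ces1pbpk-drug-v1
name: oseltamivir
is_metabolite: false
logp: 0.36
pka: 7.7
binding_protein: albumin
rb: 1.0
fu_b: 0.58
k_lp: 1.19
k_gp: 1.12
k_kp: 1.29
v_sys_l: 61.289
ka_per_min: 0.061
clint_k_ml_min: 1357.95
pathways:
  - enzyme: CES1
    clint_ml_min: 20255.4
    produces: oseltamivir_carboxylate
metabolite: oseltamivir_carboxylate
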