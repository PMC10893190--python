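schema: ces1pbpk-drug-v1
name: pethidine
is_metabolite: false
logp: 2.35
pka: 8.7
# Pethidine binds mainly to alpha1-acid glycoprotein.
binding_protein: AGP
rb: 0.87
fu_b: 0.48
k_lp: 14.82
k_gp: 4.18
k_kp: 12.02
v_sys_l: 328.676
k12_per_min: 0.002224
k21_per_min: 0.0003697
ka_per_min: 0.117
clint_k_ml_min: 58.78
mw_g_mol: 247.33
pathways:
  # Saturable hydrolysis to pethidinic acid (untracked, inactive).
  - enzyme: CES1
    vmax_nmol_min_mg: 1.56
    km_umol_l: 261
  # Saturable N-demethylation to norpethidine (untracked).
  - enzyme: CYP2B6
    vmax_nmol_min_mg: 5.382
    km_umol_l: 356
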