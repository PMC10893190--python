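schema: ces1pbpk-drug-v1
name: perindopril
is_metabolite: false
logp: -1.31
pka: 3.2
binding_protein: albumin
rb: 1.0
fu_b: 0.4
k_lp: 0.665
k_gp: 0.633
k_kp: 0.742
v_sys_l: 13.119
k12_per_min: 0.0028
k21_per_min: 0.0024
peff_1e-4_cm_s: 1.34
clint_k_ml_min: 130.2
f: 0.66
pathways:
  - enzyme: CES1
    clint_ml_min: 1011.15
    produces: perindoprilat
  # Glucuronidation to perindopril glucuronide (untracked); scaled in
  # cirrhosis by the fixed metoprolol-derived factor 0.62.
  - enzyme: UGT
    clint_ml_min: 156.47
metabolite: perindoprilat
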