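schema: ces1pbpk-drug-v1
name: remimazolam
is_metabolite: false
logp: 3.68
pka: 5.99
binding_protein: albumin
rb: 1.0
fu_b: 0.08
k_lp: 36.34
k_gp: 63.19
k_kp: 31.2
# Total blood clearance; the CES1 intrinsic clearance below is its
# well-stirred inversion with healthy Q_L = 1450 mL/min.
cl_b_ml_min: 1180
v_sys_l: 15.0768
k12_per_min: 0.01638
k21_per_min: 0.000476
k13_per_min: 0.3117
k31_per_min: 0.5057
pathways:
  - enzyme: CES1
    clint_ml_min: 79212.96
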