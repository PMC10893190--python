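schema: ces1pbpk-drug-v1
name: flumazenil
is_metabolite: false
logp: 1.64
pka: 0.86
binding_protein: albumin
rb: 1.0
fu_b: 0.6
k_lp: 2.57
k_gp: 2.71
k_kp: 2.41
# The printed intrinsic clearance (8169.9) differs 0.4% from a direct
# well-stirred inversion of cl_b (8202.0); the printed value is kept.
cl_b_ml_min: 1120
v_sys_l: 24.054
k12_per_min: 0.0376
k21_per_min: 0.0427
peff_1e-4_cm_s: 3.78
clint_k_ml_min: 1.67
pathways:
  - enzyme: CES1
    clint_ml_min: 8169.9
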