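schema: ces1pbpk-drug-v1
name: temocaprilat
is_metabolite: true
parent: temocapril
logp: 2.215
pka: 2.09
binding_protein: albumin
rb: 1.0
fu_b: 0.025
k_lp: 0.289
k_gp: 0.322
k_kp: 0.251
v_sys_l: 58.535
k12_per_min: 0.00184
k21_per_min: 0.000078
clint_k_ml_min: 949.84
# Biliary clearance taken as twice the renal intrinsic clearance; MRP2-mediated.
cl_bile_ml_min: 1899.68
pathways: []
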