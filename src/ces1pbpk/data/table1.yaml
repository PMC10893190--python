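# Physiology of the four simulated populations: an "ideal" 70-kg adult
# (healthy) and ideal Child-Pugh A/B/C cirrhosis patients.
# Units are encoded in the key names; flows mL/min, volumes mL, transit
# rates 1/min, radii cm, protein levels g/L, CES1 mg/g liver, CYP2B6 pmol/mg.
schema: ces1pbpk-physiology-v1
populations:
  healthy:
    q_l_ml_min: 1450
    q_la_ml_min: 300
    q_pv_ml_min: 1150
    q_k_ml_min: 1240
    q_gw_ml_min: {duodenum: 45, jejunum: 173, ileum: 102}
    v_liver_ml: 1690
    v_pv_ml: 70
    v_k_ml: 280
    v_gw_ml: {duodenum: 21, jejunum: 63, ileum: 42}
    k_t_per_min: {stomach: 0.04, duodenum: 0.07, jejunum: 0.03, ileum: 0.04}
    r_cm: {duodenum: 2.0, jejunum: 1.63, ileum: 1.45}
    gfr_ml_min: 105
    albumin_g_l: 44.7
    agp_g_l: 0.8
    ces1_mg_g_liver: 2.45
    cyp2b6_pmol_mg: 17
    lr_ratio: 0.037
    mrp2_ratio: 1.0
  CP-A:
    q_l_ml_min: 1436.5
    q_la_ml_min: 390
    q_pv_ml_min: 1046.5
    q_k_ml_min: 1091.2
    q_gw_ml_min: {duodenum: 45, jejunum: 173, ileum: 102}
    v_liver_ml: 1368.9
    v_pv_ml: 70
    v_k_ml: 280
    v_gw_ml: {duodenum: 21, jejunum: 63, ileum: 42}
    k_t_per_min: {stomach: 0.0504, duodenum: 0.0889, jejunum: 0.0381, ileum: 0.0508}
    r_cm: {duodenum: 2.0, jejunum: 1.63, ileum: 1.45}
    gfr_ml_min: 82
    albumin_g_l: 36.2
    agp_g_l: 0.57
    ces1_mg_g_liver: 2.45
    cyp2b6_pmol_mg: 17
    lr_ratio: 0.046
    mrp2_ratio: 0.54
  CP-B:
    q_l_ml_min: 1176.9
    q_la_ml_min: 486.9
    q_pv_ml_min: 690
    q_k_ml_min: 806
    q_gw_ml_min: {duodenum: 45, jejunum: 173, ileum: 102}
    v_liver_ml: 1098.5
    v_pv_ml: 70
    v_k_ml: 280
    v_gw_ml: {duodenum: 21, jejunum: 63, ileum: 42}
    k_t_per_min: {stomach: 0.0504, duodenum: 0.0889, jejunum: 0.0381, ileum: 0.0508}
    r_cm: {duodenum: 2.0, jejunum: 1.63, ileum: 1.45}
    gfr_ml_min: 82
    albumin_g_l: 30.4
    agp_g_l: 0.52
    ces1_mg_g_liver: 1.715
    cyp2b6_pmol_mg: 15.3
    lr_ratio: 0.052
    mrp2_ratio: 0.54
  CP-C:
    q_l_ml_min: 1656.3
    q_la_ml_min: 1020
    q_pv_ml_min: 636.3
    q_k_ml_min: 595.2
    q_gw_ml_min: {duodenum: 45, jejunum: 173, ileum: 102}
    v_liver_ml: 895.7
    v_pv_ml: 70
    v_k_ml: 280
    v_gw_ml: {duodenum: 21, jejunum: 63, ileum: 42}
    k_t_per_min: {stomach: 0.0504, duodenum: 0.0889, jejunum: 0.0381, ileum: 0.0508}
    r_cm: {duodenum: 2.0, jejunum: 1.63, ileum: 1.45}
    gfr_ml_min: 82
    albumin_g_l: 26.3
    agp_g_l: 0.46
    ces1_mg_g_liver: 0.735
    cyp2b6_pmol_mg: 13.6
    lr_ratio: 0.057
    mrp2_ratio: 0.54
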