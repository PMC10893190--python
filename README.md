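# ces1pbpk

A semi-physiologically-based pharmacokinetic (semi-PBPK) simulator that
predicts, *simultaneously*, the plasma concentration–time profiles of
carboxylesterase-1 (CES1) substrates and their active metabolites in healthy
adults and in liver-cirrhosis patients graded Child–Pugh A, B and C.

CES1 is the dominant hepatic hydrolase: it activates ACE-inhibitor prodrugs
(enalapril → enalaprilat, benazepril → benazeprilat, cilazapril, perindopril,
temocapril) and oseltamivir, and inactivates direct-acting drugs (flumazenil,
pethidine, remimazolam). Cirrhosis reduces hepatic CES1 content (to ~70% in
CP-B and ~30% in CP-C), shrinks the functional liver, redistributes splanchnic
blood flow, lowers plasma albumin and α1-acid glycoprotein, reduces GFR and
increases intestinal permeability — changes that pull the parent drug and its
metabolite in opposite directions. The package is aimed at pharmacokineticists
who want a transparent, scriptable model of those competing effects.

## The model

Amounts (mg) flow through stomach → duodenum/jejunum/ileum lumen →
gut wall → portal vein → liver → systemic pool → kidney, with optional
peripheral compartments; a parallel, absorption-free copy of the circulation
carries the metabolite, which is formed 1:1 (molar) in the liver. The liver is
well stirred: elimination is driven by the emergent venous unbound
concentration, so steady-state hepatic clearance is

    CL_H = Q_L · fu_b · CLint / (Q_L + fu_b · CLint)

and the kidney follows the analogous flow-limited form with CLint_K.
Absorption in segment *i* is first order with `ka_i = 2·Peff/r_i` (or the
drug's own ka); ileal outflow is unabsorbed loss. Saturable pathways
(pethidine's CES1 and CYP2B6 routes) use Michaelis–Menten kinetics natively.

The healthy→cirrhosis translation rescales, per compound:
CES1 CLint by the CES1-content and liver-volume ratios; other hepatic routes
by their own content ratio (CYP2B6 content, a fixed 0.62 for UGT, the MRP2
ratio for biliary clearance); fu by the binding-protein level ratio,
`fu_CI = 1/(1 + (1−fu)·(P_CI/P_HT)/fu)`; V_sys by the fu ratio; renal CLint by
the GFR ratio; and Peff/ka by the lactulose/rhamnose permeability ratio.

A virtual-population engine perturbs the listed ADME parameters independently
and uniformly over 80–120% (n = 1000 by default) and reports pointwise
5th/95th percentiles and means; a one-at-a-time sensitivity module scans fold
changes and decomposes the cirrhosis effect factor by factor.

## Worked example

```python
import ces1pbpk as c

phys = c.load_physiology()                      # bundled physiology table
drug = c.load_drug("enalapril")                 # + linked enalaprilat record
reg = c.DoseRegimen(route="oral", amount=10.0)  # 10 mg enalapril maleate

# healthy subject
res = c.simulate(c.build_system(drug, phys["healthy"], reg), t_end=24 * 60)
print(round(c.auc(res.t, res.conc["enalapril"]), 4),
      round(c.auc(res.t, res.conc["enalaprilat"]), 4))

# Child–Pugh C patient
tr = c.translate_drug(drug, phys["healthy"], phys["CP-C"])
res_c = c.simulate(c.build_system(tr, phys["CP-C"], reg), t_end=24 * 60)
print(round(c.auc(res_c.t, res_c.conc["enalapril"]), 4),
      round(c.auc(res_c.t, res_c.conc["enalaprilat"]), 4))
```

prints

```
0.1126 0.5708
0.3673 0.3284
```

i.e. AUC0–24h in µg·h/mL: severe cirrhosis roughly triples enalapril exposure
(CES1 loss dominates) while *lowering* enalaprilat exposure — less metabolite
is formed, and the reduced GFR only partly buffers its renal elimination.
The same objects feed the CLI:

```sh
ces1pbpk simulate --drug enalapril --population CP-C --dose "10 mg oral" \
    --t-end 24h --out profile.csv
ces1pbpk popsim --drug enalapril --dose "10 mg oral" --n 1000 --seed 42
ces1pbpk sensitivity --drug enalapril --dose "10 mg oral"
ces1pbpk reproduce --out-dir reproduction   # regenerate all summary tables
```

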