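# Methods

## Model structure

The simulator is a *semi*-PBPK model: the absorption and eliminating organs
are represented mechanistically, everything else is lumped into a systemic
pool with up to two empirical peripheral compartments. State variables are
amounts in mg; the canonical unit system is mg / mL / min.

**Absorption.** An oral dose enters the stomach lumen and transits
stomach → duodenum → jejunum → ileum with first-order rate constants K_t
(gastric emptying and segmental transit). Each small-bowel segment absorbs
into its gut-wall tissue with rate `ka_i`; when the record carries an
effective permeability, `ka_i = 2·Peff/r_i` from the cylindrical-lumen
surface-to-volume ratio and the segment radius, converted to cm/min; when it
carries a fitted ka, that value is used uniformly across segments. Ileal
outflow is unabsorbed (fecal) loss. No absorption occurs in the stomach or
colon, and the model has no enterohepatic recirculation.

**Distribution.** Gut wall, liver and kidney are perfusion-limited tissues:
each returns venous blood at `C_tissue·Rb/K_T:P`, with the tissue-to-plasma
partition coefficients taken as inputs. Balances are written on blood
concentrations; the systemic volume V_sys is treated as blood-referenced and
the reported plasma concentration is `A_sys/V_sys/Rb`. Peripheral exchange
acts on amounts with the tabulated K12/K21 (and K13/K31) rate constants.

**Elimination.** Only the liver and kidney eliminate. Hepatic enzymatic
pathways are driven by the unbound emergent concentration
`Cu = fu_b·C_liver·Rb/K_L:P`: linear pathways as `CLint·Cu`, saturable ones as
`Vmax·Cu/(Km+Cu)` with Vmax scaled by MPPGL (default 40 mg microsomal protein
per g liver, a standard literature value) times the liver mass (1 g/mL), and
Km converted to mass units with the molar mass. This emergent-blood
formulation is the unique one whose steady state reproduces the well-stirred
clearance `Q_L·fu_b·CLint/(Q_L+fu_b·CLint)`; the kidney likewise reproduces
the flow-limited form with CLint_K, which is the only formulation consistent
with the back-calculated cilazapril hepatic CLint of 199.7 mL/min (renal
blood clearance 77.5 mL/min removed from the total 205 mL/min before the
well-stirred inversion). Biliary clearance (temocaprilat) is an irreversible
loss from the liver. A pathway that produces a tracked metabolite transfers
its eliminated mass (scaled by a configurable metabolite/parent mass factor,
default 1.0 — molar masses of the pairs differ by under 10%) into the
metabolite's liver compartment; the metabolite model is the same structure
without the absorption chain.

**Dosing.** i.v. boluses initialize the systemic amount; infusions are
piecewise-constant inputs with an integrator restart at the window edge; oral
doses initialize the stomach. Doses are simulated as labeled (salt doses are
not corrected to base; the salt-to-base factor is exposed and defaults to 1).

## Cirrhosis translation

One scaling per mechanism, each recorded with provenance:

| parameter | scaling | source ratio |
|---|---|---|
| CES1 CLint (or Vmax) | content ratio × liver-volume ratio | 1.0 / 0.7 / 0.3 for CP-A/B/C |
| CYP2B6 route | content ratio × liver-volume ratio | 17 → 15.3 → 13.6 pmol/mg |
| UGT route | fixed 0.62 × liver-volume ratio | metoprolol AUC-change surrogate |
| biliary CL | MRP2 ratio × liver-volume ratio | 0.54 in cirrhosis |
| fu_b | single-binding-site protein-ratio formula | albumin, or AGP for pethidine |
| V_sys | fu ratio (free volume unaltered) | — |
| CLint_K | GFR ratio | 105 → 82 mL/min |
| Peff or ka | lactulose/rhamnose ratio | 0.037 → 0.046/0.052/0.057 |

For saturable pathways only the enzyme-content factor is applied to Vmax; the
liver-volume change enters through the engine's liver-mass scale-up, so the
volume factor is not double-counted. The UGT factor 0.62 is applied uniformly
to all three grades (a single number is available) — a documented limitation.
The tabulated fu_b is used directly as the binding parameter in the
protein-ratio formula; for the three compounds with Rb ≠ 1 this approximates
the plasma unbound fraction (documented approximation). Translation with the
healthy physiology on both sides is the exact identity, which the tests pin.

## Numerics

LSODA with rtol 1e-8 and atol 1e-10 mg; the output grid is refined to 0.1 min
over the dosing phase (first hour or twice the infusion length) and 1 min
afterwards, because the trapezoid rule on a coarse grid visibly overestimates
the AUC of fast distribution phases (remimazolam's K31 is 0.5/min). Cumulative
eliminations per route are carried as quadrature states, so mass balance —
administered = stored + terminal losses + unabsorbed, metabolite mass
back-converted to parent equivalents — is auditable at every output time; it
closes to ~1e-15 on intact systems and the test suite includes a deliberate
uncounted-leak negative control. NCA uses the linear trapezoid by default
(linear-up/log-down switchable), with a log-linear tail on the last three
positive points for AUC0–∞.

Study horizons: the published AUC0–t values depend on each clinical study's
last sampling time, which the summary tables do not print. The package fixes
per-drug horizons once (enalapril and the other 1980s ACE-inhibitor studies
24 h, oseltamivir 48 h, perindopril 72 h, default 48 h) as its own convention;
they are configuration, not fitted values.

## Virtual population

Each virtual individual multiplies the hepatic pathway CLint/Vmax, CLint_K,
fu_b (capped at 1), V_sys, Peff or ka, and the three partition coefficients —
for the parent and its metabolite — by independent uniform draws on
[0.8, 1.2], applied *after* any cirrhosis translation. The distribution is
uniform because only a range is specified for the underlying variability.
Draws come from counter-based substreams keyed by (seed, index), so
populations are reproducible and order-independent; an individual whose
integration fails is logged and redrawn. Because exposure is a convex
function of several perturbed parameters, the population *mean* AUC sits
systematically ~1–2% above the base case (Jensen bias) while the median stays
within 1%; consumers comparing means with base-case predictions should expect
that offset.

The generator perturbs parameters only — it does not emulate covariate
structure (weight, sex, age), parameter correlations, or inter-occasion
variability, so passing population tests demonstrate numerical and
statistical correctness of the Monte-Carlo machinery, not clinical coverage
of real between-subject variability.

## Sensitivity analysis

The one-at-a-time scan multiplies one parameter at a time over fold levels
(transit rates and portal/renal flows ×½–2, hepatic arterial flow,
permeability and hepatic CLint ×⅓–3, GFR ×0.5–1.5, unbound fractions
×0.7–1.3) and ranks parameters by the span (max/min) of the resulting AUC —
a scalar score chosen here because the source ranking metric is unstated;
near-ties should not be over-interpreted. Changing a splanchnic flow
rebalances total hepatic flow (Q_L = Q_LA + Q_PV). The contribution
decomposition switches one factor at a time (K_t, Q_PV, CLint_L, Peff, GFR,
Q_K, fu_b) from healthy to cirrhotic and compares each single-factor curve
with the fully translated prediction; the integrated curve *is* the full
translation, by construction.

## Known limitations

* The ODE right-hand side is a reconstruction constrained by closed-form
  checks (well-stirred/flow-limited steady states, the cilazapril inversion);
  the original implementation's source is not available, and some of its
  parameters were additionally optimized against clinical curves. Forward
  oral predictions therefore match the published predicted values only to a
  fold band, and a few fall outside the strict 0.8–1.25 window (the i.v.
  predictions agree to ~1%).
* Partition coefficients are inputs; no Rodgers–Rowland computation.
* No transporter kinetics beyond the lumped biliary clearance, no
  enterohepatic recirculation, no stomach/colon absorption.
* Renal elimination is flow-limited filtration+secretion scaled by GFR; no
  tubular reabsorption model.
* Grade-specific UGT ontogeny and binding-displacement interactions are out
  of scope.
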