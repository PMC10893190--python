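"""Healthy-to-cirrhosis parameter translation and derived-parameter algebra.

The translation maps a compound's ADME record, parameterized for healthy
subjects, onto a Child–Pugh A/B/C patient by rescaling each parameter with
the corresponding physiological alteration:

* hepatic CES1 intrinsic clearance — by the hepatic CES1 content ratio and
  the functional liver-volume ratio;
* other hepatic routes (CYP2B6, UGT, biliary/MRP2) — by the matching
  content ratio (a fixed 0.62 for UGT, for which no cirrhosis content data
  exist) and the liver-volume ratio;
* plasma unbound fraction — from the binding-protein level ratio assuming
  a single class of binding sites;
* apparent systemic volume — proportionally to the unbound-fraction change
  (the *free* volume of distribution is taken as unaltered);
* renal intrinsic clearance — by the GFR ratio;
* intestinal permeability (or the absorption rate constant) — by the
  lactulose/rhamnose permeability-marker ratio.

The module also houses the closed-form well-stirred/flow-limited algebra used
to back-calculate intrinsic clearances from total blood clearances, the
Michaelis–Menten linearization, and the cylindrical-lumen permeability →
absorption-rate conversion.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

from .parameters import DrugRecord, PhysiologySet, ValidationError

__all__ = [
    "TranslatedParameters",
    "scale_ces1_clint",
    "scale_other_clint",
    "scale_fu",
    "scale_volume",
    "scale_renal_clint",
    "scale_peff",
    "well_stirred_cl",
    "invert_well_stirred",
    "flow_limited_cl",
    "hepatic_split_clint",
    "mm_to_clint",
    "ka_from_peff",
    "translate_drug",
]

#: Cirrhosis/healthy AUC ratio of metoprolol, used as the UGT activity
#: surrogate (no measured hepatic UGT content exists for cirrhosis).
UGT_CIRRHOSIS_FACTOR = 0.62


# --------------------------------------------------------------------------
# Elementary scalings
# --------------------------------------------------------------------------

def scale_ces1_clint(clint_ht: float, phys_ht: PhysiologySet, phys_ci: PhysiologySet) -> float:
    """CES1-mediated hepatic CLint in the patient (mL/min)."""
    if not phys_ht.ces1_content > 0:
        raise ValidationError("ces1_content", "healthy CES1 content must be > 0")
    f_ces1 = phys_ci.ces1_content / phys_ht.ces1_content
    f_liver = phys_ci.v_liver / phys_ht.v_liver
    return clint_ht * f_ces1 * f_liver


def scale_other_clint(clint_ht: float, f_other: float,
                      phys_ht: PhysiologySet, phys_ci: PhysiologySet) -> float:
    """Hepatic CLint of a non-CES1 route, scaled by the route's content
    ratio ``f_other`` and the liver-volume ratio."""
    f_liver = phys_ci.v_liver / phys_ht.v_liver
    return clint_ht * f_other * f_liver


def _resolve_f_other(rule: str, phys_ht: PhysiologySet, phys_ci: PhysiologySet) -> float:
    if phys_ci == phys_ht:
        return 1.0  # identity translation
    if rule == "f_CYP2B6":
        return phys_ci.cyp2b6_content / phys_ht.cyp2b6_content
    if rule == "f_UGT_fixed_0.62":
        return UGT_CIRRHOSIS_FACTOR
    if rule == "MRP2":
        return phys_ci.mrp2_ratio / phys_ht.mrp2_ratio
    raise ValidationError("scaling_rule", f"cannot resolve scaling rule {rule!r}")


def scale_fu(fu_ht: float, protein_ht: float, protein_ci: float) -> float:
    """Patient unbound fraction from the binding-protein level ratio.

    Assumes binding to a single protein with unsaturated sites, so the bound:
    free ratio scales with the protein level:
    ``fu_ci = 1 / (1 + (1 - fu_ht) * (P_ci / P_ht) / fu_ht)``.
    """
    if not fu_ht > 0:
        raise ValidationError("fu_b", "healthy unbound fraction must be > 0")
    if not (protein_ht > 0 and protein_ci > 0):
        raise ValidationError("protein", "binding-protein levels must be > 0")
    if protein_ci == protein_ht:
        return fu_ht
    return 1.0 / (1.0 + (1.0 - fu_ht) * (protein_ci / protein_ht) / fu_ht)


def scale_volume(v_ht: float, fu_ht: float, fu_ci: float) -> float:
    """Apparent systemic volume scaled so the free volume is unchanged."""
    return v_ht * (fu_ci / fu_ht)


def scale_renal_clint(clint_k_ht: float, gfr_ht: float, gfr_ci: float) -> float:
    """Renal intrinsic clearance scaled by the glomerular filtration rate."""
    return clint_k_ht * (gfr_ci / gfr_ht)


def scale_peff(value_ht: float, lr_ht: float, lr_ci: float) -> float:
    """Absorption parameter (Peff or ka) scaled by the lactulose/rhamnose
    intestinal-permeability ratio."""
    return value_ht * (lr_ci / lr_ht)


# --------------------------------------------------------------------------
# Well-stirred / flow-limited algebra
# --------------------------------------------------------------------------

def well_stirred_cl(clint: float, fu_b: float, q: float) -> float:
    """Organ blood clearance of the well-stirred model,
    ``CL = Q·fu_b·CLint / (Q + fu_b·CLint)``."""
    return q * fu_b * clint / (q + fu_b * clint)


#: Steady-state renal blood clearance uses the same emergent-outflow form.
flow_limited_cl = well_stirred_cl


def invert_well_stirred(cl_b: float, fu_b: float, q_l: float) -> float:
    """Intrinsic clearance back-calculated from an organ blood clearance.

    Inverse of :func:`well_stirred_cl`; undefined for extraction ratios ≥ 1.
    """
    if cl_b < 0:
        raise ValidationError("cl_b", f"must be >= 0, got {cl_b}")
    if cl_b >= q_l:
        raise ValidationError("cl_b", f"blood clearance {cl_b} must be below organ flow {q_l}")
    return q_l * cl_b / (fu_b * (q_l - cl_b))


def hepatic_split_clint(cl_b_total: float, clint_k: float, fu_b: float,
                        q_l: float, q_k: float) -> float:
    """Hepatic CLint from a *total* blood clearance with a renal component.

    Removes the flow-limited renal blood clearance from the total, then
    inverts the well-stirred relation on the hepatic remainder.
    """
    cl_r = flow_limited_cl(clint_k, fu_b, q_k)
    cl_h = cl_b_total - cl_r
    if cl_h <= 0:
        raise ValidationError(
            "cl_b", f"renal clearance {cl_r:.4g} consumes the total {cl_b_total:.4g}; "
            "no hepatic remainder")
    return invert_well_stirred(cl_h, fu_b, q_l)


def mm_to_clint(vmax: float, km: float, mppgl: float, liver_mass: float) -> float:
    """Linearized intrinsic clearance (mL/min) of a saturable pathway.

    ``vmax`` nmol/min/mg microsomal protein, ``km`` µmol/L, ``mppgl`` mg
    microsomal protein per g liver, ``liver_mass`` g.  (vmax/km has units
    mL/min/mg; the result is the low-concentration limit used for reporting —
    the simulation engine keeps the pathway saturable.)
    """
    if km <= 0:
        raise ValidationError("km", f"must be > 0, got {km}")
    return (vmax / km) * mppgl * liver_mass


def ka_from_peff(peff: float, radius: float) -> float:
    """First-order absorption rate (1/min) in a cylindrical gut segment,
    ``ka = 2·Peff/r`` with ``peff`` in cm/s and ``radius`` in cm."""
    if radius <= 0:
        raise ValidationError("radius", f"must be > 0, got {radius}")
    return 2.0 * peff * 60.0 / radius


# --------------------------------------------------------------------------
# Whole-record translation
# --------------------------------------------------------------------------

@dataclass
class TranslatedParameters:
    """A patient-specific parameter set with per-field provenance.

    ``drug`` is a deep copy of the healthy record with every applicable field
    rescaled; ``scale_factors`` holds the named ratios that were applied and
    ``provenance`` records, per rescaled field, which scaling produced it.
    """

    drug: DrugRecord
    population_label: str
    scale_factors: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    metabolite: "TranslatedParameters | None" = None


def _translate_record(record: DrugRecord, phys_ht: PhysiologySet,
                      phys_ci: PhysiologySet) -> TranslatedParameters:
    out = record.copy()
    out.metabolite = None
    identity = phys_ci == phys_ht

    f_ces1 = phys_ci.ces1_content / phys_ht.ces1_content
    f_liver = phys_ci.v_liver / phys_ht.v_liver
    factors = {
        "f_CES1": f_ces1,
        "f_liver": f_liver,
        "GFR_ratio": phys_ci.gfr / phys_ht.gfr,
        "LR_ratio": phys_ci.lr_ratio / phys_ht.lr_ratio,
    }
    provenance: dict[str, str] = {}

    for pw in out.pathways:
        if pw.enzyme == "CES1":
            if pw.clint is not None:
                pw.clint = scale_ces1_clint(pw.clint, phys_ht, phys_ci)
                provenance[f"pathway[{pw.enzyme}].clint"] = "ces1_content_and_liver_volume"
            else:
                # liver mass enters through the engine's Vmax scale-up, so
                # only the enzyme-content ratio applies here
                pw.vmax = pw.vmax * f_ces1
                provenance[f"pathway[{pw.enzyme}].vmax"] = "ces1_content"
        else:
            f_other = _resolve_f_other(pw.scaling_rule, phys_ht, phys_ci)
            factors[f"f_other[{pw.enzyme}]"] = f_other
            if pw.clint is not None:
                pw.clint = scale_other_clint(pw.clint, f_other, phys_ht, phys_ci)
                provenance[f"pathway[{pw.enzyme}].clint"] = "other_content_and_liver_volume"
            else:
                pw.vmax = pw.vmax * f_other
                provenance[f"pathway[{pw.enzyme}].vmax"] = "other_content"

    protein_ht = phys_ht.protein_level(record.binding_protein)
    protein_ci = phys_ci.protein_level(record.binding_protein)
    fu_ci = scale_fu(record.fu_b, protein_ht, protein_ci)
    factors["fu_ratio"] = fu_ci / record.fu_b
    out.fu_b = fu_ci
    provenance["fu_b"] = f"binding_protein_ratio[{record.binding_protein}]"

    out.v_sys = scale_volume(record.v_sys, record.fu_b, fu_ci)
    provenance["v_sys"] = "unbound_fraction_ratio"

    if record.clint_k:
        out.clint_k = scale_renal_clint(record.clint_k, phys_ht.gfr, phys_ci.gfr)
        provenance["clint_k"] = "gfr_ratio"

    if record.cl_bile is not None:
        f_mrp2 = 1.0 if identity else phys_ci.mrp2_ratio / phys_ht.mrp2_ratio
        factors["MRP2_ratio"] = f_mrp2
        out.cl_bile = scale_other_clint(record.cl_bile, f_mrp2, phys_ht, phys_ci)
        provenance["cl_bile"] = "mrp2_ratio_and_liver_volume"

    if record.peff is not None:
        out.peff = scale_peff(record.peff, phys_ht.lr_ratio, phys_ci.lr_ratio)
        provenance["peff"] = "lr_ratio"
    elif record.ka is not None:
        out.ka = scale_peff(record.ka, phys_ht.lr_ratio, phys_ci.lr_ratio)
        provenance["ka"] = "lr_ratio"

    if not 0 < out.fu_b <= 1:
        raise ValidationError("fu_b", f"translated unbound fraction out of range: {out.fu_b}")
    return TranslatedParameters(
        drug=out,
        population_label=phys_ci.population_label,
        scale_factors=factors,
        provenance=provenance,
    )


def translate_drug(drug: DrugRecord, phys_ht: PhysiologySet,
                   phys_ci: PhysiologySet) -> TranslatedParameters:
    """Translate a drug record (and its linked metabolite) to a patient
    physiology.  With identical physiologies this is the identity map."""
    translated = _translate_record(drug, phys_ht, phys_ci)
    if drug.metabolite is not None:
        translated.metabolite = _translate_record(drug.metabolite, phys_ht, phys_ci)
        translated.drug.metabolite = translated.metabolite.drug
    return translated


def _as_record(drug) -> DrugRecord:
    """Accept either a raw record or a translated parameter set."""
    if isinstance(drug, TranslatedParameters):
        return drug.drug
    return copy.deepcopy(drug) if isinstance(drug, DrugRecord) else drug
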