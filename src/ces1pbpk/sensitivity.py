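"""One-at-a-time (local) sensitivity analysis.

Two complementary views:

* :func:`oat_scan` — multiply one parameter at a time by a set of fold
  levels and rank parameters by the span (max/min) of the resulting AUC;
* :func:`contribution_decomposition` — switch one physiological factor at a
  time from its healthy to its cirrhotic value (transit rates, portal and
  renal blood flow, hepatic intrinsic clearance, intestinal permeability,
  GFR, unbound fraction) and compare each single-factor curve with the
  fully translated cirrhosis prediction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import SimOptions, build_system, simulate
from .metrics import auc
from .parameters import DoseRegimen, DrugRecord, PhysiologySet, ValidationError
from .translate import (TranslatedParameters, scale_ces1_clint, scale_fu,
                        scale_other_clint, scale_peff, scale_renal_clint,
                        translate_drug, _resolve_f_other)

__all__ = ["SensitivitySpec", "PAPER_FOLD_LEVELS", "oat_scan",
           "contribution_decomposition"]

#: Fold levels used in the published scan: halving/doubling for transit and
#: the portal/renal flows, 1/3–3 for hepatic arterial flow, permeability and
#: hepatic CLint, 0.5–1.5 for GFR, 0.7–1.3 for the unbound fractions.
PAPER_FOLD_LEVELS = {
    "K_t": (0.5, 1.0, 2.0),
    "Q_PV": (0.5, 1.0, 2.0),
    "Q_K": (0.5, 1.0, 2.0),
    "Q_LA": (1 / 3, 1.0, 3.0),
    "CLint_L": (1 / 3, 1.0, 3.0),
    "Peff": (1 / 3, 1.0, 3.0),
    "GFR": (0.5, 1.0, 1.5),
    "fu_b": (0.7, 1.0, 1.3),
    "fu_b,m": (0.7, 1.0, 1.3),
}


@dataclass
class SensitivitySpec:
    """One scanned parameter: name, fold levels (must include 1) and the
    target metric ('parent' or 'metabolite' AUC)."""

    parameter: str
    levels: tuple = (0.5, 1.0, 2.0)
    target: str = "parent"

    def __post_init__(self):
        if any(not lv > 0 for lv in self.levels):
            raise ValidationError("levels", f"fold levels must be > 0, got {self.levels}")
        if not any(abs(lv - 1.0) < 1e-12 for lv in self.levels):
            raise ValidationError("levels", "fold levels must include 1")


def _apply_fold(drug: DrugRecord, phys: PhysiologySet, parameter: str,
                fold: float) -> tuple[DrugRecord, PhysiologySet]:
    """Return copies of (drug, phys) with one parameter multiplied."""
    d = drug.copy()
    p = phys
    if parameter == "K_t":
        p = dataclasses.replace(phys, k_t=tuple(k * fold for k in phys.k_t))
    elif parameter == "Q_PV":
        p = dataclasses.replace(phys, q_pv=phys.q_pv * fold,
                                q_l=phys.q_la + phys.q_pv * fold)
    elif parameter == "Q_LA":
        p = dataclasses.replace(phys, q_la=phys.q_la * fold,
                                q_l=phys.q_la * fold + phys.q_pv)
    elif parameter == "Q_K":
        p = dataclasses.replace(phys, q_k=phys.q_k * fold)
    elif parameter == "GFR":
        # renal intrinsic clearance is proportional to GFR
        p = dataclasses.replace(phys, gfr=phys.gfr * fold)
        d.clint_k *= fold
        if d.metabolite is not None:
            d.metabolite.clint_k *= fold
    elif parameter == "CLint_L":
        for pw in d.pathways:
            if pw.clint is not None:
                pw.clint *= fold
            else:
                pw.vmax *= fold
    elif parameter == "Peff":
        if d.peff is not None:
            d.peff *= fold
        elif d.ka is not None:
            d.ka *= fold
    elif parameter == "fu_b":
        d.fu_b = min(1.0, d.fu_b * fold)
    elif parameter == "fu_b,m":
        if d.metabolite is not None:
            d.metabolite.fu_b = min(1.0, d.metabolite.fu_b * fold)
    elif parameter in ("K12", "K21", "K13", "K31"):
        attr = parameter.lower()
        if getattr(d, attr) is not None:
            setattr(d, attr, getattr(d, attr) * fold)
    else:
        raise ValidationError("parameter", f"unknown scan parameter {parameter!r}")
    return d, p


def oat_scan(drug, phys: PhysiologySet, regimen: DoseRegimen,
             specs=None, t_end: float = 1440.0, t_last: float | None = None,
             grid=None, options: SimOptions | None = None):
    """Scan each parameter over its fold levels.

    Returns ``(table, ranking)``: a long-format DataFrame (parameter, fold,
    AUC per analyte) and a DataFrame of influence scores (span = max/min AUC
    over the levels) sorted descending per target.
    """
    if isinstance(drug, TranslatedParameters):
        drug = drug.drug
    if specs is None:
        specs = [SensitivitySpec(name, levels) for name, levels in PAPER_FOLD_LEVELS.items()
                 if name != "fu_b,m" or drug.metabolite is not None]
    options = options or SimOptions()

    met_name = drug.metabolite.name if drug.metabolite is not None else None
    rows = []
    for spec in specs:
        for fold in spec.levels:
            d, p = _apply_fold(drug, phys, spec.parameter, fold)
            res = simulate(build_system(d, p, regimen, options), t_end,
                           grid=grid, options=options)
            row = {"parameter": spec.parameter, "fold": fold,
                   "auc_parent": auc(res.t, res.conc[drug.name], t_last)}
            if met_name:
                row["auc_metabolite"] = auc(res.t, res.conc[met_name], t_last)
            rows.append(row)
    table = pd.DataFrame(rows)

    scores = []
    for param, grp in table.groupby("parameter", sort=False):
        entry = {"parameter": param,
                 "span_parent": grp["auc_parent"].max() / grp["auc_parent"].min()}
        if met_name:
            entry["span_metabolite"] = grp["auc_metabolite"].max() / grp["auc_metabolite"].min()
        scores.append(entry)
    ranking = pd.DataFrame(scores).sort_values("span_parent", ascending=False,
                                               ignore_index=True)
    return table, ranking


#: Factors decomposed in the healthy→cirrhosis contribution analysis.
CONTRIBUTION_FACTORS = ("K_t", "Q_PV", "CLint_L", "Peff", "GFR", "Q_K", "fu_b")


def _switch_factor(drug: DrugRecord, phys_ht: PhysiologySet,
                   phys_ci: PhysiologySet, factor: str):
    """(drug, phys) with exactly one factor moved to its cirrhotic value."""
    d = drug.copy()
    p = phys_ht
    if factor == "K_t":
        p = dataclasses.replace(phys_ht, k_t=phys_ci.k_t)
    elif factor == "Q_PV":
        p = dataclasses.replace(phys_ht, q_pv=phys_ci.q_pv,
                                q_l=phys_ht.q_la + phys_ci.q_pv)
    elif factor == "Q_K":
        p = dataclasses.replace(phys_ht, q_k=phys_ci.q_k)
    elif factor == "GFR":
        d.clint_k = scale_renal_clint(d.clint_k, phys_ht.gfr, phys_ci.gfr)
        if d.metabolite is not None:
            d.metabolite.clint_k = scale_renal_clint(
                d.metabolite.clint_k, phys_ht.gfr, phys_ci.gfr)
    elif factor == "CLint_L":
        for pw in d.pathways:
            if pw.enzyme == "CES1":
                if pw.clint is not None:
                    pw.clint = scale_ces1_clint(pw.clint, phys_ht, phys_ci)
                else:
                    pw.vmax *= phys_ci.ces1_content / phys_ht.ces1_content
            else:
                f_other = _resolve_f_other(pw.scaling_rule, phys_ht, phys_ci)
                if pw.clint is not None:
                    pw.clint = scale_other_clint(pw.clint, f_other, phys_ht, phys_ci)
                else:
                    pw.vmax *= f_other
    elif factor == "Peff":
        if d.peff is not None:
            d.peff = scale_peff(d.peff, phys_ht.lr_ratio, phys_ci.lr_ratio)
        elif d.ka is not None:
            d.ka = scale_peff(d.ka, phys_ht.lr_ratio, phys_ci.lr_ratio)
    elif factor == "fu_b":
        for rec in filter(None, (d, d.metabolite)):
            rec.fu_b = scale_fu(rec.fu_b,
                                phys_ht.protein_level(rec.binding_protein),
                                phys_ci.protein_level(rec.binding_protein))
    else:
        raise ValidationError("factor", f"unknown contribution factor {factor!r}")
    return d, p


def contribution_decomposition(drug: DrugRecord, phys_ht: PhysiologySet,
                               phys_ci: PhysiologySet, regimen: DoseRegimen,
                               factors=CONTRIBUTION_FACTORS,
                               t_end: float = 1440.0, t_last: float | None = None,
                               grid=None, options: SimOptions | None = None):
    """Per-factor healthy→cirrhosis contribution curves.

    Simulates the healthy base case, one run per single switched factor, and
    the fully translated ("integrated") cirrhosis case; reports each
    factor's direction of change on the parent (and metabolite) AUC.
    """
    options = options or SimOptions()
    met_name = drug.metabolite.name if drug.metabolite is not None else None

    def run(d, p):
        res = simulate(build_system(d, p, regimen, options), t_end, grid=grid,
                       options=options)
        entry = {"result": res, "auc_parent": auc(res.t, res.conc[drug.name], t_last)}
        if met_name:
            entry["auc_metabolite"] = auc(res.t, res.conc[met_name], t_last)
        return entry

    out = {"healthy": run(drug, phys_ht)}
    for factor in factors:
        d, p = _switch_factor(drug, phys_ht, phys_ci, factor)
        entry = run(d, p)
        entry["direction_parent"] = float(np.sign(entry["auc_parent"]
                                                  - out["healthy"]["auc_parent"]))
        if met_name:
            entry["direction_metabolite"] = float(np.sign(
                entry["auc_metabolite"] - out["healthy"]["auc_metabolite"]))
        out[factor] = entry
    out["integrated"] = run(translate_drug(drug, phys_ht, phys_ci), phys_ci)
    return out
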