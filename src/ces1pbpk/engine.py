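"""Semi-physiological ODE model: gut lumen transit, gut-wall absorption,
portal vein, well-stirred liver, kidney and a systemic pool with optional
peripheral compartments — simultaneously for a parent drug and its tracked
metabolite.

Model structure
---------------
Amounts (mg) are the state variables.  Organ balances are written on blood
concentrations; each perfusion-limited tissue (gut wall, liver, kidney)
returns venous blood at ``C_tissue · Rb / K_tissue:plasma``, so at steady
state the liver reproduces the well-stirred clearance
``Q_L·fu_b·CLint/(Q_L + fu_b·CLint)`` and the kidney the flow-limited form
``Q_K·fu_b·CLint_K/(Q_K + fu_b·CLint_K)``.  The systemic volume is treated
as blood-referenced; the reported plasma concentration is
``A_sys/V_sys/Rb``.

Oral doses enter the stomach lumen and transit through three small-bowel
segments (duodenum → jejunum → ileum); each segment absorbs into its gut
wall with a first-order rate, either the drug's own ``ka`` or
``2·Peff/r_i`` from the segment radius.  Ileal outflow is unabsorbed
(fecal) loss.  Elimination occurs only in the liver (enzymatic pathways,
linear or Michaelis–Menten, plus lumped biliary clearance, irreversible)
and the kidney.  Metabolite formed by a producing pathway appears in the
metabolite's own liver compartment; the metabolite model has the same
structure minus the absorption chain.

Cumulative eliminated amounts per route are carried as extra quadrature
states so mass balance can be audited at every output time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .parameters import DoseRegimen, DrugRecord, PhysiologySet, ValidationError
from .translate import TranslatedParameters, ka_from_peff

__all__ = ["SimOptions", "OdeSystem", "SimulationResult", "build_system",
           "simulate", "mass_balance"]

#: Default liver microsomal protein content (mg per g liver) used to scale
#: Michaelis–Menten Vmax values expressed per mg microsomal protein.
DEFAULT_MPPGL = 40.0


@dataclass
class SimOptions:
    """Numerical and scaling options for one simulation."""

    rtol: float = 1e-8
    atol: float = 1e-10  # mg
    method: str = "LSODA"
    mppgl: float = DEFAULT_MPPGL  # mg microsomal protein / g liver
    met_mass_factor: float = 1.0  # mg metabolite formed per mg parent converted


@dataclass
class _Species:
    """Parameter bindings and state slice for one circulating compound."""

    record: DrugRecord
    has_gut: bool  # lumen/absorption chain present
    idx: dict = field(default_factory=dict)
    ka: tuple = ()
    # hepatic pathway bindings: (kind, produces_index, a, b, accumulator_index)
    pathways: list = field(default_factory=list)
    mass_factor: float = 1.0


@dataclass
class OdeSystem:
    """A fully bound ODE right-hand side plus dose events.

    All rate parameters are plain floats resolved at build time; tests may
    copy and tamper with them (e.g. to break flow balance deliberately).
    """

    phys: PhysiologySet
    regimen: DoseRegimen
    species: list[_Species]
    n_states: int
    y0: np.ndarray
    infusion_rate: float  # mg/min into the systemic pool
    infusion_end: float  # min
    labels: list[str]

    def administered(self, t: np.ndarray) -> np.ndarray:
        """Dose administered up to each time (mg)."""
        dose = self.regimen.dose_mg
        if self.infusion_rate > 0:
            return self.infusion_rate * np.minimum(np.asarray(t, float), self.infusion_end)
        return np.full_like(np.asarray(t, float), dose)

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros_like(y)
        phys = self.phys
        q_gw_sum = sum(phys.q_gw)
        q_pv_direct = phys.q_pv - q_gw_sum

        formed = {}  # target species index -> mg/min formed in liver
        for s in self.species:
            rec = s.record
            ix = s.idx
            rb = rec.rb
            c_sys = y[ix["sys"]] / rec.v_sys

            if s.has_gut:
                kt = phys.k_t
                a_st = y[ix["stomach"]]
                dy[ix["stomach"]] = -kt[0] * a_st
                inflow = kt[0] * a_st
                for i in range(3):
                    a_lum = y[ix["lumen"][i]]
                    out = kt[i + 1] * a_lum
                    absorbed = s.ka[i] * a_lum
                    dy[ix["lumen"][i]] = inflow - out - absorbed
                    dy[ix["gw"][i]] += absorbed
                    inflow = out
                dy[ix["fecal"]] = inflow  # ileal outflow is unabsorbed loss

            # gut wall (perfusion-limited) and portal vein
            pv_in = q_pv_direct * c_sys
            for i in range(3):
                c_gw = y[ix["gw"][i]] / phys.v_gw[i]
                c_gw_out = c_gw * rb / rec.k_gp
                dy[ix["gw"][i]] += phys.q_gw[i] * (c_sys - c_gw_out)
                pv_in += phys.q_gw[i] * c_gw_out
            c_pv = y[ix["pv"]] / phys.v_pv
            dy[ix["pv"]] = pv_in - phys.q_pv * c_pv

            # liver: well-stirred, emergent-blood driven elimination
            c_liv = y[ix["liver"]] / phys.v_liver
            c_liv_out = c_liv * rb / rec.k_lp
            elim_hep = 0.0
            for kind, produces, a, b, acc in s.pathways:
                if kind == "linear":
                    rate = a * c_liv_out  # a = clint*fu_b
                else:  # saturable: a = Vmax_total (mg/min), b = Km (mg/mL)
                    cu = rec.fu_b * c_liv_out
                    rate = a * cu / (b + cu)
                elim_hep += rate
                dy[acc] = rate
                if produces is not None:
                    formed[produces] = formed.get(produces, 0.0) + rate
            bile = (rec.cl_bile or 0.0) * rec.fu_b * c_liv_out
            dy[ix["bile"]] = bile
            dy[ix["liver"]] = (phys.q_la * c_sys + phys.q_pv * c_pv
                               - phys.q_l * c_liv_out - elim_hep - bile)

            # kidney
            c_k_out = (y[ix["kidney"]] / phys.v_k) * rb / rec.k_kp
            renal = rec.clint_k * rec.fu_b * c_k_out
            dy[ix["kidney"]] = phys.q_k * (c_sys - c_k_out) - renal
            dy[ix["renal"]] = renal

            # systemic pool + peripheral exchange
            dsys = (phys.q_l * c_liv_out + phys.q_k * c_k_out
                    - (phys.q_la + phys.q_pv + phys.q_k) * c_sys)
            if "per1" in ix:
                dsys += rec.k21 * y[ix["per1"]] - rec.k12 * y[ix["sys"]]
                dy[ix["per1"]] = rec.k12 * y[ix["sys"]] - rec.k21 * y[ix["per1"]]
            if "per2" in ix:
                dsys += rec.k31 * y[ix["per2"]] - rec.k13 * y[ix["sys"]]
                dy[ix["per2"]] = rec.k13 * y[ix["sys"]] - rec.k31 * y[ix["per2"]]
            dy[ix["sys"]] = dsys

        # metabolite formation (mass-converted) into the target liver
        for target, rate in formed.items():
            s_t = self.species[target]
            dy[s_t.idx["liver"]] += rate * s_t.mass_factor
            dy[s_t.idx["formed"]] = rate * s_t.mass_factor

        if self.infusion_rate > 0 and t < self.infusion_end:
            dy[self.species[0].idx["sys"]] += self.infusion_rate
        return dy


@dataclass
class SimulationResult:
    """Time grids, plasma curves and the mass-balance ledger of one run."""

    t: np.ndarray  # min
    conc: dict  # name -> plasma concentration, ng/mL
    amounts: dict  # state label -> mg trajectory
    eliminated: dict  # route label -> cumulative mg
    administered: np.ndarray  # mg
    dose_mg: float
    system: OdeSystem
    diagnostics: dict = field(default_factory=dict)


def build_system(drug, phys: PhysiologySet, regimen: DoseRegimen,
                 options: SimOptions | None = None) -> OdeSystem:
    """Assemble the coupled parent(+metabolite) ODE system for one regimen.

    ``drug`` may be a healthy :class:`DrugRecord` or a cirrhosis-translated
    :class:`TranslatedParameters`; the linked metabolite record is taken
    from the parent record.
    """
    options = options or SimOptions()
    if isinstance(drug, TranslatedParameters):
        drug = drug.drug
    if not isinstance(drug, DrugRecord):
        raise TypeError(f"expected DrugRecord or TranslatedParameters, got {type(drug)}")

    oral = regimen.route == "oral"
    if oral and not drug.has_absorption:
        raise ValidationError("route", f"{drug.name} has neither Peff nor ka; cannot dose orally")
    produced = drug.produced_metabolites
    if produced and drug.metabolite is None:
        raise ValidationError("metabolite", f"{drug.name} produces {produced} but no metabolite record is linked")

    records = [(drug, oral)]
    if drug.metabolite is not None:
        records.append((drug.metabolite, False))
    name_to_index = {rec.name: i for i, (rec, _) in enumerate(records)}

    species: list[_Species] = []
    labels: list[str] = []
    n = 0

    def add(label: str) -> int:
        nonlocal n
        labels.append(label)
        n += 1
        return n - 1

    for rec, has_gut in records:
        s = _Species(record=rec, has_gut=has_gut)
        s.mass_factor = options.met_mass_factor if rec.is_metabolite else 1.0
        p = rec.name
        if has_gut:
            s.idx["stomach"] = add(f"{p}:stomach")
            s.idx["lumen"] = [add(f"{p}:lumen_{seg}") for seg in ("duodenum", "jejunum", "ileum")]
            if rec.ka is not None:
                s.ka = (rec.ka,) * 3
            else:
                s.ka = tuple(ka_from_peff(rec.peff, r) for r in phys.r)
        s.idx["gw"] = [add(f"{p}:gw_{seg}") for seg in ("duodenum", "jejunum", "ileum")]
        s.idx["pv"] = add(f"{p}:pv")
        s.idx["liver"] = add(f"{p}:liver")
        s.idx["kidney"] = add(f"{p}:kidney")
        s.idx["sys"] = add(f"{p}:sys")
        if rec.k12 is not None:
            s.idx["per1"] = add(f"{p}:per1")
        if rec.k13 is not None:
            s.idx["per2"] = add(f"{p}:per2")
        species.append(s)

    # accumulator states (quadratures) after the dynamic states
    for s in species:
        rec = s.record
        p = rec.name
        for pw in rec.pathways:
            acc = add(f"{p}:elim_{pw.enzyme}")
            target = name_to_index.get(pw.produces) if pw.produces else None
            if pw.is_saturable:
                if rec.mw is None:
                    raise ValidationError("mw", f"{rec.name}: saturable pathway needs a molar mass")
                vmax_total = pw.vmax * 1e-6 * rec.mw * options.mppgl * phys.v_liver  # mg/min
                km_mass = pw.km * rec.mw * 1e-6  # mg/mL
                s.pathways.append(("saturable", target, vmax_total, km_mass, acc))
            else:
                s.pathways.append(("linear", target, pw.clint * rec.fu_b, 0.0, acc))
        s.idx["renal"] = add(f"{p}:elim_renal")
        s.idx["bile"] = add(f"{p}:elim_bile")
        if s.has_gut:
            s.idx["fecal"] = add(f"{p}:fecal")
        if rec.is_metabolite:
            s.idx["formed"] = add(f"{p}:formed")

    y0 = np.zeros(n)
    dose = regimen.dose_mg
    infusion_rate, infusion_end = 0.0, 0.0
    if regimen.route == "oral":
        y0[species[0].idx["stomach"]] = dose
    elif regimen.route == "iv_bolus":
        y0[species[0].idx["sys"]] = dose
    else:
        infusion_rate = dose / regimen.infusion_duration
        infusion_end = regimen.infusion_duration

    return OdeSystem(phys=phys, regimen=regimen, species=species, n_states=n,
                     y0=y0, infusion_rate=infusion_rate, infusion_end=infusion_end,
                     labels=labels)


def _default_grid(t_end: float, infusion_end: float) -> np.ndarray:
    """Output grid: fine during the dosing phase, 1-min afterwards."""
    fine_end = min(t_end, max(60.0, 2.0 * infusion_end))
    fine = np.arange(0.0, fine_end, 0.1)
    coarse = np.arange(np.ceil(fine_end), t_end + 0.5, 1.0)
    pts = np.concatenate([fine, coarse, [infusion_end, t_end]])
    return np.unique(np.clip(pts, 0.0, t_end))


def simulate(system: OdeSystem, t_end: float, grid=None,
             options: SimOptions | None = None) -> SimulationResult:
    """Integrate the system to ``t_end`` (min) on a stiff-capable solver.

    Infusions are handled as piecewise-constant input with an integrator
    restart at the window edge.  ``grid`` may be a step (float, min) or an
    explicit array of output times.
    """
    options = options or SimOptions()
    if not t_end > 0:
        raise ValidationError("t_end", f"must be > 0, got {t_end}")
    if grid is None:
        t_eval = _default_grid(t_end, system.infusion_end)
    elif np.isscalar(grid):
        t_eval = np.unique(np.clip(np.concatenate(
            [np.arange(0.0, t_end + grid / 2, grid), [system.infusion_end, t_end]]), 0.0, t_end))
    else:
        t_eval = np.asarray(grid, float)

    edges = [0.0]
    if 0.0 < system.infusion_end < t_end:
        edges.append(system.infusion_end)
    edges.append(t_end)

    ts, ys = [], []
    y = system.y0.copy()
    nfev = 0
    for a, b in zip(edges[:-1], edges[1:]):
        seg_eval = t_eval[(t_eval >= a) & (t_eval <= b)]
        sol = solve_ivp(system.rhs, (a, b), y, method=options.method,
                        rtol=options.rtol, atol=options.atol, t_eval=seg_eval,
                        dense_output=False)
        if not sol.success:
            raise RuntimeError(
                f"integration failed at t={sol.t[-1] if sol.t.size else a:.3f} min: {sol.message}")
        nfev += sol.nfev
        if ts and sol.t.size and ts[-1].size and sol.t[0] == ts[-1][-1]:
            ts.append(sol.t[1:]); ys.append(sol.y[:, 1:])
        else:
            ts.append(sol.t); ys.append(sol.y)
        # both window edges are always in the output grid, so the last
        # column is the state at b
        y = sol.y[:, -1]

    t = np.concatenate(ts)
    ymat = np.concatenate(ys, axis=1)

    conc = {}
    for s in system.species:
        rec = s.record
        # mg/mL blood -> ng/mL plasma
        conc[rec.name] = ymat[s.idx["sys"]] / rec.v_sys / rec.rb * 1e6

    amounts = {label: ymat[i] for i, label in enumerate(system.labels)}
    eliminated = {}
    for s in system.species:
        p = s.record.name
        for kind, _tgt, _a, _b, acc in s.pathways:
            eliminated[system.labels[acc]] = ymat[acc]
        eliminated[f"{p}:renal"] = ymat[s.idx["renal"]]
        eliminated[f"{p}:bile"] = ymat[s.idx["bile"]]
        if s.has_gut:
            eliminated[f"{p}:fecal"] = ymat[s.idx["fecal"]]

    return SimulationResult(
        t=t, conc=conc, amounts=amounts, eliminated=eliminated,
        administered=system.administered(t), dose_mg=system.regimen.dose_mg,
        system=system, diagnostics={"nfev": nfev, "n_states": system.n_states},
    )


def mass_balance(result: SimulationResult) -> float:
    """Maximum relative mass-balance closure error over the output grid.

    Administered dose must equal stored amounts plus terminal eliminations
    (metabolite mass back-converted to parent equivalents); eliminations
    through producing pathways are transfers, not losses.
    """
    system = result.system
    total = np.zeros_like(result.t)
    for s in system.species:
        rec = s.record
        fac = s.mass_factor
        stored = np.zeros_like(result.t)
        for key in ("stomach", "pv", "liver", "kidney", "sys", "per1", "per2"):
            if key in s.idx:
                stored += result.amounts[system.labels[s.idx[key]]]
        for key in ("lumen", "gw"):
            if key in s.idx:
                for i in s.idx[key]:
                    stored += result.amounts[system.labels[i]]
        lost = np.zeros_like(result.t)
        for kind, target, _a, _b, acc in s.pathways:
            if target is None:  # producing pathways transfer mass onward
                lost += result.amounts[system.labels[acc]]
        lost += result.amounts[system.labels[s.idx["renal"]]]
        lost += result.amounts[system.labels[s.idx["bile"]]]
        if s.has_gut:
            lost += result.amounts[system.labels[s.idx["fecal"]]]
        total += (stored + lost) / fac

    adm = result.administered
    denom = np.where(adm > 0, adm, 1.0)
    return float(np.max(np.abs((adm - total) / denom)))
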