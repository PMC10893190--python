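"""Typed data model for physiology, drug and dosing inputs.

The package works in a single canonical unit system — mg for amounts, mL for
volumes, min for time — so every loader converts on the way in (e.g. the
systemic volume is tabulated in L and stored in mL).  Two exceptions, kept in
their native units because every formula that touches them expects those
units: the effective intestinal permeability ``peff`` (cm/s, converted to
cm/min at the point of use) and the Michaelis–Menten pair for saturable
hepatic pathways (``vmax`` in nmol/min/mg microsomal protein, ``km`` in
µmol/L), which the simulation engine converts to mass units with the drug's
molar mass.

Bundled fixtures under ``ces1pbpk/data`` encode the published physiology of
the four populations (healthy and Child–Pugh A/B/C) and the ADME records of
nine CES1 substrates with their six tracked metabolites.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "ValidationError",
    "PhysiologySet",
    "EliminationPathway",
    "DrugRecord",
    "DoseRegimen",
    "GUT_SEGMENTS",
    "POPULATIONS",
    "load_physiology",
    "load_drug",
    "write_drug",
    "write_physiology",
    "available_drugs",
    "normalize_units",
]

GUT_SEGMENTS = ("duodenum", "jejunum", "ileum")
POPULATIONS = ("healthy", "CP-A", "CP-B", "CP-C")

DRUG_SCHEMA = "ces1pbpk-drug-v1"
PHYSIOLOGY_SCHEMA = "ces1pbpk-physiology-v1"


class ValidationError(ValueError):
    """Raised when a record violates an invariant; names the offending field."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


# --------------------------------------------------------------------------
# Physiology
# --------------------------------------------------------------------------

@dataclass
class PhysiologySet:
    """One population column of the physiology table.

    Flows in mL/min, volumes in mL, transit rates in 1/min, gut radii in cm,
    plasma binding proteins in g/L, hepatic CES1 content in mg/g liver,
    CYP2B6 in pmol/mg microsomal protein.  ``lr_ratio`` is the
    lactulose/rhamnose intestinal-permeability marker and ``mrp2_ratio`` the
    relative canalicular MRP2 transporter abundance (1.0 in health).
    """

    population_label: str
    q_l: float
    q_la: float
    q_pv: float
    q_k: float
    q_gw: tuple[float, float, float]
    v_liver: float
    v_pv: float
    v_k: float
    v_gw: tuple[float, float, float]
    k_t: tuple[float, float, float, float]  # stomach, duodenum, jejunum, ileum
    r: tuple[float, float, float]
    gfr: float
    albumin: float
    agp: float
    ces1_content: float
    cyp2b6_content: float
    lr_ratio: float
    mrp2_ratio: float

    def __post_init__(self):
        self.q_gw = tuple(float(x) for x in self.q_gw)
        self.v_gw = tuple(float(x) for x in self.v_gw)
        self.k_t = tuple(float(x) for x in self.k_t)
        self.r = tuple(float(x) for x in self.r)
        self.validate()

    def validate(self) -> None:
        for name in ("q_l", "q_la", "q_pv", "q_k", "v_liver", "v_pv", "v_k",
                     "gfr", "albumin", "agp", "ces1_content",
                     "cyp2b6_content", "lr_ratio", "mrp2_ratio"):
            value = getattr(self, name)
            if not value > 0:
                raise ValidationError(name, f"must be strictly positive, got {value}")
        for name in ("q_gw", "v_gw", "k_t", "r"):
            if any(not v > 0 for v in getattr(self, name)):
                raise ValidationError(name, f"all entries must be strictly positive, got {getattr(self, name)}")
        if abs(self.q_l - (self.q_la + self.q_pv)) > 1e-3 * self.q_l:
            raise ValidationError(
                "q_l",
                f"hepatic blood flow {self.q_l} must equal hepatic arterial + "
                f"portal flow {self.q_la + self.q_pv} (within 0.1%)",
            )
        if sum(self.q_gw) > self.q_pv:
            raise ValidationError("q_gw", "summed gut-wall flows exceed portal vein flow")

    def protein_level(self, binding_protein: str) -> float:
        """Plasma level (g/L) of the named binding protein (albumin or AGP)."""
        if binding_protein == "albumin":
            return self.albumin
        if binding_protein == "AGP":
            return self.agp
        raise ValidationError("binding_protein", f"unknown protein {binding_protein!r}")


# --------------------------------------------------------------------------
# Drug records
# --------------------------------------------------------------------------

#: Cirrhosis scale factor applied to each hepatic enzyme's intrinsic clearance.
PATHWAY_SCALING_RULES = {
    "CES1": "f_CES1",
    "CYP2B6": "f_CYP2B6",
    "UGT": "f_UGT_fixed_0.62",
}


@dataclass
class EliminationPathway:
    """One hepatic elimination route: either linear (clint, mL/min) or
    saturable (vmax nmol/min/mg protein with km µmol/L), optionally producing
    a tracked metabolite in a 1:1 molar conversion."""

    enzyme: str
    clint: Optional[float] = None
    vmax: Optional[float] = None
    km: Optional[float] = None
    produces: Optional[str] = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.enzyme not in PATHWAY_SCALING_RULES:
            raise ValidationError("enzyme", f"unknown hepatic enzyme {self.enzyme!r}")
        saturable = self.vmax is not None or self.km is not None
        if saturable and self.clint is not None:
            raise ValidationError("clint", "a pathway is either linear or saturable, not both")
        if saturable:
            if self.vmax is None or self.km is None:
                raise ValidationError("vmax", "saturable pathway needs both vmax and km")
            if not self.km > 0:
                raise ValidationError("km", f"must be > 0, got {self.km}")
            if self.vmax < 0:
                raise ValidationError("vmax", f"must be >= 0, got {self.vmax}")
        elif self.clint is None:
            raise ValidationError("clint", "pathway needs clint or (vmax, km)")
        elif self.clint < 0:
            raise ValidationError("clint", f"must be >= 0, got {self.clint}")

    @property
    def is_saturable(self) -> bool:
        return self.vmax is not None

    @property
    def scaling_rule(self) -> str:
        return PATHWAY_SCALING_RULES[self.enzyme]


@dataclass
class DrugRecord:
    """ADME parameter set for one compound (one drug-table row).

    ``v_sys`` is stored in mL; ``peff`` in cm/s; rate constants in 1/min;
    clearances in mL/min.  ``metabolite`` holds the linked metabolite record
    when the compound has a tracked metabolite.
    """

    name: str
    binding_protein: str
    rb: float
    fu_b: float
    k_lp: float
    k_gp: float
    k_kp: float
    v_sys: float  # mL
    pathways: list[EliminationPathway] = field(default_factory=list)
    logp: Optional[float] = None
    pka: Optional[float] = None
    cl_b: Optional[float] = None
    k12: Optional[float] = None
    k21: Optional[float] = None
    k13: Optional[float] = None
    k31: Optional[float] = None
    peff: Optional[float] = None  # cm/s
    ka: Optional[float] = None  # 1/min
    clint_k: float = 0.0
    cl_bile: Optional[float] = None
    f: Optional[float] = None
    mw: Optional[float] = None  # g/mol
    is_metabolite: bool = False
    parent: Optional[str] = None
    metabolite_name: Optional[str] = None
    metabolite: Optional["DrugRecord"] = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not 0 < self.fu_b <= 1:
            raise ValidationError("fu_b", f"must be in (0, 1], got {self.fu_b}")
        if not self.rb > 0:
            raise ValidationError("rb", f"must be > 0, got {self.rb}")
        for name in ("k_lp", "k_gp", "k_kp"):
            if not getattr(self, name) > 0:
                raise ValidationError(name, f"partition coefficient must be > 0, got {getattr(self, name)}")
        if not self.v_sys > 0:
            raise ValidationError("v_sys", f"must be > 0, got {self.v_sys}")
        for name in ("k12", "k21", "k13", "k31"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValidationError(name, f"must be >= 0, got {value}")
        if (self.k13 is not None or self.k31 is not None) and self.k12 is None:
            raise ValidationError("k13", "second peripheral compartment requires the first (k12/k21)")
        if self.clint_k < 0:
            raise ValidationError("clint_k", f"must be >= 0, got {self.clint_k}")
        if self.cl_bile is not None and self.cl_bile < 0:
            raise ValidationError("cl_bile", f"must be >= 0, got {self.cl_bile}")
        if self.binding_protein not in ("albumin", "AGP"):
            raise ValidationError("binding_protein", f"must be 'albumin' or 'AGP', got {self.binding_protein!r}")
        for pw in self.pathways:
            pw.validate()

    @property
    def has_absorption(self) -> bool:
        return self.peff is not None or self.ka is not None

    @property
    def produced_metabolites(self) -> list[str]:
        return [p.produces for p in self.pathways if p.produces]

    def copy(self) -> "DrugRecord":
        return copy.deepcopy(self)


@dataclass
class DoseRegimen:
    """One administration: route, labeled amount and infusion duration.

    ``amount`` is the labeled salt dose in mg (or mg/kg when ``per_kg``);
    ``salt_to_base_factor`` defaults to 1.0 — doses are simulated as labeled,
    matching the published tables which never salt-correct.
    """

    route: str  # iv_bolus | iv_infusion | oral
    amount: float
    per_kg: bool = False
    body_weight: float = 70.0
    infusion_duration: float = 0.0  # min
    salt_to_base_factor: float = 1.0

    def __post_init__(self):
        if self.route not in ("iv_bolus", "iv_infusion", "oral"):
            raise ValidationError("route", f"unknown route {self.route!r}")
        if not self.amount > 0:
            raise ValidationError("amount", f"must be > 0, got {self.amount}")
        if self.infusion_duration < 0:
            raise ValidationError("infusion_duration", f"must be >= 0, got {self.infusion_duration}")
        if self.route == "iv_infusion" and self.infusion_duration == 0:
            raise ValidationError("infusion_duration", "iv_infusion requires a positive duration")

    @property
    def dose_mg(self) -> float:
        dose = self.amount * (self.body_weight if self.per_kg else 1.0)
        return dose * self.salt_to_base_factor


# --------------------------------------------------------------------------
# Unit normalization of raw mappings
# --------------------------------------------------------------------------

# Raw fixture key -> (canonical field, multiplicative factor to canonical units)
_DRUG_KEY_MAP = {
    "v_sys_l": ("v_sys", 1000.0),  # L -> mL
    "peff_1e-4_cm_s": ("peff", 1e-4),  # 1e-4 cm/s -> cm/s
    "ka_per_min": ("ka", 1.0),
    "clint_k_ml_min": ("clint_k", 1.0),
    "cl_b_ml_min": ("cl_b", 1.0),
    "cl_bile_ml_min": ("cl_bile", 1.0),
    "k12_per_min": ("k12", 1.0),
    "k21_per_min": ("k21", 1.0),
    "k13_per_min": ("k13", 1.0),
    "k31_per_min": ("k31", 1.0),
    "mw_g_mol": ("mw", 1.0),
}
_PATHWAY_KEY_MAP = {
    "clint_ml_min": ("clint", 1.0),
    "vmax_nmol_min_mg": ("vmax", 1.0),
    "km_umol_l": ("km", 1.0),
}


def normalize_units(raw: dict, key_map: dict | None = None) -> dict:
    """Convert a unit-suffixed raw mapping to canonical field names/units.

    Idempotent: keys already in canonical form pass through unchanged, so
    normalizing twice equals normalizing once.
    """
    key_map = _DRUG_KEY_MAP if key_map is None else key_map
    out = {}
    for key, value in raw.items():
        if key in key_map:
            canonical, factor = key_map[key]
            out[canonical] = None if value is None else float(value) * factor
        else:
            out[key] = value
    return out


# --------------------------------------------------------------------------
# Loaders / writers
# --------------------------------------------------------------------------

def _data_root():
    return resources.files("ces1pbpk") / "data"


def available_drugs() -> list[str]:
    """Names of all bundled compound fixtures (parents and metabolites)."""
    root = _data_root() / "drugs"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def _read_yaml(source) -> dict:
    if isinstance(source, (str, Path)) and not str(source).endswith((".yaml", ".yml")):
        # bundled name
        name = str(source)
        candidate = _data_root() / f"{name}.yaml"
        try:
            text = candidate.read_text()
        except FileNotFoundError:
            candidate = _data_root() / "drugs" / f"{name}.yaml"
            try:
                text = candidate.read_text()
            except FileNotFoundError:
                raise ValidationError("source", f"no bundled fixture named {name!r}")
        return yaml.safe_load(text)
    return yaml.safe_load(Path(source).read_text())


def load_physiology(source="table1") -> dict[str, PhysiologySet]:
    """Load the physiology table; returns one validated set per population."""
    raw = _read_yaml(source)
    if raw.get("schema") != PHYSIOLOGY_SCHEMA:
        raise ValidationError("schema", f"expected {PHYSIOLOGY_SCHEMA!r}, got {raw.get('schema')!r}")
    pops = raw.get("populations", {})
    missing = [p for p in POPULATIONS if p not in pops]
    if missing:
        raise ValidationError("populations", f"missing population columns: {missing}")
    out = {}
    for label, rec in pops.items():
        try:
            out[label] = PhysiologySet(
                population_label=label,
                q_l=float(rec["q_l_ml_min"]),
                q_la=float(rec["q_la_ml_min"]),
                q_pv=float(rec["q_pv_ml_min"]),
                q_k=float(rec["q_k_ml_min"]),
                q_gw=tuple(float(rec["q_gw_ml_min"][s]) for s in GUT_SEGMENTS),
                v_liver=float(rec["v_liver_ml"]),
                v_pv=float(rec["v_pv_ml"]),
                v_k=float(rec["v_k_ml"]),
                v_gw=tuple(float(rec["v_gw_ml"][s]) for s in GUT_SEGMENTS),
                k_t=tuple(float(rec["k_t_per_min"][s]) for s in ("stomach",) + GUT_SEGMENTS),
                r=tuple(float(rec["r_cm"][s]) for s in GUT_SEGMENTS),
                gfr=float(rec["gfr_ml_min"]),
                albumin=float(rec["albumin_g_l"]),
                agp=float(rec["agp_g_l"]),
                ces1_content=float(rec["ces1_mg_g_liver"]),
                cyp2b6_content=float(rec["cyp2b6_pmol_mg"]),
                lr_ratio=float(rec["lr_ratio"]),
                mrp2_ratio=float(rec["mrp2_ratio"]),
            )
        except KeyError as exc:
            raise ValidationError(str(exc.args[0]), f"missing field in population {label!r}")
    return out


def load_drug(source, with_metabolite: bool = True) -> DrugRecord:
    """Load one compound record; links the tracked metabolite when present."""
    raw = _read_yaml(source)
    if raw.get("schema") != DRUG_SCHEMA:
        raise ValidationError("schema", f"expected {DRUG_SCHEMA!r}, got {raw.get('schema')!r}")
    norm = normalize_units({k: v for k, v in raw.items() if k != "schema"})
    pathways = [
        EliminationPathway(
            enzyme=p["enzyme"],
            produces=p.get("produces"),
            **{k: v for k, v in normalize_units(p, _PATHWAY_KEY_MAP).items()
               if k in ("clint", "vmax", "km")},
        )
        for p in norm.pop("pathways", []) or []
    ]
    met_name = norm.pop("metabolite", None)
    record = DrugRecord(pathways=pathways, metabolite_name=met_name, **norm)
    if with_metabolite and met_name:
        record.metabolite = load_drug(met_name, with_metabolite=False)
    return record


def _drug_to_raw(record: DrugRecord) -> dict:
    inverse = {canonical: (key, factor) for key, (canonical, factor) in _DRUG_KEY_MAP.items()}
    raw: dict = {"schema": DRUG_SCHEMA}
    for f_ in dataclasses.fields(record):
        name = f_.name
        if name in ("pathways", "metabolite", "metabolite_name"):
            continue
        value = getattr(record, name)
        if value is None:
            continue
        if name in inverse:
            key, factor = inverse[name]
            raw[key] = value / factor
        else:
            raw[name] = value
    raw["pathways"] = []
    for p in record.pathways:
        entry: dict = {"enzyme": p.enzyme}
        if p.clint is not None:
            entry["clint_ml_min"] = p.clint
        if p.vmax is not None:
            entry["vmax_nmol_min_mg"] = p.vmax
            entry["km_umol_l"] = p.km
        if p.produces:
            entry["produces"] = p.produces
        raw["pathways"].append(entry)
    if record.metabolite_name:
        raw["metabolite"] = record.metabolite_name
    return raw


def write_drug(record: DrugRecord, path) -> None:
    """Serialize a compound record; ``load_drug`` round-trips every field."""
    Path(path).write_text(yaml.safe_dump(_drug_to_raw(record), sort_keys=False))


def write_physiology(populations: dict[str, PhysiologySet], path) -> None:
    pops = {}
    for label, p in populations.items():
        pops[label] = {
            "q_l_ml_min": p.q_l,
            "q_la_ml_min": p.q_la,
            "q_pv_ml_min": p.q_pv,
            "q_k_ml_min": p.q_k,
            "q_gw_ml_min": dict(zip(GUT_SEGMENTS, p.q_gw)),
            "v_liver_ml": p.v_liver,
            "v_pv_ml": p.v_pv,
            "v_k_ml": p.v_k,
            "v_gw_ml": dict(zip(GUT_SEGMENTS, p.v_gw)),
            "k_t_per_min": dict(zip(("stomach",) + GUT_SEGMENTS, p.k_t)),
            "r_cm": dict(zip(GUT_SEGMENTS, p.r)),
            "gfr_ml_min": p.gfr,
            "albumin_g_l": p.albumin,
            "agp_g_l": p.agp,
            "ces1_mg_g_liver": p.ces1_content,
            "cyp2b6_pmol_mg": p.cyp2b6_content,
            "lr_ratio": p.lr_ratio,
            "mrp2_ratio": p.mrp2_ratio,
        }
    Path(path).write_text(
        yaml.safe_dump({"schema": PHYSIOLOGY_SCHEMA, "populations": pops}, sort_keys=False)
    )
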