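"""Virtual-population engine: independent uniform 80–120% perturbation of
the listed ADME parameters, batch simulation, and pointwise 5th/95th
percentile + mean summaries.

Each virtual individual gets its own counter-based random substream derived
from (seed, index), so a population is reproducible and order-independent:
individual *i* is identical whether simulated alone or inside a batch.
Perturbation is applied *after* any cirrhosis translation, mirroring the
translate-then-randomize workflow of the underlying study design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import SimOptions, SimulationResult, build_system, simulate
from .metrics import summarize
from .parameters import DoseRegimen, DrugRecord, PhysiologySet, ValidationError
from .translate import TranslatedParameters

__all__ = ["PopulationSpec", "PopulationResult", "sample_individual",
           "simulate_population"]


@dataclass
class PopulationSpec:
    """Monte-Carlo specification: n individuals, multiplier range, seed."""

    n: int = 1000
    low: float = 0.8
    high: float = 1.2
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.low <= self.high:
            raise ValidationError("low", f"need 0 < low <= high, got ({self.low}, {self.high})")
        if self.n < 1:
            raise ValidationError("n", f"need n >= 1, got {self.n}")


def _perturb_record(rec: DrugRecord, rng: np.random.Generator,
                    low: float, high: float) -> None:
    """Multiply the variability-bearing parameters of one record in place."""
    def draw() -> float:
        return float(rng.uniform(low, high))

    for pw in rec.pathways:
        if pw.clint is not None:
            pw.clint *= draw()
        else:
            pw.vmax *= draw()
    if rec.clint_k:
        rec.clint_k *= draw()
    rec.fu_b = min(1.0, rec.fu_b * draw())
    rec.v_sys *= draw()
    if rec.peff is not None:
        rec.peff *= draw()
    if rec.ka is not None:
        rec.ka *= draw()
    rec.k_lp *= draw()
    rec.k_gp *= draw()
    rec.k_kp *= draw()


def sample_individual(base, spec: PopulationSpec, index: int) -> DrugRecord:
    """One virtual individual's parameter set.

    Every listed parameter (hepatic pathway CLint/Vmax, renal CLint, fu_b,
    V_sys, Peff/ka, and the three partition coefficients) of the parent and
    of its tracked metabolite is multiplied by an independent uniform draw
    in [low, high]; fu_b is capped at 1.  Deterministic in (seed, index).
    """
    if isinstance(base, TranslatedParameters):
        base = base.drug
    rec = base.copy()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(index,)))
    _perturb_record(rec, rng, spec.low, spec.high)
    if rec.metabolite is not None:
        _perturb_record(rec.metabolite, rng, spec.low, spec.high)
    return rec


@dataclass
class PopulationResult:
    """Pointwise percentile bands, mean curves and per-individual metrics."""

    t: np.ndarray
    mean: dict  # analyte -> ng/mL
    p5: dict
    p95: dict
    summaries: pd.DataFrame  # per (individual, analyte) NCA metrics
    base: SimulationResult
    n_resampled: int = 0
    failures: list = field(default_factory=list)


def simulate_population(drug, phys: PhysiologySet, regimen: DoseRegimen,
                        spec: PopulationSpec, t_end: float, grid=None,
                        options: SimOptions | None = None,
                        t_last: float | None = None) -> PopulationResult:
    """Simulate ``spec.n`` virtual individuals and summarize the curves.

    An individual whose integration fails is logged and replaced by a fresh
    draw (indices beyond ``n``), so the output always holds ``n`` subjects.
    """
    options = options or SimOptions()
    base_sys = build_system(drug, phys, regimen, options)
    base_res = simulate(base_sys, t_end, grid=grid, options=options)
    analytes = list(base_res.conc)

    curves = {a: np.empty((spec.n, base_res.t.size)) for a in analytes}
    rows = []
    failures: list[str] = []
    next_extra = spec.n
    for i in range(spec.n):
        index = i
        while True:
            indiv = sample_individual(drug, spec, index)
            try:
                res = simulate(build_system(indiv, phys, regimen, options),
                               t_end, grid=base_res.t, options=options)
                break
            except RuntimeError as exc:
                failures.append(f"individual {index}: {exc}")
                index, next_extra = next_extra, next_extra + 1
        for a in analytes:
            curves[a][i] = res.conc[a]
            s = summarize(res, a, t_last=t_last)
            rows.append({"individual": i, "analyte": a, "auc0_t": s.auc0_t,
                         "auc0_inf": s.auc0_inf, "cmax": s.cmax,
                         "tmax": s.tmax, "cl": s.cl})

    return PopulationResult(
        t=base_res.t,
        mean={a: curves[a].mean(axis=0) for a in analytes},
        p5={a: np.percentile(curves[a], 5, axis=0) for a in analytes},
        p95={a: np.percentile(curves[a], 95, axis=0) for a in analytes},
        summaries=pd.DataFrame(rows),
        base=base_res,
        n_resampled=len(failures),
        failures=failures,
    )
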