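"""Non-compartmental summary of simulated profiles and cirrhosis exposure
ratios (AUCR, CmaxR) with the 0.5–2-fold / 0.8–1.25-fold acceptance flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .engine import SimulationResult
from .parameters import ValidationError

__all__ = ["PKSummary", "auc", "auc_inf", "summarize", "aucr", "cl_ratio",
           "cmaxr", "fold_check"]

#: ng/mL·min -> µg·h/mL
_NG_MIN_TO_UG_H = 1.0 / 1000.0 / 60.0


@dataclass
class PKSummary:
    """AUC (µg·h/mL), Cmax (ng/mL), Tmax (min) and, for i.v. doses, total
    clearance CL = dose/AUC0–∞ (L/min)."""

    analyte: str
    dose_mg: float
    t_last: float  # min
    auc0_t: float  # µg·h/mL
    auc0_inf: Optional[float]  # µg·h/mL
    cmax: float  # ng/mL
    tmax: float  # min
    cl: Optional[float] = None  # L/min, i.v. only

    def __post_init__(self):
        if self.auc0_inf is not None and self.auc0_t > self.auc0_inf * (1 + 1e-9):
            raise ValidationError("auc0_inf", "AUC0–t cannot exceed AUC0–∞")


def auc(t: np.ndarray, c: np.ndarray, t_last: float | None = None,
        method: str = "linear") -> float:
    """Trapezoidal AUC to ``t_last`` in µg·h/mL (``t`` min, ``c`` ng/mL).

    ``method='linear'`` (default) is the plain linear trapezoid;
    ``'linuplogdown'`` uses the log trapezoid on strictly decreasing
    positive segments.
    """
    t = np.asarray(t, float)
    c = np.asarray(c, float)
    if t_last is not None:
        keep = t <= t_last + 1e-9
        t, c = t[keep], c[keep]
    if t.size < 2:
        return 0.0
    if method == "linear":
        total = float(np.trapezoid(c, t))
    elif method == "linuplogdown":
        dt = np.diff(t)
        c1, c2 = c[:-1], c[1:]
        lin = (c1 + c2) / 2 * dt
        down = (c2 < c1) & (c2 > 0) & (c1 > 0)
        log_seg = (c1 - c2) / np.log(c1 / np.where(down, c2, 1.0), where=down,
                                     out=np.ones_like(c1)) * dt
        total = float(np.sum(np.where(down, log_seg, lin)))
    else:
        raise ValidationError("method", f"unknown AUC method {method!r}")
    return total * _NG_MIN_TO_UG_H


def _lambda_z(t: np.ndarray, c: np.ndarray, n_points: int = 3) -> float | None:
    pos = c > 0
    t, c = t[pos], c[pos]
    if t.size < n_points:
        return None
    slope = np.polyfit(t[-n_points:], np.log(c[-n_points:]), 1)[0]
    return -slope if slope < 0 else None


def auc_inf(t: np.ndarray, c: np.ndarray, method: str = "linear") -> float | None:
    """AUC extrapolated to infinity with a log-linear tail fit on the last
    three positive points; ``None`` when no declining tail exists."""
    t = np.asarray(t, float)
    c = np.asarray(c, float)
    lz = _lambda_z(t, c)
    if lz is None:
        return None
    c_last = c[c > 0][-1]
    return auc(t, c, method=method) + c_last / lz * _NG_MIN_TO_UG_H


def summarize(result: SimulationResult, analyte: str, t_last: float | None = None,
              dose_mg: float | None = None) -> PKSummary:
    """Non-compartmental summary of one simulated analyte."""
    if analyte not in result.conc:
        raise ValidationError("analyte", f"{analyte!r} not in simulation output "
                                         f"{sorted(result.conc)}")
    t = result.t
    c = result.conc[analyte]
    t_last = float(t[-1]) if t_last is None else float(t_last)
    dose = result.dose_mg if dose_mg is None else dose_mg
    a_t = auc(t, c, t_last)
    a_inf = auc_inf(t, c)
    if a_inf is not None and a_inf < a_t:
        a_inf = a_t  # numerically flat tail
    i_max = int(np.argmax(c))
    cl = None
    if result.system.regimen.route in ("iv_bolus", "iv_infusion") and a_inf:
        cl = dose / a_inf / 60.0  # mg/(µg·h/mL) = L/h -> L/min
    return PKSummary(analyte=analyte, dose_mg=dose, t_last=t_last, auc0_t=a_t,
                     auc0_inf=a_inf, cmax=float(c[i_max]), tmax=float(t[i_max]),
                     cl=cl)


def aucr(auc_ci: float, auc_ht: float, dose_ci: float | None = None,
         dose_ht: float | None = None) -> float:
    """Cirrhosis/healthy AUC ratio, dose-normalized when doses differ."""
    if dose_ci is not None and dose_ht is not None:
        return (auc_ci / dose_ci) / (auc_ht / dose_ht)
    return auc_ci / auc_ht


def cl_ratio(cl_ht: float, cl_ci: float) -> float:
    """AUCR computed from clearances (healthy/cirrhosis); equals the
    dose-normalized AUC ratio for linear i.v. kinetics."""
    return cl_ht / cl_ci


def cmaxr(cmax_ci: float, cmax_ht: float, dose_ci: float | None = None,
          dose_ht: float | None = None) -> float:
    """Cirrhosis/healthy Cmax ratio, dose-normalized when doses differ."""
    if dose_ci is not None and dose_ht is not None:
        return (cmax_ci / dose_ci) / (cmax_ht / dose_ht)
    return cmax_ci / cmax_ht


def fold_check(pred: float, obs: float) -> tuple[bool, bool]:
    """(within 0.5–2-fold, within the stricter 0.8–1.25-fold band) of
    obs/pred."""
    if pred <= 0 or obs <= 0:
        raise ValidationError("fold_check", "predictions and observations must be > 0")
    ratio = obs / pred
    return 0.5 <= ratio <= 2.0, 0.8 <= ratio <= 1.25
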