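"""Retrograde enzyme-specific intrinsic clearance and forward hepatic clearance.

The retrograde calculation inverts an observed systemic clearance into
per-enzyme unbound intrinsic clearances (uL/min/pmol enzyme), splitting the
hepatic component across CYP pathways by their fractional contribution and
normalising by liver weight, microsomal protein yield (MPPGL) and enzyme
abundance.  The forward direction recombines those into a whole-liver CLint
and applies the hepatic well-stirred model.

Basis note.  The printed retrograde expression normalises (CLiv - CLR) and fu
by the blood:plasma ratio, but the reference forward clearances are
reproduced exactly by the plasma-basis well-stirred form
CL_H = Q_H*fu*CLint/(Q_H + fu*CLint).  The package therefore stores CLint on
the plasma basis by default (``basis="plasma"``), which makes the
retrograde->forward round trip recover CLiv - CLR to machine precision; the
verbatim blood-normalised form is available as ``basis="blood"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .errors import ValidationError

#: uL/min -> L/h
UL_MIN_TO_L_H = 60.0e-6


@dataclass(frozen=True)
class RetrogradeInput:
    """Inputs for the retrograde intrinsic-clearance calculation (one compound)."""

    cl_iv: float                         # L/h, plasma
    cl_renal: float                      # L/h, plasma
    fu: float
    blood_plasma_ratio: float
    hepatic_blood_flow: float            # L/h
    percent_hepatic_by_enzyme: Mapping[str, float]   # enzyme -> % of hepatic CL
    liver_weight: float = 1650.0         # g
    mppgl: float = 40.0                  # mg microsomal protein / g liver
    abundance_by_enzyme: Mapping[str, float] = field(default_factory=dict)  # pmol/mg
    isef_by_enzyme: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not 0 < self.fu <= 1:
            raise ValidationError(f"fu must be in (0,1], got {self.fu}")
        if self.cl_renal > self.cl_iv:
            raise ValidationError("cl_renal exceeds cl_iv")

    def isef(self, enzyme: str) -> float:
        return self.isef_by_enzyme.get(enzyme, 1.0)


def _hepatic_clearance_on_basis(inp: RetrogradeInput, basis: str) -> tuple[float, float]:
    """(CL_H, fu) expressed on the requested concentration basis."""
    cl_h = inp.cl_iv - inp.cl_renal
    if basis == "plasma":
        return cl_h, inp.fu
    if basis == "blood":
        return cl_h / inp.blood_plasma_ratio, inp.fu / inp.blood_plasma_ratio
    raise ValidationError(f"unknown basis {basis!r}")


def retrograde_clint(inp: RetrogradeInput, basis: str = "plasma"
                     ) -> dict[str, float]:
    """Per-enzyme unbound intrinsic clearance, uL/min/pmol enzyme.

    CLint_e = (%_e/100) * Q_H*CL_H / [fu*(Q_H - CL_H)]
              / (LW * MPPGL * abundance_e * 60e-6) / ISEF_e
    with CL_H and fu on the chosen basis.  Raises if the systemic clearance
    is infeasible for the well-stirred model (CL_H >= Q_H).
    """
    cl_h, fu = _hepatic_clearance_on_basis(inp, basis)
    q_h = inp.hepatic_blood_flow
    if cl_h >= q_h:
        raise ValidationError(
            f"well-stirred infeasibility: hepatic clearance {cl_h:.3f} L/h "
            f"(basis={basis}) is not below hepatic blood flow {q_h:.3f} L/h")
    clint_whole_liver = q_h * cl_h / (fu * (q_h - cl_h))    # L/h, whole liver
    out = {}
    for enzyme, pct in inp.percent_hepatic_by_enzyme.items():
        abundance = inp.abundance_by_enzyme.get(enzyme)
        if abundance is None:
            raise ValidationError(f"no abundance supplied for enzyme {enzyme}")
        scale = inp.liver_weight * inp.mppgl * abundance * UL_MIN_TO_L_H
        out[enzyme] = (pct / 100.0) * clint_whole_liver / scale / inp.isef(enzyme)
    return out


def retrograde_residual_clint(inp: RetrogradeInput, basis: str = "plasma") -> float:
    """Whole-liver CLint (L/h) of the hepatic clearance NOT assigned to a CYP.

    The enzyme percentages may sum below 100%; the remainder is carried as an
    unassigned (non-CYP) hepatic intrinsic clearance so that the retrograde ->
    forward round trip remains an exact identity.
    """
    cl_h, fu = _hepatic_clearance_on_basis(inp, basis)
    q_h = inp.hepatic_blood_flow
    if cl_h >= q_h:
        raise ValidationError("well-stirred infeasibility")
    assigned = sum(inp.percent_hepatic_by_enzyme.values())
    share = max(0.0, 1.0 - assigned / 100.0)
    return share * q_h * cl_h / (fu * (q_h - cl_h))


def scale_to_whole_liver(clint_by_enzyme: Mapping[str, float],
                         abundance_by_enzyme: Mapping[str, float],
                         mppgl: float, liver_weight: float,
                         isef_by_enzyme: Mapping[str, float] | None = None) -> float:
    """Whole-liver intrinsic clearance, L/h, from per-pmol enzyme clearances.

    Sum over enzymes of clint * ISEF * abundance * MPPGL * LW * 60e-6; an
    enzyme with zero abundance (e.g. a CYP2D6 poor metabolizer) contributes 0.
    """
    isef_by_enzyme = isef_by_enzyme or {}
    total = 0.0
    for enzyme, clint in clint_by_enzyme.items():
        abundance = abundance_by_enzyme.get(enzyme, 0.0)
        total += (clint * isef_by_enzyme.get(enzyme, 1.0) * abundance
                  * mppgl * liver_weight * UL_MIN_TO_L_H)
    return total


def well_stirred_hepatic_clearance(clint_total: float, fu: float, q_h: float) -> float:
    """Hepatic well-stirred model, CL_H = Q_H*fu*CLint/(Q_H + fu*CLint)."""
    if clint_total < 0 or fu <= 0 or q_h <= 0:
        raise ValidationError("clint, fu and q_h must be positive")
    return q_h * fu * clint_total / (q_h + fu * clint_total)


def extraction_ratio(cl_h: float, q_h: float) -> float:
    """Hepatic extraction ratio E = CL_H/Q_H."""
    if not 0 <= cl_h <= q_h:
        raise ValidationError(
            f"cl_h must lie in [0, q_h]; got cl_h={cl_h}, q_h={q_h}")
    return cl_h / q_h


#: healthy-population reference GFR ratio used for renal clearance scaling
HEALTHY_GFR_RATIO = 0.99


def scale_renal_clearance(cl_r_healthy: float, renal_function_ratio: float,
                          healthy_ratio: float = HEALTHY_GFR_RATIO) -> float:
    """Scale renal clearance in proportion to the GFR ratio."""
    if renal_function_ratio < 0:
        raise ValidationError("renal_function_ratio must be >= 0")
    return cl_r_healthy * renal_function_ratio / healthy_ratio


def retrograde_report(inp: RetrogradeInput, basis: str = "plasma"):
    """DataFrame: enzyme, clint (uL/min/pmol), whole-liver L/h contribution."""
    import pandas as pd

    clint = retrograde_clint(inp, basis=basis)
    rows = []
    for enzyme, value in clint.items():
        contribution = scale_to_whole_liver(
            {enzyme: value}, inp.abundance_by_enzyme, inp.mppgl, inp.liver_weight,
            inp.isef_by_enzyme)
        rows.append({"enzyme": enzyme, "clint_ul_min_pmol": value,
                     "whole_liver_l_h": contribution})
    return pd.DataFrame(rows)
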