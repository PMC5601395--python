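"""Simvastatin pharmacokinetics and LDL pharmacodynamics.

PK: first-order absorption from a gut depot into a parent (simvastatin)
compartment, complete first-order conversion to the active metabolite
(simvastatin acid), first-order elimination of the metabolite.  All amounts
in mg; apparent clearances/volumes in L/hr and L, so every rate constant is
CL/V in 1/hr.

PD: an inhibitory indirect-response (turnover) model on circulating LDL,
driven by the metabolite concentration C_met (ng/mL):

    dLDL/dt = K_in·(1 − E(C_met)) − K_out·LDL,   E = Emax·C/(EC50 + C),

with K_out = K_in/LDL_baseline so the drug-free steady state is exactly the
baseline.  The maximal achievable steady-state reduction is the fraction
Emax of baseline.
"""

from __future__ import annotations

from typing import NamedTuple

from .params import PKPDParams

__all__ = ["PKState", "PKDerivatives", "metabolite_concentration", "pk_derivatives", "drug_effect", "ldl_derivative"]


class PKState(NamedTuple):
    """Drug amounts (mg) and circulating LDL (nmol/L)."""

    A_gut: float
    A_parent: float
    A_met: float
    LDL_plasma: float


class PKDerivatives(NamedTuple):
    dA_gut: float
    dA_parent: float
    dA_met: float


def metabolite_concentration(A_met: float, p: PKPDParams) -> float:
    """Metabolite plasma concentration in ng/mL: 1000·A_met/V3 (mg and L in)."""
    return 1000.0 * A_met / p.V3


def pk_derivatives(s: PKState, p: PKPDParams) -> PKDerivatives:
    """Amount derivatives (mg/h) of the depot → parent → metabolite chain."""
    if s.A_gut < 0 or s.A_parent < 0 or s.A_met < 0:
        raise ValueError(f"drug amounts must be nonnegative, got {tuple(s)!r}")
    k_parent = p.CL2 / p.V2
    k_met = p.CL3 / p.V3
    dA_gut = -p.Ka * s.A_gut
    dA_parent = p.Ka * s.A_gut - k_parent * s.A_parent
    dA_met = k_parent * s.A_parent - k_met * s.A_met
    return PKDerivatives(dA_gut, dA_parent, dA_met)


def drug_effect(C_met: float, Emax: float, EC50: float) -> float:
    """Fractional inhibition of LDL production: E = Emax·C/(EC50 + C) ∈ [0, Emax]."""
    if C_met < 0:
        raise ValueError(f"metabolite concentration must be >= 0, got {C_met!r}")
    if not 0.0 <= Emax <= 1.0 or EC50 <= 0:
        raise ValueError("need 0 <= Emax <= 1 and EC50 > 0")
    return Emax * C_met / (EC50 + C_met)


def ldl_derivative(LDL: float, E: float, p: PKPDParams) -> float:
    """Turnover-model derivative of circulating LDL (nmol/L/h)."""
    if LDL < 0:
        raise ValueError(f"LDL must be >= 0, got {LDL!r}")
    if not 0.0 <= E <= 1.0:
        raise ValueError(f"fractional inhibition must lie in [0, 1], got {E!r}")
    return p.K_in * (1.0 - E) - p.K_out * LDL
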