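"""Kedem–Katchalsky transendothelial transport with WSS-modulated conductivity.

The endothelium is a semipermeable membrane carrying a filtration (volume)
flux Jv = Lp·(Δp − σΔΠ) and a solute flux Js = P0·Δc + (1−σ)·Jv·c̄, the
standard coupled volume/solute description from irreversible thermodynamics.
Low wall shear stress opens intercellular junctions; this is represented by a
monotone non-increasing hydraulic conductivity Lp(τ) that decays from Lp_ref
at stagnation to a configurable floor at high shear.

These functions are pure algebra and unit-agnostic in time: feed per-second
(or per-hour) conductivities and permeabilities and the fluxes come out per
second (or per hour).
"""

from __future__ import annotations

__all__ = ["transmural_velocity", "ldl_flux", "hydraulic_conductivity"]


def transmural_velocity(Lp: float, dp: float, sigma: float, osmotic_term: float = 0.0) -> float:
    """Filtration velocity Jv = Lp·(Δp − σΔΠ).

    ``osmotic_term`` is the lumped σΔΠ value (Pa).  A negative result (reverse
    filtration) is returned as-is; clamping is caller policy.
    """
    if Lp < 0:
        raise ValueError(f"hydraulic conductivity must be >= 0, got {Lp!r}")
    return Lp * (dp - osmotic_term)


def ldl_flux(P0: float, dc: float, Jv: float, sigma: float, cbar: float) -> float:
    """Solute flux per unit endothelial area: Js = P0·Δc + (1−σ)·Jv·c̄.

    ``cbar`` is the mean of the lumen-side and wall-side concentrations; with
    σ = 1 convection is fully reflected and only the diffusive term remains.
    """
    if P0 < 0:
        raise ValueError(f"diffusive permeability must be >= 0, got {P0!r}")
    if cbar < 0:
        raise ValueError(f"mean membrane concentration must be >= 0, got {cbar!r}")
    return P0 * dc + (1.0 - sigma) * Jv * cbar


def hydraulic_conductivity(
    tau: float, Lp_ref: float, tau0: float, floor_fraction: float
) -> float:
    """Shear-dependent hydraulic conductivity.

    Lp(τ) = Lp_ref · (f + (1−f)·τ0/(τ0+τ)) with floor fraction f, so
    Lp(0) = Lp_ref, Lp(τ0) = Lp_ref·(1+f)/2 and Lp(∞) = f·Lp_ref.  Monotone
    non-increasing in τ: high shear protects, stagnation renders the wall
    leaky (atheroprone).
    """
    if tau < 0:
        raise ValueError(f"wall shear stress must be >= 0, got {tau!r}")
    if not 0.0 <= floor_fraction <= 1.0:
        raise ValueError(f"floor_fraction must lie in [0, 1], got {floor_fraction!r}")
    if Lp_ref < 0 or tau0 <= 0:
        raise ValueError("Lp_ref must be >= 0 and tau0 > 0")
    return Lp_ref * (floor_fraction + (1.0 - floor_fraction) * tau0 / (tau0 + tau))
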