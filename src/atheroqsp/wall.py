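"""Well-mixed compartment model of inflammation inside the arterial wall.

The spatially resolved convection–diffusion–reaction transport of LDL through
the intima is reduced to a single well-mixed compartment.  Five species are
tracked: native LDL (L_w, nmol/L of wall tissue), oxidized LDL (Lox, nmol/L),
monocytes (m), macrophages (M) and foam cells (F), the last three as number
densities (cells/m³).  The cascade is

* LDL enters across the endothelium (flux Js per unit area) and is oxidized
  at first-order rate r_w;
* ox-LDL recruits circulating monocytes (saturating in Lox, suppressed by
  wall shear stress), which differentiate to macrophages at rate ρ1;
* macrophages ingest ox-LDL and convert to foam cells; each conversion
  consumes ``eta`` ox-LDL particles and one macrophage;
* every species carries its own first-order clearance (d_m, d_M, d_F, d_lox),
  the compartmental stand-in for the advective/diffusive loss pathways of the
  original transport equation.

All functions are time-unit agnostic: pass rates in 1/h (the engine's
convention) and derivatives come out per hour.
"""

from __future__ import annotations

from typing import NamedTuple

from .params import PARTICLES_PER_NMOL_L, AtheroRates

__all__ = ["WallState", "WallDerivatives", "WallGeometry", "monocyte_recruitment", "wall_derivatives"]


class WallState(NamedTuple):
    """Species densities inside the wall compartment."""

    L_w: float   # native LDL, nmol/L
    Lox: float   # oxidized LDL, nmol/L
    m: float     # monocytes, cells/m³
    M: float     # macrophages, cells/m³
    F: float     # foam cells, cells/m³


class WallDerivatives(NamedTuple):
    dL_w: float
    dLox: float
    dm: float
    dM: float
    dF: float


class WallGeometry(NamedTuple):
    """Endothelial exchange area and compartment volume (SI)."""

    S_endo: float   # m², endothelial surface
    V_wall: float   # m³, wall compartment volume


def monocyte_recruitment(
    tau: float,
    Lox: float,
    rec_max: float,
    K_Lox: float,
    tau_half: float,
    chi: float,
) -> float:
    """Monocyte recruitment flux across the endothelium (cells per area per time).

    rec = χ · rec_max · Lox/(Lox + K_Lox) · 1/(1 + τ/τ_half):
    saturating Michaelis form in the inflammatory stimulus (ox-LDL) and
    hyperbolically suppressed by wall shear stress, reproducing the
    localization of lesions to low-shear regions.  Zero without ox-LDL.
    """
    if min(tau, Lox, rec_max, K_Lox, tau_half, chi) < 0:
        raise ValueError("all recruitment arguments must be >= 0")
    if Lox == 0.0:
        return 0.0
    return chi * rec_max * (Lox / (Lox + K_Lox)) / (1.0 + tau / tau_half)


def wall_derivatives(
    ws: WallState,
    p: AtheroRates,
    Js: float,
    tau: float,
    geometry: WallGeometry,
) -> WallDerivatives:
    """Time derivatives of the five wall species.

    ``Js`` is the endothelial LDL flux per unit area ((nmol/L)·m per time) and
    ``tau`` the current wall shear stress (Pa).  Foam-cell production follows
    mass-action ingestion k_m·M·Lox_p scaled by the per-cell particle quota
    eta; the same ingestion term, converted back to nmol/L, depletes ox-LDL,
    and each conversion consumes one macrophage.
    """
    L_w, Lox, m, M, F = ws
    if min(ws) < 0:
        raise ValueError(f"wall state must be nonnegative, got {tuple(ws)!r}")

    sv = geometry.S_endo / geometry.V_wall  # 1/m, area-to-volume of the compartment

    uptake_conc = p.k_m * M * Lox                    # nmol/L per time, ox-LDL ingested
    foam_production = uptake_conc * PARTICLES_PER_NMOL_L / p.eta  # cells/m³ per time

    rec = monocyte_recruitment(tau, Lox, p.rec_max, p.K_Lox, p.tau_half, p.chi)

    dL_w = Js * sv - p.r_w * L_w
    dLox = p.r_w * L_w - uptake_conc - p.d_lox * Lox
    dm = rec * sv * p.m_lumen_scale - p.rho1 * m - p.d_m * m
    dM = p.rho1 * m - foam_production - p.d_M * M
    dF = foam_production - p.d_F * F
    return WallDerivatives(dL_w, dLox, dm, dM, dF)
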