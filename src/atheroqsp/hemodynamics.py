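"""Quasi-steady Poiseuille hemodynamics in an idealized cylindrical segment.

Blood is treated as Newtonian and the flow as fully developed and steady, so
the wall shear stress (WSS) follows the closed form τ = 4μQ/(πR³).  Plaque
material protruding into the lumen is redistributed as a uniform annulus over
the segment, which gives an exact algebraic map between intruded volume and
lumen radius.  All quantities here are SI (m, m³/s, Pa·s, Pa).
"""

from __future__ import annotations

import math

__all__ = ["wall_shear_stress", "lumen_radius_from_intrusion", "OcclusionError"]


class OcclusionError(ValueError):
    """Raised when the intruding plaque volume fills the entire lumen."""


def wall_shear_stress(mu: float, Q: float, R: float) -> float:
    """WSS of steady Poiseuille flow: τ = 4μQ/(πR³).

    Parameters
    ----------
    mu : blood dynamic viscosity (Pa·s), > 0.
    Q : volumetric flow rate (m³/s), >= 0.
    R : lumen radius (m), > 0.

    Returns
    -------
    Wall shear stress in Pa.
    """
    if mu <= 0:
        raise ValueError(f"viscosity must be > 0, got {mu!r}")
    if R <= 0:
        raise ValueError(f"lumen radius must be > 0, got {R!r}")
    if Q < 0:
        raise ValueError(f"flow must be >= 0, got {Q!r}")
    return 4.0 * mu * Q / (math.pi * R**3)


def lumen_radius_from_intrusion(R0: float, L: float, V_intrude: float) -> float:
    """Lumen radius after an annular volume ``V_intrude`` displaces the lumen.

    Inverts the annulus-volume relation πL(R0² − R²) = V_intrude, i.e.
    R = sqrt(R0² − V_intrude/(πL)).  Raises :class:`OcclusionError` when the
    intruded volume reaches the full lumen volume πR0²L.
    """
    if R0 <= 0 or L <= 0:
        raise ValueError("R0 and L must be > 0")
    if V_intrude < 0:
        raise ValueError(f"intruded volume must be >= 0, got {V_intrude!r}")
    lumen_volume = math.pi * R0**2 * L
    if V_intrude >= lumen_volume:
        raise OcclusionError(
            f"intruded volume {V_intrude:g} m³ >= lumen volume {lumen_volume:g} m³"
        )
    return math.sqrt(R0**2 - V_intrude / (math.pi * L))
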