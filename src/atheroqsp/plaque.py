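"""Plaque volume bookkeeping and the Constant-Volume → Plaque-Growing event.

The wall has a finite interstitial capacity, the fraction ``phi`` of its
initial volume, that infiltrating cells and accumulated lipid can fill
without deforming the vessel.  While the occupied volume stays below that
capacity the artery is in the *ConstantVolume* phase; once it exceeds it the
model switches — a discrete, irreversible event — to *PlaqueGrowing*, and
every unit of excess volume intrudes into the lumen (inward remodeling),
narrowing it.

Occupied volume has two parts: the live cellular load (monocytes,
macrophages, foam cells, each with a fixed unit volume) and an irreversibly
accumulating extracellular lipid/necrotic pool fed by cleared foam cells —
the compartment that gives the lesion its multi-year memory.

The clinical endpoint is %TAV, the percent change of total atheroma volume
(wall volume plus lumen intrusion) relative to its initial value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .params import AtheroRates
from .wall import WallState

__all__ = [
    "PlaqueState",
    "occupied_volume",
    "growth_event_value",
    "percent_tav",
    "core_accumulation_rate",
]


@dataclass(frozen=True)
class PlaqueState:
    """Volume bookkeeping of the lesion at one time point."""

    phase: str                    # "ConstantVolume" or "PlaqueGrowing"
    V_occupied: float             # m³, total species + core volume
    V_capacity: float             # m³, phi · initial wall volume
    V_atheroma: float             # m³, wall volume + lumen intrusion
    transition_time: Optional[float] = None  # h, first capacity crossing

    def __post_init__(self) -> None:
        if self.phase not in ("ConstantVolume", "PlaqueGrowing"):
            raise ValueError(f"unknown plaque phase {self.phase!r}")


def occupied_volume(
    ws: WallState, p: AtheroRates, V_wall: float, V_core: float = 0.0
) -> float:
    """Volume taken up inside the wall by cells and retained lipid (m³).

    Linear in every species: V = V_wall·(v_mono·m + v_mac·M + v_foam·F) +
    V_core.  The volume of dissolved LDL itself is negligible at these
    concentrations and is not counted.
    """
    if min(ws) < 0 or V_core < 0:
        raise ValueError("species densities and core volume must be nonnegative")
    cell_fraction = p.v_mono * ws.m + p.v_mac * ws.M + p.v_foam * ws.F
    return V_wall * cell_fraction + V_core


def core_accumulation_rate(F: float, p: AtheroRates, V_wall: float) -> float:
    """Growth rate of the extracellular lipid/necrotic pool (m³ per time).

    Foam cells cleared at rate d_F deposit the retained fraction of their
    volume into the pool instead of vanishing: dV_core/dt =
    retention · v_foam · d_F · F · V_wall.  This is the only irreversible
    volume source in the model.
    """
    if F < 0:
        raise ValueError(f"foam-cell density must be >= 0, got {F!r}")
    return p.core_retention * p.v_foam * p.d_F * F * V_wall


def growth_event_value(ps: PlaqueState) -> float:
    """Signed distance to the phase-transition surface: V_occupied − V_capacity.

    The integrator locates the zero upcrossing of this function as the
    discrete Constant-Volume → Plaque-Growing event.
    """
    return ps.V_occupied - ps.V_capacity


def percent_tav(V_atheroma_t: float, V_atheroma_0: float) -> float:
    """Percent change of total atheroma volume: 100·(V_t − V_0)/V_0."""
    if V_atheroma_0 <= 0:
        raise ValueError(f"initial atheroma volume must be > 0, got {V_atheroma_0!r}")
    return 100.0 * (V_atheroma_t - V_atheroma_0) / V_atheroma_0
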