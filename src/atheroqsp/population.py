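"""Virtual populations: parameter sampling and between-patient spread.

Patient-to-patient variability is introduced by drawing a designated subset
of kinetic parameters independently from log-normal distributions whose
median equals the typical-patient value and whose coefficient of variation
is configurable.  Log-normal sampling preserves positivity, the invariant
every rate and concentration must satisfy.

The default varied subset spans the lipid, inflammatory and recruitment
axes of the model: {k_m, r_w, rec_max, m_lumen, LDL_baseline}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .engine import SimulationResult
from .params import AtheroParams, PKPDParams

__all__ = [
    "PopulationSpec",
    "DEFAULT_VARIED_PARAMS",
    "sample_population",
    "growth_spread",
    "transition_times",
]

DEFAULT_VARIED_PARAMS: tuple[str, ...] = ("k_m", "r_w", "rec_max", "m_lumen", "LDL_baseline")

_ATHERO_FIELDS = set(AtheroParams.model_fields)
_PKPD_FIELDS = set(PKPDParams.model_fields)


@dataclass(frozen=True)
class PopulationSpec:
    """A seeded recipe for a virtual patient population."""

    base_athero: AtheroParams
    base_pkpd: PKPDParams
    n: int = 50
    cv: float = 0.25
    varied: Sequence[str] = DEFAULT_VARIED_PARAMS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError(f"population size must be >= 0, got {self.n!r}")
        if self.cv < 0:
            raise ValueError(f"cv must be >= 0, got {self.cv!r}")
        unknown = [f for f in self.varied if f not in _ATHERO_FIELDS | _PKPD_FIELDS]
        if unknown:
            raise ValueError(f"unknown parameter(s) to vary: {unknown}")


def sample_population(spec: PopulationSpec) -> list[tuple[AtheroParams, PKPDParams]]:
    """Draw ``n`` parameter bundles.

    Each varied parameter is multiplied by exp(s·Z) with Z standard normal
    and s = sqrt(ln(1 + cv²)), i.e. a log-normal with median at the base
    value and the requested CV.  Fixed seed ⇒ bit-identical resample.
    """
    rng = np.random.default_rng(spec.seed)
    s = math.sqrt(math.log1p(spec.cv**2))
    bundles: list[tuple[AtheroParams, PKPDParams]] = []
    for _ in range(spec.n):
        athero_up: dict[str, float] = {}
        pkpd_up: dict[str, float] = {}
        for name in spec.varied:
            factor = math.exp(s * rng.standard_normal()) if spec.cv > 0 else 1.0
            if name in _ATHERO_FIELDS:
                athero_up[name] = getattr(spec.base_athero, name) * factor
            else:
                pkpd_up[name] = getattr(spec.base_pkpd, name) * factor
        bundles.append(
            (
                spec.base_athero.model_copy(update=athero_up),
                spec.base_pkpd.model_copy(update=pkpd_up),
            )
        )
    return bundles


def growth_spread(pct_tav_values: Sequence[float]) -> float:
    """Maximum pairwise relative difference of growth: 100·(max − min)/min.

    Requires at least two patients and strictly positive growth for every
    patient (a patient whose plaque never started growing has no defined
    relative spread).
    """
    vals = np.asarray(pct_tav_values, dtype=float)
    if vals.size < 2:
        raise ValueError("growth_spread needs at least two patients")
    vmin = float(vals.min())
    if vmin <= 0:
        raise ValueError(f"all growths must be > 0 for a relative spread, min={vmin!r}")
    return 100.0 * (float(vals.max()) - vmin) / vmin


def transition_times(results: Sequence[SimulationResult]) -> list[Optional[float]]:
    """Per-patient Constant-Volume → Plaque-Growing times (None if never)."""
    return [r.transition_time_h for r in results]
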