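"""Bundled scenario presets mirroring the study's three patient groups.

* ``control`` — no dosing; pure disease progression over 2 years.
* ``regular_treatment`` — 40 mg simvastatin daily during year 1 of a 2-year
  horizon, every dose taken.
* ``imperfect_adherence`` — the same regimen filtered through the two-state
  Markov adherence chain with p_t = 0.90 and q_nt = 0.25 (a patient missing
  ~10% of doses in the long run).
* ``population`` — the untreated typical patient, intended as the base for a
  CV = 0.25 virtual population.

Presets are returned as fresh, immutable bundles; callers may override the
seed and horizon without mutating the stored definition.
"""

from __future__ import annotations

from .params import (
    AdherenceSpec,
    AtheroParams,
    EngineSettings,
    PKPDParams,
    Regimen,
    ScenarioBundle,
)

__all__ = ["PRESET_NAMES", "get_preset"]

PRESET_NAMES = ("control", "regular_treatment", "imperfect_adherence", "population")

_TWO_YEARS_H = 17520.0
_ONE_YEAR_H = 8760.0


def get_preset(
    name: str,
    seed: int = 0,
    horizon_h: float = _TWO_YEARS_H,
    dose_mg: float = 40.0,
) -> ScenarioBundle:
    """Build a named scenario preset; unknown names raise ``KeyError``."""
    athero, pkpd = AtheroParams(), PKPDParams()
    common = dict(athero=athero, pkpd=pkpd, engine=EngineSettings(), horizon_h=horizon_h)
    if name in ("control", "population"):
        return ScenarioBundle(**common)
    if name == "regular_treatment":
        return ScenarioBundle(
            regimen=Regimen(dose_mg=dose_mg, interval_h=24.0, start_h=0.0, duration_h=_ONE_YEAR_H),
            **common,
        )
    if name == "imperfect_adherence":
        return ScenarioBundle(
            regimen=Regimen(dose_mg=dose_mg, interval_h=24.0, start_h=0.0, duration_h=_ONE_YEAR_H),
            adherence=AdherenceSpec(p_t=0.90, q_nt=0.25, seed=seed),
            **common,
        )
    raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
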