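"""Parameter bundles, unit conventions and scenario configuration.

Two unit conventions coexist deliberately:

* **Source units** — the units in which the physiological and PKPD constants
  are usually tabulated (rates in s⁻¹ for the vessel-wall biology, L/hr and
  1/hr for the pharmacokinetics, mm for geometry).  :class:`AtheroParams` and
  :class:`PKPDParams` store values in source units so that a scenario file can
  be written straight from a parameter table.
* **Internal units** — a single canonical time unit (hours) and SI lengths,
  used by every differential equation in the engine.  :meth:`AtheroParams.to_hourly`
  performs the conversion exactly once, at load time, eliminating the classic
  mixed-timescale bug of coupling a per-second disease model to a per-hour PK
  model.

Scenario files are flat YAML documents with ``athero``, ``pkpd``, ``regimen``,
``adherence`` and ``engine`` sections; any omitted key falls back to the
typical-patient default.
"""

from __future__ import annotations

import math
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = [
    "AtheroParams",
    "AtheroRates",
    "PKPDParams",
    "Regimen",
    "AdherenceSpec",
    "EngineSettings",
    "ScenarioBundle",
    "default_params",
    "load_scenario",
    "serialize_scenario",
    "S_PER_H",
    "PARTICLES_PER_NMOL_L",
    "M_LUMEN_REF_CELLS_PER_L",
]

#: seconds per hour; the only time-unit conversion factor in the package.
S_PER_H = 3600.0

#: 1 nmol/L = 1e-6 mol/m³ → Avogadro gives 6.022e17 particles per m³.
PARTICLES_PER_NMOL_L = 6.02214076e17

#: reference blood monocyte concentration (cells/l) against which a patient's
#: m_lumen scales the recruitment flux.
M_LUMEN_REF_CELLS_PER_L = 5.5e8

#: shipped recruitment calibration scalar: produced by
#: ``engine.calibrate_control_growth`` against the documented control-growth
#: convention (untreated %TAV = 8.0 at 730 days) and frozen here.
CHI_DEFAULT = 1.059908938


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class AtheroParams(_Frozen):
    """Vessel, transport and wall-biology constants for one patient.

    Rates are stored in the per-second units of the source table; call
    :meth:`to_hourly` for the engine's internal convention.
    """

    # --- tabulated physiology -------------------------------------------
    R_lumen_initial: float = 3.0      # mm, initial lumen radius
    k_m: float = 9.25e-24             # m³ cell⁻¹ s⁻¹, foam-cell formation constant
    d_m: float = 5.75e-6              # s⁻¹, monocyte clearance out of the wall
    d_M: float = 5.75e-6              # s⁻¹, macrophage clearance
    d_F: float = 5.75e-6              # s⁻¹, foam-cell clearance
    d_lox: float = 2.4e-5             # s⁻¹, oxidized-LDL clearance
    r_w: float = 3.0e-4               # s⁻¹, LDL oxidation rate in the wall
    mu: float = 0.004                 # Pa·s, blood viscosity
    rho1: float = 1.15e-6             # s⁻¹, monocyte→macrophage differentiation
    delta_p: float = 2400.0           # Pa, transendothelial pressure difference
    Q: float = 0.0075                 # l/s, blood flow
    m_lumen: float = 5.5e8            # cells/l, blood monocyte concentration
    sigma: float = 0.997              # -, endothelial reflection coefficient

    # --- reconstruction constants (documented in docs/methods.md) -------
    segment_length: float = 10.0      # mm, modelled segment length
    wall_thickness: float = 0.5       # mm, intima+media thickness
    Lp_ref: float = 3.0e-12           # m Pa⁻¹ s⁻¹, hydraulic conductivity at zero WSS
    P0: float = 1.0e-11               # m/s, diffusive endothelial permeability
    osmotic_term: float = 0.0         # Pa, σΔΠ lumped osmotic contribution
    tau0: float = 1.0                 # Pa, WSS scale of the Lp shear response
    Lp_floor_fraction: float = 0.2    # -, high-WSS floor of Lp relative to Lp_ref
    rec_max: float = 1.0e5            # cells m⁻² s⁻¹, saturating recruitment flux
    K_Lox: float = 2.0                # nmol/L, ox-LDL half-saturation of recruitment
    tau_half: float = 1.0             # Pa, WSS at which recruitment is halved
    eta: float = 100.0                # ox-LDL particles consumed per foam cell formed
    phi: float = 0.02                 # -, interstitial capacity fraction of the wall
    v_mono: float = 4.0e-16           # m³, monocyte unit volume
    v_mac: float = 5.0e-15            # m³, macrophage unit volume
    v_foam: float = 1.5e-14           # m³, foam-cell unit volume
    chi: float = CHI_DEFAULT          # -, recruitment calibration scalar
    core_retention: float = 1.0       # -, fraction of cleared foam-cell volume retained

    @field_validator(
        "R_lumen_initial", "k_m", "d_m", "d_M", "d_F", "d_lox", "r_w", "mu",
        "rho1", "delta_p", "Q", "m_lumen", "segment_length", "wall_thickness",
        "Lp_ref", "P0", "tau0", "rec_max", "K_Lox", "tau_half", "eta",
        "v_mono", "v_mac", "v_foam", "chi",
    )
    @classmethod
    def _positive(cls, v: float, info) -> float:
        if not v > 0:
            raise ValueError(f"{info.field_name} must be > 0, got {v!r}")
        return v

    @field_validator("sigma", "phi", "Lp_floor_fraction", "core_retention")
    @classmethod
    def _unit_interval(cls, v: float, info) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{info.field_name} must lie in [0, 1], got {v!r}")
        return v

    @field_validator("osmotic_term")
    @classmethod
    def _finite(cls, v: float, info) -> float:
        if not math.isfinite(v):
            raise ValueError(f"{info.field_name} must be finite")
        return v

    def to_hourly(self) -> "AtheroRates":
        """Convert to the canonical internal convention (hours, SI lengths).

        Each per-second rate is multiplied by exactly 3600 (one floating-point
        multiply, hence exact to one ulp); geometry converts mm → m and the
        monocyte concentration l⁻¹ → m⁻³.
        """
        return AtheroRates(
            R_lumen_initial_m=self.R_lumen_initial * 1e-3,
            segment_length_m=self.segment_length * 1e-3,
            wall_thickness_m=self.wall_thickness * 1e-3,
            k_m=self.k_m * S_PER_H,
            d_m=self.d_m * S_PER_H,
            d_M=self.d_M * S_PER_H,
            d_F=self.d_F * S_PER_H,
            d_lox=self.d_lox * S_PER_H,
            r_w=self.r_w * S_PER_H,
            rho1=self.rho1 * S_PER_H,
            Lp_ref=self.Lp_ref * S_PER_H,
            P0=self.P0 * S_PER_H,
            rec_max=self.rec_max * S_PER_H,
            mu=self.mu,
            delta_p=self.delta_p,
            Q_m3_s=self.Q * 1e-3,
            m_lumen_m3=self.m_lumen * 1e3,
            m_lumen_scale=self.m_lumen / M_LUMEN_REF_CELLS_PER_L,
            sigma=self.sigma,
            osmotic_term=self.osmotic_term,
            tau0=self.tau0,
            Lp_floor_fraction=self.Lp_floor_fraction,
            K_Lox=self.K_Lox,
            tau_half=self.tau_half,
            eta=self.eta,
            phi=self.phi,
            v_mono=self.v_mono,
            v_mac=self.v_mac,
            v_foam=self.v_foam,
            chi=self.chi,
            core_retention=self.core_retention,
        )


class AtheroRates(_Frozen):
    """:class:`AtheroParams` converted to internal units (hours, metres).

    ``mu`` (Pa·s), ``delta_p`` (Pa) and ``Q_m3_s`` (m³/s) stay in SI seconds:
    they enter only the instantaneous (algebraic) wall-shear-stress relation,
    never a time derivative.
    """

    R_lumen_initial_m: float
    segment_length_m: float
    wall_thickness_m: float
    k_m: float            # m³ cell⁻¹ h⁻¹
    d_m: float            # 1/h
    d_M: float            # 1/h
    d_F: float            # 1/h
    d_lox: float          # 1/h
    r_w: float            # 1/h
    rho1: float           # 1/h
    Lp_ref: float         # m Pa⁻¹ h⁻¹
    P0: float             # m/h
    rec_max: float        # cells m⁻² h⁻¹
    mu: float             # Pa·s
    delta_p: float        # Pa
    Q_m3_s: float         # m³/s
    m_lumen_m3: float     # cells/m³
    m_lumen_scale: float  # -, m_lumen relative to the typical patient
    sigma: float
    osmotic_term: float
    tau0: float
    Lp_floor_fraction: float
    K_Lox: float          # nmol/L
    tau_half: float       # Pa
    eta: float
    phi: float
    v_mono: float
    v_mac: float
    v_foam: float
    chi: float
    core_retention: float


class PKPDParams(_Frozen):
    """Simvastatin parent/metabolite PK and LDL indirect-response constants.

    ``K_out`` is derived as ``K_in / LDL_baseline`` so that the drug-free
    steady state of the turnover model is exactly the baseline LDL.
    """

    CL2: float = 1740.0          # L/hr, apparent clearance, parent compartment
    V2: float = 8980.0           # L, apparent volume, parent compartment
    CL3: float = 383.0           # L/hr, apparent clearance, metabolite compartment
    V3: float = 1190.0           # L, apparent volume, metabolite compartment
    Ka: float = 2.76             # 1/hr, first-order absorption rate
    K_in: float = 29.52          # nmol/L/hr, hepatic LDL production rate
    Emax: float = 0.489          # -, maximal fractional inhibition of production
    EC50: float = 0.0868         # ng/mL, metabolite concentration at half-max effect
    LDL_baseline: float = 1400.0  # nmol/L, pre-treatment circulating LDL

    @field_validator("CL2", "V2", "CL3", "V3", "Ka", "K_in", "EC50", "LDL_baseline")
    @classmethod
    def _positive(cls, v: float, info) -> float:
        if not v > 0:
            raise ValueError(f"{info.field_name} must be > 0, got {v!r}")
        return v

    @field_validator("Emax")
    @classmethod
    def _emax_range(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"Emax must lie in [0, 1], got {v!r}")
        return v

    @property
    def K_out(self) -> float:
        """LDL first-order loss rate (1/hr), pinned to the baseline."""
        return self.K_in / self.LDL_baseline


class Regimen(_Frozen):
    """A planned dosing schedule: discrete dose events at fixed spacing."""

    dose_mg: float = 40.0        # mg per dose
    interval_h: float = 24.0     # h between doses
    start_h: float = 0.0         # h, treatment initiation (first dose)
    duration_h: float = 8760.0   # h, length of the treatment window

    @field_validator("dose_mg", "duration_h")
    @classmethod
    def _nonneg(cls, v: float, info) -> float:
        if v < 0:
            raise ValueError(f"{info.field_name} must be >= 0, got {v!r}")
        return v

    @field_validator("interval_h")
    @classmethod
    def _positive(cls, v: float) -> float:
        if not v > 0:
            raise ValueError(f"interval_h must be > 0, got {v!r}")
        return v

    @field_validator("start_h")
    @classmethod
    def _finite_start(cls, v: float) -> float:
        if v < 0 or not math.isfinite(v):
            raise ValueError(f"start_h must be a finite nonnegative time, got {v!r}")
        return v


class AdherenceSpec(_Frozen):
    """Two-state Markov chain over consecutive planned doses.

    ``p_t`` is the probability of taking today's dose given yesterday's was
    taken; ``q_nt`` the probability of missing it given yesterday's was missed.
    """

    p_t: float = 0.90
    q_nt: float = 0.25
    seed: int = 0
    initial_state: Literal["Taking", "NotTaking"] = "Taking"

    @field_validator("p_t", "q_nt")
    @classmethod
    def _prob(cls, v: float, info) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{info.field_name} must be a probability in [0, 1], got {v!r}")
        return v


class EngineSettings(_Frozen):
    """Numerical controls for the hybrid integrator."""

    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "LSODA"
    output_step_h: float = 24.0

    @field_validator("rtol", "atol", "output_step_h")
    @classmethod
    def _positive(cls, v: float, info) -> float:
        if not v > 0:
            raise ValueError(f"{info.field_name} must be > 0, got {v!r}")
        return v


class ScenarioBundle(_Frozen):
    """Fully validated scenario: parameters, regimen, adherence and settings.

    ``regimen is None`` means an untreated (control) run; ``adherence is None``
    means full adherence to the planned regimen.
    """

    athero: AtheroParams
    pkpd: PKPDParams
    regimen: Optional[Regimen] = None
    adherence: Optional[AdherenceSpec] = None
    engine: EngineSettings = EngineSettings()
    horizon_h: float = 17520.0

    @field_validator("horizon_h")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError(f"horizon_h must be >= 0, got {v!r}")
        return v

    @model_validator(mode="after")
    def _adherence_needs_regimen(self) -> "ScenarioBundle":
        if self.adherence is not None and self.regimen is None:
            raise ValueError("adherence specified without a regimen")
        return self

    @property
    def athero_hourly(self) -> AtheroRates:
        return self.athero.to_hourly()


def default_params() -> tuple[AtheroParams, PKPDParams]:
    """Typical-patient defaults: the tabulated values plus the documented
    reconstruction constants, in source units."""
    return AtheroParams(), PKPDParams()


_SECTIONS = {
    "athero": AtheroParams,
    "pkpd": PKPDParams,
    "regimen": Regimen,
    "adherence": AdherenceSpec,
    "engine": EngineSettings,
}


def load_scenario(config_text: str) -> ScenarioBundle:
    """Parse and validate a YAML scenario document.

    Every key is optional; missing values fall back to the typical-patient
    defaults.  The ``regimen`` and ``adherence`` sections are only
    instantiated when present (their absence encodes control / full
    adherence).  Raises ``ValueError`` naming the offending field on any
    validation failure.
    """
    raw = yaml.safe_load(config_text) if config_text.strip() else {}
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("scenario document must be a mapping of sections")
    unknown = set(raw) - set(_SECTIONS) - {"horizon_h"}
    if unknown:
        raise ValueError(f"unknown scenario section(s): {sorted(unknown)}")

    kwargs: dict = {}
    for name, model in _SECTIONS.items():
        section = raw.get(name)
        if name in ("regimen", "adherence"):
            if section is None:
                continue
            kwargs[name] = model(**section)
        else:
            kwargs[name] = model(**(section or {}))
    if "horizon_h" in raw:
        kwargs["horizon_h"] = raw["horizon_h"]
    return ScenarioBundle(**kwargs)


def serialize_scenario(bundle: ScenarioBundle) -> str:
    """Emit a YAML document that round-trips through :func:`load_scenario`."""
    doc: dict = {
        "athero": bundle.athero.model_dump(),
        "pkpd": bundle.pkpd.model_dump(),
        "engine": bundle.engine.model_dump(),
        "horizon_h": bundle.horizon_h,
    }
    if bundle.regimen is not None:
        doc["regimen"] = bundle.regimen.model_dump()
    if bundle.adherence is not None:
        doc["adherence"] = bundle.adherence.model_dump()
    return yaml.safe_dump(doc, sort_keys=True)
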