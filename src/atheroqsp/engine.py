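"""Hybrid continuous/discrete-event simulation engine.

One patient-run integrates a 10-state ODE system — three drug amounts,
circulating LDL, five wall species and the extracellular lipid core — with
two kinds of discrete events layered on top:

* **dose events**: integration stops exactly at every planned dose time and
  the gut depot is incremented by the dose amount whenever the adherence
  trace says the dose was taken;
* **the plaque-growth event**: the first upcrossing of the wall's
  interstitial capacity is located by the integrator's event mechanism and
  switches the lesion irreversibly from Constant-Volume to Plaque-Growing.

Hemodynamics are quasi-static: wall shear stress and lumen radius are
recomputed algebraically from the current state at every derivative
evaluation, so narrowing feeds back on transport within the same step.  The
concentration difference driving endothelial LDL flux is plasma LDL (from
the PD model) minus wall LDL, which is how the statin effect propagates into
the wall.

Internal units: hours, metres, mg, nmol/L, cells/m³.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import hemodynamics
from .adherence import build_dose_times, simulate_adherence
from .endothelial import hydraulic_conductivity, ldl_flux, transmural_velocity
from .params import (
    AdherenceSpec,
    AtheroParams,
    AtheroRates,
    EngineSettings,
    PKPDParams,
    Regimen,
    ScenarioBundle,
)
from .pkpd import drug_effect, metabolite_concentration

__all__ = [
    "SimulationResult",
    "simulate_patient",
    "simulate_scenario",
    "compare_scenarios",
    "calibrate_control_growth",
    "CalibrationError",
    "SolverError",
]

# state-vector layout
_GUT, _PARENT, _MET, _LDL, _LW, _LOX, _MONO, _MAC, _FOAM, _CORE = range(10)
_NSTATE = 10

#: stop and log an occlusion when the intrusion fills this lumen fraction.
_OCCLUSION_FRACTION = 0.95


class SolverError(RuntimeError):
    """ODE integration failed; carries the last valid state for diagnosis."""

    def __init__(self, message: str, t: float, y: np.ndarray):
        super().__init__(f"{message} (t={t:.3f} h)")
        self.t = t
        self.y = y


class CalibrationError(RuntimeError):
    pass


@dataclass
class _Geometry:
    """Constants precomputed once per run from the hourly parameter bundle."""

    R0: float          # m
    L: float           # m
    S_endo: float      # m²
    V_wall: float      # m³
    V_capacity: float  # m³
    V_lumen: float     # m³
    sv: float          # 1/m

    @classmethod
    def from_rates(cls, p: AtheroRates) -> "_Geometry":
        R0 = p.R_lumen_initial_m
        L = p.segment_length_m
        h = p.wall_thickness_m
        S = 2.0 * math.pi * R0 * L
        V_wall = math.pi * ((R0 + h) ** 2 - R0**2) * L
        return cls(
            R0=R0,
            L=L,
            S_endo=S,
            V_wall=V_wall,
            V_capacity=p.phi * V_wall,
            V_lumen=math.pi * R0**2 * L,
            sv=S / V_wall,
        )


@dataclass
class SimulationResult:
    """Uniform-grid trajectories plus the discrete-event log of one run."""

    time_h: np.ndarray
    ldl_plasma: np.ndarray          # nmol/L
    c_met: np.ndarray               # ng/mL
    wss: np.ndarray                 # Pa
    lumen_radius_mm: np.ndarray
    atheroma_volume_mm3: np.ndarray
    pct_tav: np.ndarray
    states: np.ndarray              # (n_t, 10) raw state vectors
    events: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def transition_time_h(self) -> Optional[float]:
        for ev in self.events:
            if ev["event"] == "growth_transition":
                return ev["time_h"]
        return None

    @property
    def occluded(self) -> bool:
        return any(ev["event"] == "occlusion" for ev in self.events)

    def pct_tav_at(self, t_h: float) -> float:
        """%TAV linearly interpolated at time ``t_h``."""
        return float(np.interp(t_h, self.time_h, self.pct_tav))

    def ldl_at(self, t_h: float) -> float:
        return float(np.interp(t_h, self.time_h, self.ldl_plasma))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.time_h,
                "ldl_plasma_nmol_l": self.ldl_plasma,
                "c_met_ng_ml": self.c_met,
                "wss_pa": self.wss,
                "lumen_radius_mm": self.lumen_radius_mm,
                "atheroma_volume_mm3": self.atheroma_volume_mm3,
                "pct_tav": self.pct_tav,
            }
        )

    def events_frame(self) -> pd.DataFrame:
        cols = ["time_h", "event", "detail"]
        rows = [
            {"time_h": ev["time_h"], "event": ev["event"],
             "detail": ";".join(f"{k}={v}" for k, v in sorted(ev.items())
                                 if k not in ("time_h", "event"))}
            for ev in sorted(self.events, key=lambda e: e["time_h"])
        ]
        return pd.DataFrame(rows, columns=cols)


def _occupied_volume_arr(y: np.ndarray, p: AtheroRates, geom: _Geometry) -> float:
    return (
        geom.V_wall
        * (p.v_mono * y[_MONO] + p.v_mac * y[_MAC] + p.v_foam * y[_FOAM])
        + y[_CORE]
    )


def _make_rhs(p: AtheroRates, pk: PKPDParams, geom: _Geometry):
    """Build the coupled derivative function (plain floats, hot path)."""
    k_parent = pk.CL2 / pk.V2
    k_met = pk.CL3 / pk.V3
    k_out = pk.K_out
    conv_foam = p.k_m * 6.02214076e17 / p.eta  # (nmol/L)⁻¹ h⁻¹ → cells/m³ per (cells/m³·nmol/L)
    vol_coeff_m = geom.V_wall * p.v_mono
    vol_coeff_M = geom.V_wall * p.v_mac
    vol_coeff_F = geom.V_wall * p.v_foam
    pi_L = math.pi * geom.L
    R0_sq = geom.R0**2
    tau_const = 4.0 * p.mu * p.Q_m3_s / math.pi
    core_rate = p.core_retention * p.v_foam * p.d_F * geom.V_wall
    rec_scale = p.chi * p.rec_max * p.m_lumen_scale * geom.sv

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        # integrator safeguard: tiny negative excursions are treated as zero
        A_gut = max(y[_GUT], 0.0)
        A_parent = max(y[_PARENT], 0.0)
        A_met = max(y[_MET], 0.0)
        LDL = max(y[_LDL], 0.0)
        L_w = max(y[_LW], 0.0)
        Lox = max(y[_LOX], 0.0)
        mono = max(y[_MONO], 0.0)
        mac = max(y[_MAC], 0.0)
        foam = max(y[_FOAM], 0.0)
        core = max(y[_CORE], 0.0)

        # --- PK / PD -----------------------------------------------------
        dgut = -pk.Ka * A_gut
        dparent = pk.Ka * A_gut - k_parent * A_parent
        dmet = k_parent * A_parent - k_met * A_met
        C_met = 1000.0 * A_met / pk.V3
        E = pk.Emax * C_met / (pk.EC50 + C_met)
        dldl = pk.K_in * (1.0 - E) - k_out * LDL

        # --- quasi-static hemodynamics ------------------------------------
        V_occ = vol_coeff_m * mono + vol_coeff_M * mac + vol_coeff_F * foam + core
        V_int = V_occ - geom.V_capacity
        if V_int > 0.0:
            R = math.sqrt(max(R0_sq - V_int / pi_L, 1e-12))
        else:
            R = geom.R0
        tau = tau_const / R**3

        # --- endothelial transport ---------------------------------------
        Lp = p.Lp_ref * (
            p.Lp_floor_fraction
            + (1.0 - p.Lp_floor_fraction) * p.tau0 / (p.tau0 + tau)
        )
        Jv = Lp * (p.delta_p - p.osmotic_term)
        dc = LDL - L_w
        cbar = 0.5 * (LDL + L_w)
        Js = p.P0 * dc + (1.0 - p.sigma) * Jv * cbar

        # --- wall inflammation cascade -----------------------------------
        uptake = p.k_m * mac * Lox                # nmol/L/h
        foam_prod = conv_foam * mac * Lox         # cells/m³/h
        rec = rec_scale * (Lox / (Lox + p.K_Lox)) / (1.0 + tau / p.tau_half) if Lox > 0 else 0.0

        dlw = Js * geom.sv - p.r_w * L_w
        dlox = p.r_w * L_w - uptake - p.d_lox * Lox
        dmono = rec - (p.rho1 + p.d_m) * mono
        dmac = p.rho1 * mono - foam_prod - p.d_M * mac
        dfoam = foam_prod - p.d_F * foam
        dcore = core_rate * foam

        return np.array(
            [dgut, dparent, dmet, dldl, dlw, dlox, dmono, dmac, dfoam, dcore]
        )

    return rhs


def simulate_patient(
    athero: AtheroParams,
    pkpd: PKPDParams,
    regimen: Optional[Regimen] = None,
    adherence: Optional[AdherenceSpec] = None,
    horizon_h: float = 17520.0,
    settings: Optional[EngineSettings] = None,
) -> SimulationResult:
    """Simulate one patient over ``horizon_h`` hours.

    ``regimen=None`` is the untreated control; ``adherence=None`` with a
    regimen means full adherence (every planned dose taken).  Returns the
    trajectories on a uniform output grid together with the event log and
    the fully resolved metadata.
    """
    if horizon_h < 0:
        raise ValueError(f"horizon_h must be >= 0, got {horizon_h!r}")
    settings = settings or EngineSettings()
    p = athero.to_hourly()
    geom = _Geometry.from_rates(p)
    rhs = _make_rhs(p, pkpd, geom)

    # planned doses and realized adherence -------------------------------
    events: list[dict] = []
    if regimen is not None and regimen.dose_mg >= 0:
        dose_times = build_dose_times(regimen)
        dose_times = dose_times[dose_times < horizon_h]
    else:
        dose_times = np.array([])
    if adherence is not None and dose_times.size:
        trace = simulate_adherence(adherence, dose_times.size)
    else:
        trace = np.ones(dose_times.size, dtype=np.int64)

    # output grid ---------------------------------------------------------
    step = settings.output_step_h
    n_steps = int(round(horizon_h / step)) if horizon_h > 0 else 0
    grid = np.linspace(0.0, n_steps * step, n_steps + 1)
    if grid[-1] < horizon_h - 1e-9:
        grid = np.append(grid, horizon_h)

    y = np.zeros(_NSTATE)
    y[_LDL] = pkpd.LDL_baseline

    # event functions -----------------------------------------------------
    transition_time: Optional[float] = None

    def growth_event(t, yv):
        return _occupied_volume_arr(yv, p, geom) - geom.V_capacity

    growth_event.direction = 1.0

    def occlusion_event(t, yv):
        V_int = _occupied_volume_arr(yv, p, geom) - geom.V_capacity
        return V_int - _OCCLUSION_FRACTION * geom.V_lumen

    occlusion_event.terminal = True
    occlusion_event.direction = 1.0

    breakpoints = np.unique(np.concatenate([dose_times, [0.0, horizon_h]]))
    breakpoints = breakpoints[(breakpoints >= 0.0) & (breakpoints <= horizon_h)]

    rec_t: list[float] = [0.0]
    rec_y: list[np.ndarray] = [y.copy()]
    dose_iter = {t: bool(tk) for t, tk in zip(dose_times, trace)}
    halted = False

    for t0, t1 in zip(breakpoints[:-1], breakpoints[1:]):
        if t0 in dose_iter:
            taken = dose_iter[t0]
            if taken:
                y = y.copy()
                y[_GUT] += regimen.dose_mg
            events.append({"time_h": float(t0), "event": "dose", "taken": taken,
                           "dose_mg": regimen.dose_mg if taken else 0.0})
        if t1 <= t0:
            continue
        te = grid[(grid > t0 + 1e-9) & (grid <= t1 + 1e-9)]
        t_eval = np.unique(np.append(te, t1))
        sol = solve_ivp(
            rhs,
            (t0, t1),
            y,
            method=settings.method,
            t_eval=t_eval,
            events=[growth_event, occlusion_event],
            rtol=settings.rtol,
            atol=settings.atol,
        )
        if not sol.success:
            raise SolverError(sol.message, t0, y)
        if transition_time is None and sol.t_events[0].size:
            transition_time = float(sol.t_events[0][0])
            events.append({"time_h": transition_time, "event": "growth_transition"})
        if sol.t_events[1].size:  # occlusion: halt
            t_occ = float(sol.t_events[1][0])
            events.append({"time_h": t_occ, "event": "occlusion"})
            # scipy returns bare lists when the terminal event precedes t_eval
            sol_t = np.atleast_1d(np.asarray(sol.t, dtype=float))
            sol_y = np.asarray(sol.y, dtype=float).reshape(_NSTATE, -1) if sol_t.size else np.empty((_NSTATE, 0))
            keep = sol_t <= t_occ
            for tt, yy in zip(sol_t[keep], sol_y[:, keep].T):
                if tt > rec_t[-1] + 1e-9:
                    rec_t.append(float(tt))
                    rec_y.append(yy)
            rec_t.append(t_occ)
            rec_y.append(sol.y_events[1][0])
            halted = True
            break
        for tt, yy in zip(sol.t, sol.y.T):
            if np.any(np.isclose(tt, grid, rtol=0.0, atol=1e-6)) and tt > rec_t[-1] + 1e-9:
                rec_t.append(float(tt))
                rec_y.append(yy)
        y = sol.y[:, -1]

    # handle a dose exactly at the horizon boundary (none planned by contract)
    time_arr = np.array(rec_t)
    states = np.maximum(np.array(rec_y), 0.0)

    # derived series ------------------------------------------------------
    V_occ = (
        geom.V_wall
        * (
            p.v_mono * states[:, _MONO]
            + p.v_mac * states[:, _MAC]
            + p.v_foam * states[:, _FOAM]
        )
        + states[:, _CORE]
    )
    V_int = np.maximum(V_occ - geom.V_capacity, 0.0)
    R = np.sqrt(np.maximum(geom.R0**2 - V_int / (math.pi * geom.L), 1e-12))
    wss = 4.0 * p.mu * p.Q_m3_s / (math.pi * R**3)
    V_atheroma = geom.V_wall + V_int
    pct_tav = 100.0 * V_int / geom.V_wall
    c_met = np.array([metabolite_concentration(a, pkpd) for a in states[:, _MET]])

    metadata = {
        "athero": athero.model_dump(),
        "pkpd": pkpd.model_dump(),
        "regimen": regimen.model_dump() if regimen is not None else None,
        "adherence": adherence.model_dump() if adherence is not None else None,
        "settings": settings.model_dump(),
        "horizon_h": horizon_h,
        "n_doses_planned": int(dose_times.size),
        "n_doses_taken": int(trace.sum()) if trace.size else 0,
        "halted_on_occlusion": halted,
        "V_wall_initial_mm3": geom.V_wall * 1e9,
        "V_capacity_mm3": geom.V_capacity * 1e9,
    }
    return SimulationResult(
        time_h=time_arr,
        ldl_plasma=states[:, _LDL],
        c_met=c_met,
        wss=wss,
        lumen_radius_mm=R * 1e3,
        atheroma_volume_mm3=V_atheroma * 1e9,
        pct_tav=pct_tav,
        states=states,
        events=events,
        metadata=metadata,
    )


def simulate_scenario(bundle: ScenarioBundle) -> SimulationResult:
    """Run :func:`simulate_patient` on a loaded scenario bundle."""
    return simulate_patient(
        bundle.athero,
        bundle.pkpd,
        regimen=bundle.regimen,
        adherence=bundle.adherence,
        horizon_h=bundle.horizon_h,
        settings=bundle.engine,
    )


def compare_scenarios(
    results: Mapping[str, SimulationResult] | Sequence[SimulationResult],
    horizon_h: Optional[float] = None,
) -> pd.DataFrame:
    """Pairwise %TAV and plasma-LDL differences at a common horizon.

    Differences are (first − second) for every ordered pair in the given
    order; trajectories on mismatched grids are linearly interpolated at the
    evaluation horizon (default: the latest time common to all runs).
    """
    if not isinstance(results, Mapping):
        results = {f"scenario_{i}": r for i, r in enumerate(results)}
    if len(results) < 2:
        raise ValueError("need at least two scenarios to compare")
    if horizon_h is None:
        horizon_h = min(r.time_h[-1] for r in results.values())
    names = list(results)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ra, rb = results[a], results[b]
            rows.append(
                {
                    "scenario_a": a,
                    "scenario_b": b,
                    "horizon_h": horizon_h,
                    "pct_tav_diff": ra.pct_tav_at(horizon_h) - rb.pct_tav_at(horizon_h),
                    "ldl_diff_nmol_l": ra.ldl_at(horizon_h) - rb.ldl_at(horizon_h),
                }
            )
    return pd.DataFrame(rows)


def calibrate_control_growth(
    athero: AtheroParams,
    pkpd: PKPDParams,
    target_pct_tav: float = 8.0,
    horizon_h: float = 17520.0,
    tol: float = 0.02,
    settings: Optional[EngineSettings] = None,
    chi_bracket: tuple[float, float] = (1e-3, 1e3),
    max_iter: int = 80,
) -> float:
    """Bisect the recruitment scalar χ so the untreated run hits the target.

    The untreated %TAV at the horizon is monotone increasing in χ, so plain
    bisection on log-χ converges unconditionally inside a valid bracket.
    Returns the calibrated χ with |%TAV(χ) − target| <= tol; raises
    :class:`CalibrationError` when the bracket does not straddle the target.
    """
    if target_pct_tav <= 0:
        raise ValueError("target_pct_tav must be > 0")

    def growth(chi: float) -> float:
        pars = athero.model_copy(update={"chi": chi})
        res = simulate_patient(pars, pkpd, horizon_h=horizon_h, settings=settings)
        return res.pct_tav_at(horizon_h)

    current = growth(athero.chi)
    if abs(current - target_pct_tav) <= tol:
        return athero.chi

    lo, hi = chi_bracket
    g_lo, g_hi = growth(lo), growth(hi)
    if not (g_lo < target_pct_tav < g_hi):
        raise CalibrationError(
            f"bracket does not straddle target: %TAV({lo:g})={g_lo:.3f}, "
            f"%TAV({hi:g})={g_hi:.3f}, target={target_pct_tav:g}"
        )
    for _ in range(max_iter):
        mid = math.sqrt(lo * hi)
        g_mid = growth(mid)
        if abs(g_mid - target_pct_tav) <= tol:
            return mid
        if g_mid < target_pct_tav:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"bisection did not reach |%TAV − {target_pct_tav:g}| <= {tol:g} "
        f"within {max_iter} iterations (last bracket [{lo:g}, {hi:g}])"
    )
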