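# Methods

`atheroqsp` simulates early atherosclerotic plaque growth in one idealized
coronary segment and the effect of daily simvastatin on it, including
imperfect medication adherence. It is a hybrid model: a stiff system of ten
coupled ODEs integrated continuously, with two kinds of discrete events —
dose administrations and the plaque-growth phase transition — layered on
top. This note records the model, its assumptions, the tunable parameters,
and the design choices made where the design was genuinely open.

## Model structure

### Hemodynamics (quasi-steady Poiseuille)

Blood is Newtonian, the vessel a straight cylinder of initial radius
R₀ = 3.0 mm and length 10 mm, and the flow steady at Q = 0.0075 l/s, so the
wall shear stress is the closed form τ = 4μQ/(πR³). Flow is held fixed as
the lumen narrows (the segment is short relative to the vasculature that
sets its flow), so narrowing *raises* τ — a stabilizing feedback on
transport. τ and R are recomputed algebraically from the current state at
every derivative evaluation (quasi-static coupling); no pulsatility is
modelled.

### Transendothelial transport (Kedem–Katchalsky)

Volume flux Jv = Lp(τ)·(Δp − σΔΠ) and LDL flux
Js = P₀·Δc + (1−σ)·Jv·c̄, with Δp = 2400 Pa, σ = 0.997, Δc the difference
between plasma LDL (from the PD model) and wall LDL, and c̄ their
arithmetic mean. The lumped osmotic term σΔΠ defaults to 0, a common
simplification when the focus is pressure-driven filtration. Low shear
renders the endothelium leaky through

    Lp(τ) = Lp_ref · (f + (1−f)·τ₀/(τ₀+τ)),   f = 0.2, τ₀ = 1 Pa,

a monotone non-increasing form with Lp(0) = Lp_ref = 3×10⁻¹² m Pa⁻¹ s⁻¹
and a high-shear floor of f·Lp_ref. Only Lp is shear-modulated; the
diffusive permeability P₀ = 10⁻¹¹ m/s is held shear-independent (the
simplest faithful reading; both are configurable).

### Wall inflammation (well-mixed compartment)

The spatially resolved convection–diffusion–reaction transport in the
intima is reduced to one well-mixed compartment of volume
V_wall = π((R₀+h)² − R₀²)L ≈ 102 mm³ (wall thickness h = 0.5 mm). Species:
native LDL L_w and oxidized LDL L_ox (nmol/L), monocytes m, macrophages M
and foam cells F (cells/m³):

    dL_w/dt  = Js·(S/V) − r_w·L_w
    dL_ox/dt = r_w·L_w − k_m·M·L_ox − d_lox·L_ox
    dm/dt    = rec(τ, L_ox)·(S/V)·(m_lumen/m_ref) − (ρ₁ + d_m)·m
    dM/dt    = ρ₁·m − k_m·M·L_ox,p/η − d_M·M
    dF/dt    = k_m·M·L_ox,p/η − d_F·F

with L_ox,p the ox-LDL concentration in particles/m³ (1 nmol/L =
6.022×10¹⁷ m⁻³), η the particles ingested per foam-cell conversion, and
recruitment flux

    rec = χ·rec_max · L_ox/(L_ox + K_Lox) · 1/(1 + τ/τ_half).

Every clearance constant (d_m, d_M, d_F, d_lox) is first order — the
compartmental stand-in for the advective and diffusive loss pathways of the
full transport equation. Macrophages are consumed 1:1 on conversion, and
the ingestion term in dL_ox/dt is the exact particle-bookkeeping mirror of
foam production (η particles per cell). Nonnegativity is preserved by
construction: every loss term vanishes with its own species.

### Plaque volume, the growth event, and %TAV

Occupied volume V_occ = V_wall·(v_mono·m + v_mac·M + v_foam·F) + V_core.
The wall tolerates infiltration up to an interstitial capacity
φ·V_wall; the first upcrossing of that capacity is a discrete, irreversible
event ("Constant Volume" → "Plaque Growing"), located by the integrator's
event mechanism. Beyond capacity, excess volume intrudes into the lumen
(inward remodeling): R = sqrt(R₀² − V_int/(πL)). The clinical endpoint is
%TAV = 100·(V_atheroma − V_atheroma,0)/V_atheroma,0 with
V_atheroma = V_wall + V_int, so %TAV = 100·V_int/V_wall. If the intrusion
ever reached 95% of the lumen volume the run would halt with an occlusion
event.

**The extracellular core.** V_core is an irreversibly accumulating
extracellular lipid/necrotic pool fed by cleared foam cells:
dV_core/dt = ρ_ret·v_foam·d_F·F·V_wall (retention ρ_ret = 1 by default).
This compartment is essential, not cosmetic: all five cellular species
relax to quasi-steady state within ~2 weeks (the slowest clearance,
5.75×10⁻⁶ s⁻¹, has a 2-day time constant), so without an integrating pool
the lesion volume would saturate within a month and a 1-year treatment
would leave no trace at year 2. Foam-cell death feeding a necrotic core is
the standard accumulating compartment in atherosclerosis ODE models; it
keeps the tabulated foam-cell clearance rate intact while giving the lesion
its multi-year memory.

### PKPD of simvastatin

First-order absorption (Ka = 2.76 h⁻¹) from a gut depot, a parent
compartment (CL₂/V₂ = 1740/8980 L h⁻¹/L), complete conversion to the
active acid metabolite (CL₃/V₃ = 383/1190), all amounts in mg. The
metabolite concentration C_met = 1000·A_met/V₃ ng/mL drives an inhibitory
indirect-response model of circulating LDL:

    dLDL/dt = K_in·(1 − E) − K_out·LDL,   E = Emax·C_met/(EC50 + C_met),

with K_in = 29.52 nmol L⁻¹ h⁻¹, Emax = 0.489, EC50 = 0.0868 ng/mL and
K_out = K_in/LDL_baseline so the drug-free steady state is exactly the
1400 nmol/L baseline. Doses are discrete events: integration stops at each
planned dose time and the depot is incremented when the dose is taken.
Dose size defaults to 40 mg once daily — a standard simvastatin
prescription; the headline treatment scenario doses daily during year 1 of
a 2-year horizon.

### Medication adherence

A two-state Markov chain over consecutive planned doses with
P(take|took) = p_t and P(miss|missed) = q_nt; transition matrix
[[p_t, 1−p_t], [1−q_nt, q_nt]]. The reference imperfect-adherence scenario
uses p_t = 0.90, q_nt = 0.25, whose stationary missed fraction is
(1−p_t)/((1−p_t)+(1−q_nt)) = 2/17 ≈ 11.8% — a patient missing roughly one
dose in nine, with misses mildly clustered (mean run length 1/(1−q_nt) =
1.33). The first trace element is drawn from the transition out of the
initial state, which defaults to Taking (initiation = first dose at t = 0).
One seeded generator per simulation; the seed is recorded in the run
metadata and fixed seeds give bit-identical traces.

## Units

Source units follow the parameter tables (per-second rates for wall
biology, per-hour for PK, mm for geometry). At load every per-second rate
is multiplied by exactly 3600 into the single internal time unit (hours);
lengths convert to metres, monocyte concentration to cells/m³. μ, Δp and Q
stay in SI seconds because they enter only the instantaneous shear-stress
relation. Wall lipids are tracked in nmol/L, cells in cells/m³ — a stated
convention, since the originating compartmental literature does not fix
one.

## Parameters that matter, and calibration

Tabulated patient constants (Table-defaults in `AtheroParams`/`PKPDParams`)
are taken as given. The reconstruction constants are:

| constant | default | role / rationale |
|---|---|---|
| segment_length | 10 mm | typical imaged coronary segment |
| wall_thickness | 0.5 mm | intima+media of a mildly diseased coronary |
| Lp_ref, P₀ | 3e-12 m Pa⁻¹ s⁻¹, 1e-11 m/s | literature-range endothelial transport values |
| τ₀, τ_half | 1 Pa | characteristic low-shear scale; baseline τ ≈ 1.41 Pa sits on the responsive part of both curves |
| Lp floor f | 0.2 | high-shear endothelium stays ~5× tighter than stagnant |
| K_Lox | 2 nmol/L | near the untreated operating point of L_ox (≈1.7 nmol/L), keeping recruitment responsive to LDL lowering |
| rec_max | 1e5 cells m⁻² s⁻¹ | order of measured monocyte adhesion fluxes |
| v_mono, v_mac, v_foam | 4e-16, 5e-15, 1.5e-14 m³ | cytology-scale unit volumes |
| η | 100 particles/cell | sets macrophage→foam conversion to a ~100-day time constant at baseline L_ox; much larger values make foam formation negligibly slow against the 2-day macrophage clearance, and the resulting growth cannot be bought back by recruitment because macrophage volume is capacity-limited |
| φ | 0.02 | free interstitial capacity; small enough that every virtual patient's lesion enters the growing phase well inside a 2-year study window |
| ρ_ret | 1.0 | cleared foam-cell volume fully retained in the core |
| χ | 1.059908938 | **calibrated**, see below |

**Control-growth convention.** One scalar, the recruitment multiplier χ, is
calibrated by bisection so that the untreated typical patient reaches
%TAV = 8.0 at 730 days (≈4%/yr) — the mid-range of the control-arm
progression trends reported by intravascular-ultrasound statin trials,
which bracket roughly 1–2%/yr (slow) to >15%/yr (fast). The calibrated
value is frozen as the shipped default; `calibrate_control_growth`
re-derives it (and returns the current χ unchanged when it already
satisfies the convention).

With these defaults the untreated patient transitions to the growing phase
at ~day 110 and the 1-year-treated patient's 2-year growth is ~2.9
percentage points below control. The adherence scenario (p_t = 0.90,
q_nt = 0.25) costs ~0.2 percentage points relative to full adherence: a
missed dose forfeits about one day of inhibition (a single dose holds
C_met above EC50 for ~33 h), and LDL rebuilds with t½ = ln2/K_out ≈ 33 h,
so 11.8% missed doses recover only ~8% of the LDL suppression; the wall
cascade amplifies exposure roughly quadratically, not enough to make the
penalty much larger. This is a structural property of the tabulated PKPD
constants, not of the calibration.

## Virtual populations

Patient variability: a designated subset of parameters — by default
{k_m, r_w, rec_max, m_lumen, LDL_baseline}, spanning the lipid,
inflammatory and recruitment axes — is drawn independently log-normal with
median at the typical value and CV = 0.25. Log-normal sampling preserves
positivity. Fifty such patients differ in 2-year growth by an order of
magnitude and in transition time from ~3 weeks to ~9 months; the maximum
pairwise relative spread, 100·(max−min)/min, far exceeds 100%. The spread
statistic requires strictly positive growth for every patient and is
undefined (raises) otherwise.

## Numerical choices

* Stiff adaptive integration (LSODA; rtol 1e-8, atol 1e-10 by default,
  configurable). Dose times are segment boundaries, never stepped over.
* The phase transition is detected with the solver's event location; the
  dynamics themselves use the continuous ramp max(0, V_occ − capacity), so
  the right-hand side is continuous across the event.
* Tiny negative excursions of states near zero (solver order effects) are
  clamped to zero inside the derivative and in the reported trajectories.
* Output is sampled on a uniform grid (24 h default). Sampled values at
  dose times are pre-dose (trough) values. Halving the output step changes
  the 2-year %TAV by far less than 0.1% — output sampling is decoupled from
  the adaptive integration grid.
* Bisection for χ runs on a log scale with a monotonicity guarantee; the
  exit contract is |%TAV(χ) − target| ≤ tol.

## What the scenarios emulate — and what they do not

The defaults *are* the study conditions: a single typical patient, a
2-year horizon, 40 mg daily dosing during year 1, the (0.90, 0.25)
adherence chain, and a CV = 0.25 population of 50. The simulated wall is a
single well-mixed compartment — no axial or transmural gradients, no
cytokine intermediates, smooth-muscle cells, fibrous cap or HDL; no
outward (Glagov) remodeling; no pleiotropic (LDL-independent) statin
effects; no discontinuation hazard or dose-timing jitter. Passing tests
therefore demonstrate internal consistency and the stated emergent
behaviours of this reconstruction, not fidelity to any individual
patient's anatomy or to spatially resolved transport. The two-compartment
PK is an apparent-parameter reduction; between-occasion PK variability is
not modelled.

## Known limitations

* The wall-inflammation ODEs are a documented reconstruction constrained
  by the tabulated symbols, units and rate constants; the original
  spatially resolved formulation is not reproduced. The diffusivity D_w has
  no separate role in the compartment reduction — its loss pathway is
  absorbed into the first-order d_* constants.
* The adherence penalty under the reference chain is ~0.2 %TAV points at
  2 years; analyses of LDL exposure (above) indicate this magnitude is
  forced by the PKPD constants, so markedly larger published penalties
  cannot be reproduced by re-weighting this reconstruction alone.
* The growth-spread statistic is sensitive to the slowest patient in the
  sample and therefore to the population seed; it is reported per seeded
  population, not as a population-free constant.
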