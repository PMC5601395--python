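# Fully spelled-out scenario for the typical patient: daily 40 mg simvastatin
# during year 1 of a 2-year horizon, filtered through the reference Markov
# adherence chain. Every key is optional — omitted keys fall back to these
# same defaults; omit the whole `regimen` section for an untreated control
# and the `adherence` section for full adherence.
#
# Units are the source-table conventions; rates given per second are
# converted to the internal per-hour convention at load.

athero:
  R_lumen_initial: 3.0       # mm, initial lumen radius
  k_m: 9.25e-24              # m^3 cell^-1 s^-1, foam-cell formation constant
  d_m: 5.75e-6               # s^-1, monocyte clearance out of the wall
  d_M: 5.75e-6               # s^-1, macrophage clearance
  d_F: 5.75e-6               # s^-1, foam-cell clearance
  d_lox: 2.4e-5              # s^-1, oxidized-LDL clearance
  r_w: 3.0e-4                # s^-1, LDL oxidation rate
  mu: 0.004                  # Pa s, blood viscosity
  rho1: 1.15e-6              # s^-1, monocyte -> macrophage differentiation
  delta_p: 2400.0            # Pa, transendothelial pressure difference
  Q: 0.0075                  # l/s, blood flow
  m_lumen: 5.5e8             # cells/l, blood monocyte concentration
  sigma: 0.997               # -, endothelial reflection coefficient
  # reconstruction constants (see docs/methods.md)
  segment_length: 10.0       # mm
  wall_thickness: 0.5        # mm
  Lp_ref: 3.0e-12            # m Pa^-1 s^-1, hydraulic conductivity at zero WSS
  P0: 1.0e-11                # m/s, diffusive endothelial permeability
  osmotic_term: 0.0          # Pa, lumped sigma*deltaPi
  tau0: 1.0                  # Pa, WSS scale of the Lp response
  Lp_floor_fraction: 0.2     # -, high-shear floor of Lp
  rec_max: 1.0e5             # cells m^-2 s^-1, saturating recruitment flux
  K_Lox: 2.0                 # nmol/L, ox-LDL half-saturation of recruitment
  tau_half: 1.0              # Pa, WSS halving recruitment
  eta: 100.0                 # ox-LDL particles consumed per foam cell
  phi: 0.02                  # -, interstitial capacity fraction
  v_mono: 4.0e-16            # m^3, monocyte unit volume
  v_mac: 5.0e-15             # m^3, macrophage unit volume
  v_foam: 1.5e-14            # m^3, foam-cell unit volume
  chi: 1.059908938           # -, calibrated recruitment scalar
  core_retention: 1.0        # -, cleared foam-cell volume retained in the core

pkpd:
  CL2: 1740.0                # L/hr, apparent clearance, parent
  V2: 8980.0                 # L, apparent volume, parent
  CL3: 383.0                 # L/hr, apparent clearance, metabolite
  V3: 1190.0                 # L, apparent volume, metabolite
  Ka: 2.76                   # 1/hr, absorption rate constant
  K_in: 29.52                # nmol/L/hr, LDL production rate
  Emax: 0.489                # -, max fractional inhibition
  EC50: 0.0868               # ng/mL, half-max metabolite concentration
  LDL_baseline: 1400.0       # nmol/L

regimen:
  dose_mg: 40.0              # mg per dose
  interval_h: 24.0           # h between doses
  start_h: 0.0               # h, treatment initiation
  duration_h: 8760.0         # h, treatment window (1 year)

adherence:
  p_t: 0.90                  # P(take | took previous)
  q_nt: 0.25                 # P(miss | missed previous)
  seed: 0
  initial_state: Taking

engine:
  rtol: 1.0e-8
  atol: 1.0e-10
  method: LSODA
  output_step_h: 24.0

horizon_h: 17520.0           # 2 years
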