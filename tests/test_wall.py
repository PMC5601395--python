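"""Wall-inflammation cascade: recruitment, derivatives, invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from atheroqsp.params import PARTICLES_PER_NMOL_L, AtheroParams, S_PER_H
from atheroqsp.wall import (
    WallGeometry,
    WallState,
    monocyte_recruitment,
    wall_derivatives,
)


@pytest.fixture(scope="module")
def rates(athero):
    return athero.to_hourly()


@pytest.fixture(scope="module")
def geom():
    # 3 mm lumen, 10 mm segment, 0.5 mm wall
    import math

    R0, L, h = 3e-3, 1e-2, 5e-4
    return WallGeometry(S_endo=2 * math.pi * R0 * L,
                        V_wall=math.pi * ((R0 + h) ** 2 - R0**2) * L)


class TestRecruitment:
    def test_no_oxldl_no_recruitment(self):
        assert monocyte_recruitment(0.0, 0.0, 1e5, 2.0, 1.0, 1.0) == 0.0

    def test_saturation_limit(self):
        rec = monocyte_recruitment(0.0, 1e12, 1e5, 2.0, 1.0, 1.3)
        assert rec == pytest.approx(1.3 * 1e5, rel=1e-9)

    def test_half_saturation_in_both_drivers(self):
        # Lox = K_Lox and tau = tau_half each halve the flux: together 1/4
        rec = monocyte_recruitment(1.0, 2.0, 1e5, 2.0, 1.0, 1.0)
        assert rec == pytest.approx(0.25 * 1e5)

    def test_decreasing_in_shear(self):
        recs = [monocyte_recruitment(t, 5.0, 1e5, 2.0, 1.0, 1.0) for t in (0, 1, 2, 5)]
        assert all(b < a for a, b in zip(recs, recs[1:]))


class TestWallDerivatives:
    def test_zero_state_zero_flux_is_stationary(self, rates, geom):
        d = wall_derivatives(WallState(0, 0, 0, 0, 0), rates, Js=0.0, tau=1.4, geometry=geom)
        assert all(v == 0.0 for v in d)

    def test_no_macrophages_no_foam_production(self, rates, geom):
        ws = WallState(L_w=0, Lox=5.0, m=0, M=0, F=1e9)
        d = wall_derivatives(ws, rates, Js=0.0, tau=1.4, geometry=geom)
        assert d.dF == pytest.approx(-rates.d_F * 1e9)

    def test_foam_production_arithmetic(self, geom):
        # k_m = 9.25e-24 m³/cell/s, M = 5e11 cells/m³, Lox = 1e18 particles/m³
        # and eta = 1e4 particles/cell give 4.625e2 foam cells m⁻³ s⁻¹.
        p = AtheroParams(eta=1e4).to_hourly()
        Lox_nmol = 1e18 / PARTICLES_PER_NMOL_L
        ws = WallState(L_w=0, Lox=Lox_nmol, m=0, M=5e11, F=0)
        d = wall_derivatives(ws, p, Js=0.0, tau=0.0, geometry=geom)
        per_second = d.dF / S_PER_H
        assert per_second == pytest.approx(4.625e2, rel=1e-9)

    def test_negative_state_rejected(self, rates, geom):
        with pytest.raises(ValueError):
            wall_derivatives(WallState(-1, 0, 0, 0, 0), rates, 0.0, 1.0, geom)

    @given(
        L_w=st.floats(0, 1e3),
        Lox=st.floats(0, 1e3),
        m=st.floats(0, 1e14),
        M=st.floats(0, 1e14),
        F=st.floats(0, 1e14),
        Js=st.floats(0, 1e-3),
        tau=st.floats(0, 10),
    )
    def test_boundary_derivatives_point_inward(self, rates, geom, L_w, Lox, m, M, F, Js, tau):
        """Wherever a species is zero, its derivative is nonnegative:
        the nonnegative orthant is forward-invariant."""
        ws = WallState(L_w, Lox, m, M, F)
        d = wall_derivatives(ws, rates, Js=Js, tau=tau, geometry=geom)
        for value, deriv in zip(ws, d):
            if value == 0.0:
                assert deriv >= 0.0

    @given(
        Lox=st.floats(0.1, 1e3),
        M=st.floats(1e12, 1e15),
    )
    def test_particle_bookkeeping(self, rates, geom, Lox, M):
        """Ox-LDL particles consumed per unit time = eta × foam cells produced.

        Probed with no native LDL (so the ox-LDL balance isolates uptake and
        clearance) at macrophage densities where the uptake flux is resolvable
        above floating-point cancellation of the clearance term.
        """
        ws = WallState(0.0, Lox, 0.0, M, 0.0)
        d = wall_derivatives(ws, rates, Js=0.0, tau=0.0, geometry=geom)
        consumed_particles = (-rates.d_lox * Lox - d.dLox) * PARTICLES_PER_NMOL_L
        produced = d.dF  # F = 0 so no clearance term
        assert consumed_particles == pytest.approx(rates.eta * produced, rel=1e-6)

    def test_isolated_wall_decays_to_zero(self, rates, geom):
        """With no LDL influx and no recruitment every species drains away."""
        p = rates.model_copy(update={"rec_max": 1e-30})
        y0 = np.array([10.0, 5.0, 1e12, 1e12, 1e11])

        def rhs(t, y):
            return np.array(
                wall_derivatives(WallState(*np.maximum(y, 0.0)), p, 0.0, 1.4, geom)
            )

        sol = solve_ivp(rhs, (0, 5e4), y0, rtol=1e-8, atol=1e-6, method="LSODA")
        assert sol.success
        assert np.all(np.abs(sol.y[:, -1]) < np.maximum(1e-6 * y0, 1e-3))
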