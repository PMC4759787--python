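"""Tests of the moment-closure systems: algebraic identities, closed-form
limits, a fixed-step integration oracle, and the extension contracts."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from dsbkin import (
    ExtensionRates,
    MeanState,
    RateConstants,
    integrate,
    persistence_auc,
    rhs_antibody,
    rhs_auger,
    rhs_conditional,
    rhs_naive,
)

ZERO = RateConstants(0, 0, 0, 0, 0, 0)
EXT = ExtensionRates(k7=1.0, k8=10.0, tat0=0.05)


class TestRhsNaive:
    def test_absorbing_zero_state(self, mcf7):
        np.testing.assert_array_equal(rhs_naive((0, 0, 0), mcf7), [0, 0, 0])

    def test_fresh_break_only_recruits(self, mcf7):
        np.testing.assert_allclose(rhs_naive((1, 0, 0), mcf7), [0, 1236, 0])

    def test_post_repair_subsystem_decays(self, mcf7):
        # with mX=0 the (mY, mZ) system is linear; stability means both
        # eigenvalues negative, so any start relaxes to (0, 0)
        sol = integrate("naive", mcf7, init=MeanState(mX=0, mY=40, mZ=120),
                        grid=np.linspace(0, 5, 51))
        assert sol.mY[-1] < 1e-8 and sol.mZ[-1] < 1e-8


class TestRhsConditional:
    def test_single_population_limit(self, mcf7):
        # at mX=1 the repaired branch is empty/frozen and (u, v) obey the
        # naive equations evaluated at mX=1
        d = rhs_conditional((1.0, 5.0, 10.0, 0.0, 0.0), mcf7)
        naive = rhs_naive((1.0, 5.0, 10.0), mcf7)
        assert d[0] == pytest.approx(-mcf7.k1 * 1.0 * 5.0)
        assert d[1] == pytest.approx(naive[1]) and d[2] == pytest.approx(naive[2])
        assert d[3] == 0.0 and d[4] == 0.0  # frozen empty branch

    def test_mixture_identity_is_exact(self, mcf7):
        # d/dt of mY = mX u + (1-mX) w from the closed branch equations must
        # reproduce the exact linear unconditional equation (and likewise mZ)
        m = np.array([0.6, 40.0, 110.0, 12.0, 30.0])
        mX, u, v, w, s = m
        d = rhs_conditional(m, mcf7)
        mY = mX * u + (1 - mX) * w
        mZ = mX * v + (1 - mX) * s
        dmY = d[0] * u + mX * d[1] - d[0] * w + (1 - mX) * d[3]
        dmZ = d[0] * v + mX * d[2] - d[0] * s + (1 - mX) * d[4]
        assert dmY == pytest.approx(mcf7.k2 * mX + mcf7.k3 * mZ - mcf7.k4 * mY, rel=1e-12)
        assert dmZ == pytest.approx(mcf7.k5 * mY - mcf7.k6 * mZ, rel=1e-12)

    def test_integrate_matches_direct_branch_integration(self, mcf7):
        # the non-singular form used by integrate() must agree with direct
        # integration of the (mX, u, v, w, s) equations away from mX=1
        grid = np.linspace(0, 6, 25)
        y0 = [0.99, 0.0, 0.0, 0.0, 0.0]
        direct = solve_ivp(lambda t, y: rhs_conditional(y, mcf7), (0, 6), y0,
                           t_eval=grid, method="LSODA", rtol=1e-10, atol=1e-12)
        sol = integrate("conditional", mcf7, init=MeanState(mX=0.99, mY=0, mZ=0),
                        grid=grid, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(sol.mX, direct.y[0], rtol=1e-5, atol=1e-8)
        mZ_direct = direct.y[0] * direct.y[2] + (1 - direct.y[0]) * direct.y[4]
        np.testing.assert_allclose(sol.mZ, mZ_direct, rtol=1e-4, atol=1e-6)


class TestIntegrate:
    def test_zero_init_stays_zero(self, mcf7):
        sol = integrate("naive", mcf7, init=MeanState(mX=0, mY=0, mZ=0),
                        grid=np.linspace(0, 10, 11))
        assert np.all(sol.mX == 0) and np.all(sol.mZ == 0)

    @pytest.mark.parametrize("closure", ["naive", "conditional"])
    def test_means_stay_physical(self, mcf7, closure, grid24):
        sol = integrate(closure, mcf7, grid=grid24)
        assert np.all(sol.mX >= -1e-9) and np.all(sol.mX <= 1 + 1e-9)
        assert np.all(sol.mY >= -1e-9) and np.all(sol.mZ >= -1e-9)
        assert np.all(np.diff(sol.mX) <= 1e-9)  # monotone decay, baseline model

    def test_long_time_limit_is_zero_steady_state(self, mcf7, mda):
        for rates in (mcf7, mda):
            sol = integrate("conditional", rates, grid=np.linspace(0, 200, 101))
            assert sol.mX[-1] < 1e-6 and sol.mY[-1] < 1e-6 and sol.mZ[-1] < 1e-6

    def test_agrees_with_fixed_step_rk4(self, mcf7):
        # independent fixed-step fourth-order reference on the naive system
        grid = np.linspace(0, 2, 9)
        sol = integrate("naive", mcf7, grid=grid, rtol=1e-10, atol=1e-12)
        n_steps = 20000  # 2500 fixed steps per grid interval
        h = 2.0 / n_steps
        y = np.array([1.0, 0.0, 0.0])
        out = [y.copy()]
        for i in range(1, n_steps + 1):
            k1 = rhs_naive(y, mcf7)
            k2 = rhs_naive(y + h / 2 * k1, mcf7)
            k3 = rhs_naive(y + h / 2 * k2, mcf7)
            k4 = rhs_naive(y + h * k3, mcf7)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            if i % 2500 == 0:
                out.append(y.copy())
        ref = np.array(out)
        np.testing.assert_allclose(sol.mX, ref[:, 0], rtol=1e-6, atol=1e-10)
        np.testing.assert_allclose(sol.mZ, ref[:, 2], rtol=1e-6, atol=1e-8)

    def test_tolerance_halving_stability(self, mcf7):
        g = np.linspace(0, 24, 25)
        a = integrate("conditional", mcf7, grid=g, rtol=1e-6, atol=1e-8)
        b = integrate("conditional", mcf7, grid=g, rtol=5e-7, atol=5e-9)
        assert abs(a.mX[-1] - b.mX[-1]) < 10 * 1e-6

    def test_rejects_auger_on_conditional_closure(self, mcf7):
        ext = ExtensionRates(k7=1, k8=10, tat0=0.05, kappa=0.002, R=4)
        with pytest.raises(ValueError, match="naive"):
            integrate("conditional", mcf7, ext=ext)


class TestAntibodyExtension:
    def test_null_extension_identical_rhs(self, mcf7):
        null = ExtensionRates(k7=1.0, k8=10.0, tat0=0.0)
        d_ext = rhs_antibody((0.7, 20.0, 80.0, 0.0), mcf7, null)
        d_base = rhs_naive((0.7, 20.0, 80.0), mcf7)
        np.testing.assert_array_equal(d_ext[:3], d_base)
        assert d_ext[3] == 0.0

    @pytest.mark.parametrize("closure", ["naive", "conditional"])
    def test_null_extension_identical_trajectories(self, mcf7, closure, grid24):
        null = ExtensionRates(k7=1.0, k8=10.0, tat0=0.0)
        with_ext = integrate(closure, mcf7, ext=null, grid=grid24)
        base = integrate(closure, mcf7, grid=grid24)
        np.testing.assert_allclose(with_ext.mX, base.mX, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(with_ext.mZ, base.mZ, rtol=1e-8, atol=1e-9)
        assert np.all(with_ext.mQ == 0)

    def test_binding_equilibrium_fixed_point(self, mcf7):
        # with mZ held at z, dmQ/dt vanishes exactly at mQ = (k8 tat0 / k7) z
        # and drives mQ toward that value from either side
        z = 120.0
        q_star = EXT.k8 * EXT.tat0 / EXT.k7 * z
        assert rhs_antibody((0.5, 10.0, z, q_star), mcf7, EXT)[3] == pytest.approx(0, abs=1e-9)
        assert rhs_antibody((0.5, 10.0, z, q_star / 2), mcf7, EXT)[3] > 0
        assert rhs_antibody((0.5, 10.0, z, q_star * 2), mcf7, EXT)[3] < 0

    def test_compensatory_phosphorylation(self, mcf7, grid24):
        # total phosphorylated H2AX (free + antibody-bound) exceeds the
        # unperturbed trajectory: binding masks gammaH2AX, lowering the
        # dephosphorylation flux, so more H2AX ends up phosphorylated
        base = integrate("conditional", mcf7, grid=grid24)
        sol = integrate("conditional", mcf7, ext=EXT, grid=grid24)
        total = sol.mZ + sol.mQ
        assert np.all(total[1:] >= base.mZ[1:] - 1e-9)
        assert total.max() > base.mZ.max() * 1.05


class TestAugerExtension:
    def test_zero_activity_reduces_to_antibody(self, mcf7, grid24):
        ext0 = ExtensionRates(k7=1, k8=10, tat0=0.05, kappa=0.002, R=0.0)
        a = integrate("naive", mcf7, ext=ext0, grid=grid24)
        b = integrate("naive", mcf7, ext=EXT, grid=grid24)
        np.testing.assert_array_equal(a.mX, b.mX)
        np.testing.assert_array_equal(a.mQ, b.mQ)

    def test_no_re_damage_when_saturated(self, mcf7):
        ext = ExtensionRates(k7=1, k8=10, tat0=0.05, kappa=0.002, R=8.0)
        d = rhs_auger((1.0, 0.0, 0.0, 50.0), mcf7, ext)
        assert d[0] == pytest.approx(0.0)  # no undamaged sites left to hit

    def test_damage_increases_with_specific_activity(self, mcf7):
        sols = []
        for R in (0.0, 4.0, 8.0):
            ext = ExtensionRates(k7=1, k8=10, tat0=0.05, kappa=0.002, R=R)
            sols.append(integrate("naive", mcf7, ext=ext, grid=np.linspace(0, 24, 49)))
        # pointwise non-decreasing in R after the initial repair phase
        late = slice(10, None)
        assert np.all(sols[1].mX[late] >= sols[0].mX[late] - 1e-9)
        assert np.all(sols[2].mX[late] >= sols[1].mX[late] - 1e-9)


class TestPersistenceAuc:
    def test_zero_and_rectangle(self):
        sol = integrate("naive", ZERO, init=MeanState(mX=0, mY=0, mZ=0),
                        grid=np.linspace(0, 24, 25))
        assert persistence_auc(sol, 160, 24) == 0.0
        sol1 = integrate("naive", ZERO, init=MeanState(mX=1, mY=0, mZ=0),
                         grid=np.linspace(0, 24, 25))
        assert persistence_auc(sol1, 160, 24) == pytest.approx(160 * 24)

    def test_endpoint_interpolation_and_span_error(self, mcf7):
        sol = integrate("naive", mcf7, grid=np.linspace(0, 24, 49))
        full = persistence_auc(sol, 160, 24.0)
        part = persistence_auc(sol, 160, 11.7)
        assert 0 < part < full
        with pytest.raises(ValueError, match="span"):
            persistence_auc(sol, 160, 25.0)
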