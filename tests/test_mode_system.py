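"""Truncated uniform mode dynamics: fixed points, growth rates, thresholds."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from nempol.collisions import CollisionRuleParams, build_collision_table
from nempol.mode_system import (
    FixedPointError,
    ModeState,
    ModelParams,
    critical_density,
    find_uniform_branch,
    growth_rate,
    nematic_branch,
    nematic_polar_threshold,
    odd_sector_max_growth,
    order_parameters,
    table_for,
    uniform_rhs,
)

from conftest import SIGMA, make_params


class TestOrderParameters:
    def test_disordered(self):
        st = ModeState.disordered(0.5, 10)
        P, Q, p1, p2 = order_parameters(st)
        assert np.allclose(P, 0) and np.allclose(Q, 0) and p1 == p2 == 0

    def test_fully_polar(self):
        amp = np.zeros(11, complex)
        amp[0] = amp[1] = 0.7
        P, Q, p1, _ = order_parameters(ModeState(amp))
        assert np.allclose(P, [1.0, 0.0]) and p1 == pytest.approx(1.0)

    def test_nematic_director_along_x(self):
        amp = np.zeros(11, complex)
        amp[0] = amp[2] = 0.4
        _, Q, _, p2 = order_parameters(ModeState(amp))
        assert np.allclose(Q, [[0.5, 0.0], [0.0, -0.5]])
        assert p2 == pytest.approx(1.0)
        assert Q[0, 0] + Q[1, 1] == pytest.approx(0.0)  # traceless

    def test_zero_density_degenerate(self):
        with pytest.raises(ValueError):
            order_parameters(ModeState.disordered(0.0, 10))


class TestUniformRhs:
    def test_disordered_is_fixed_point(self, table_bias):
        p = make_params(0.3, psi=0.075 * np.pi)
        rhs = uniform_rhs(ModeState.disordered(0.3, 10), p, table_bias)
        assert np.max(np.abs(rhs)) < 1e-14

    def test_density_conserved(self, table_bias):
        rng = np.random.default_rng(0)
        amp = 0.05 * (rng.standard_normal(11) + 1j * rng.standard_normal(11))
        amp[0] = 0.3
        p = make_params(0.3, psi=0.075 * np.pi)
        assert uniform_rhs(ModeState(amp), p, table_bias)[0] == 0.0

    def test_even_sector_closure(self, table_psi0):
        """A state with zero odd modes has exactly zero odd derivatives."""
        rng = np.random.default_rng(1)
        amp = np.zeros(11, complex)
        amp[0] = 0.3
        amp[2::2] = 0.05 * (rng.standard_normal(5) + 1j * rng.standard_normal(5))
        p = make_params(0.3, psi=0.0)
        rhs = uniform_rhs(ModeState(amp), p, table_psi0)
        assert np.max(np.abs(rhs[1::2])) == 0.0

    def test_small_f2_growth_matches_linear_rate(self, table_psi0):
        p = make_params(0.2, psi=0.0)
        eps = 1e-8
        amp = np.zeros(11, complex)
        amp[0], amp[2] = 0.2, eps
        rhs = uniform_rhs(ModeState(amp), p, table_psi0)
        mu2 = growth_rate(2, p, table_psi0)
        assert rhs[2].real / eps == pytest.approx(mu2, rel=1e-5)

    def test_table_params_mismatch_rejected(self, table_psi0):
        p = make_params(0.2, psi=0.3)
        with pytest.raises(ValueError):
            uniform_rhs(ModeState.disordered(0.2, 10), p, table_psi0)


class TestGrowthRates:
    def test_pure_decay_at_zero_density(self, table_bias):
        p = make_params(0.0, psi=0.075 * np.pi)
        for k in (1, 2, 3):
            assert growth_rate(k, p, table_bias) < 0

    def test_zero_at_critical_density(self, table_psi0):
        rho2c = critical_density(2, SIGMA, 0.0, table_psi0)
        p = make_params(rho2c, psi=0.0)
        assert growth_rate(2, p, table_psi0) == pytest.approx(0.0, abs=1e-12)
        p2 = make_params(2 * rho2c, psi=0.0)
        assert growth_rate(2, p2, table_psi0) > 0

    def test_critical_density_scales_inversely_with_kernel(self):
        base = CollisionRuleParams(psi=0.0, sigma_c=SIGMA, kernel_prefactor=1.0)
        dbl = CollisionRuleParams(psi=0.0, sigma_c=SIGMA, kernel_prefactor=2.0)
        r1 = critical_density(2, SIGMA, 0.0, build_collision_table(4, base))
        r2 = critical_density(2, SIGMA, 0.0, build_collision_table(4, dbl))
        assert r2 == pytest.approx(r1 / 2.0, rel=1e-12)

    def test_critical_density_agrees_with_bisection(self, table_psi0):
        """Closed-form rho_2c equals the root of mu_2 found by bisection."""
        rho2c = critical_density(2, SIGMA, 0.0, table_psi0)

        def mu2(rho):
            return growth_rate(2, make_params(rho, psi=0.0), table_psi0)

        root = brentq(mu2, 0.5 * rho2c, 2.0 * rho2c, xtol=1e-14)
        assert root == pytest.approx(rho2c, rel=1e-10)

    def test_critical_curves_cross_at_intermediate_bias(self, prefactor):
        """rho_1c and rho_2c cross as the polar bias increases."""
        def caps(psi_pi):
            t = table_for(make_params(0.2, psi=psi_pi * np.pi))
            return (critical_density(1, SIGMA, psi_pi * np.pi, t),
                    critical_density(2, SIGMA, psi_pi * np.pi, t))

        r1_lo, r2_lo = caps(0.125)
        r1_hi, r2_hi = caps(0.15)
        assert r1_lo > r2_lo and r1_hi < r2_hi


class TestUniformBranches:
    def test_disordered_below_thresholds(self, table_bias):
        p = make_params(0.1, psi=0.075 * np.pi)
        br = find_uniform_branch(p, table_bias)
        assert br.symmetry == "disordered"

    def test_nematic_above_rho2c_at_moderate_bias(self, table_bias):
        """At psi = 0.075 pi just above rho_2c the uniform solution is
        nematic: f1 stays zero, f2 grows."""
        p = make_params(0.25, psi=0.075 * np.pi)
        br = find_uniform_branch(p, table_bias, seed="nematic")
        assert br.symmetry == "nematic"
        assert abs(br.f1) < 1e-8
        assert abs(br.f2) > 0.05
        assert br.f2.real > 0 and abs(br.f2.imag) < 1e-9  # gauge fixed

    def test_fixed_point_matches_independent_stiff_integration(self, table_bias):
        """The Newton fixed point equals the long-time limit of a separate
        stiff integrator run from the same seeded initial condition."""
        p = make_params(0.25, psi=0.075 * np.pi)
        br = find_uniform_branch(p, table_bias, seed="nematic")

        amp0 = np.zeros(11, complex)
        amp0[0], amp0[2] = 0.25, 1e-3 * 0.25

        def ode(t, y):
            amp = np.zeros(11, complex)
            amp[0] = 0.25
            amp[1:] = y[:10] + 1j * y[10:]
            r = uniform_rhs(ModeState(amp), p, table_bias)[1:]
            return np.concatenate([r.real, r.imag])

        y0 = np.concatenate([amp0[1:].real, amp0[1:].imag])
        sol = solve_ivp(ode, (0, 4000.0), y0, method="BDF", rtol=1e-10, atol=1e-13)
        f = sol.y[:10, -1] + 1j * sol.y[10:, -1]
        assert abs(f[1]) == pytest.approx(abs(br.f2), abs=1e-8)

    def test_gauge_covariance(self, table_bias):
        """Rotating all modes f_k -> f_k e^{i k phi} maps fixed points to
        fixed points."""
        p = make_params(0.25, psi=0.075 * np.pi)
        br = find_uniform_branch(p, table_bias, seed="nematic")
        rng = np.random.default_rng(3)
        for phi in rng.uniform(-np.pi, np.pi, 3):
            rot = br.state.rotated(phi)
            assert np.max(np.abs(uniform_rhs(rot, p, table_bias))) < 1e-9

    def test_truncation_convergence(self, prefactor):
        """Branch amplitudes at kc=10 vs kc=14 agree to 1e-4 relative."""
        amps = {}
        for kc in (10, 14):
            p = ModelParams(rho_bar=0.25, sigma=SIGMA, psi=0.075 * np.pi, kc=kc)
            t = table_for(p, kmax=kc)
            amps[kc] = abs(nematic_branch(p, t).f2)
        assert amps[14] == pytest.approx(amps[10], rel=1e-4)


class TestNematicPolarThreshold:
    def test_absent_without_bias(self, table_psi0):
        assert nematic_polar_threshold(SIGMA, 0.0, table_psi0, rho_max=0.5) is None

    def test_present_at_moderate_bias(self, prefactor):
        psi = 0.1 * np.pi
        t = table_for(make_params(0.3, psi=psi))
        thr = nematic_polar_threshold(SIGMA, psi, t, rho_max=0.5)
        assert thr is not None
        rho2c = critical_density(2, SIGMA, psi, t)
        assert thr > rho2c

    def test_branch_switching_oracle(self, prefactor):
        """Crossing the threshold switches the attractor seeded from a tiny
        odd perturbation of the nematic branch from nematic to polar."""
        psi = 0.1 * np.pi
        t = table_for(make_params(0.3, psi=psi))
        thr = nematic_polar_threshold(SIGMA, psi, t, rho_max=0.5)
        margin = 0.02
        below = find_uniform_branch(make_params(thr - margin, psi=psi), t, seed="polar")
        above = find_uniform_branch(make_params(thr + margin, psi=psi), t, seed="polar")
        assert below.symmetry == "nematic"
        assert above.symmetry == "polar"

    def test_threshold_is_an_odd_sector_zero_crossing(self, prefactor):
        psi = 0.1 * np.pi
        t = table_for(make_params(0.3, psi=psi))
        thr = nematic_polar_threshold(SIGMA, psi, t, rho_max=0.5)
        for rho, sign in ((thr * 0.97, -1), (thr * 1.03, +1)):
            p = make_params(rho, psi=psi)
            br = nematic_branch(p, t)
            assert np.sign(odd_sector_max_growth(br, p, t)) == sign


def test_branch_scan_exports_csv_rows(table_bias, tmp_path):
    from nempol.mode_system import branch_scan

    df = branch_scan([0.1, 0.25], SIGMA, 0.075 * np.pi, table_bias)
    assert list(df["symmetry"]) == ["disordered", "nematic"]
    out = tmp_path / "scan.csv"
    df.to_csv(out, index=False)
    assert out.exists() and "f2_abs" in out.read_text()
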