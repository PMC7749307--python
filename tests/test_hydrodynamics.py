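"""Hydrodynamic field theory: coefficients, thresholds, spectral solver."""

import numpy as np
import pytest

from nempol.hydrodynamics import (
    HydroConfig,
    HydroFields,
    classify_point_hydro,
    default_coefficients,
    derive_linear_coefficients,
    hydro_linear_matrix,
    hydro_max_growth,
    hydro_rhs,
    initial_fields,
    minimal_alpha2,
    nematic_amplitude,
    nematic_polar_threshold_hydro,
    polar_fixed_point,
    run_hydro,
)
from nempol.mode_system import ModelParams, critical_density, table_for

from conftest import SIGMA


@pytest.fixture(scope="module")
def coeffs():
    return default_coefficients(alpha2=1.5)


class TestCoefficients:
    def test_nematic_onset_matches_kinetic_theory_exactly(self, coeffs, table_psi0):
        """beta0/beta1 equals the kinetic rho_2c at psi=0 (same collision
        integrals enter both theories)."""
        rho2c_kin = critical_density(2, SIGMA, 0.0, table_psi0)
        assert coeffs.rho_2c == pytest.approx(rho2c_kin, rel=1e-12)

    def test_linear_coefficients_vanish_without_noise(self, prefactor):
        from nempol.collisions import CollisionRuleParams, build_collision_table

        sig = 1e-4
        t = build_collision_table(4, CollisionRuleParams(
            psi=0.0, sigma_c=sig, kernel_prefactor=prefactor))
        a0, a1, b0, b1 = derive_linear_coefficients(sig, t)
        assert a0 < 1e-8 and b0 < 1e-7

    def test_alpha0_below_beta0(self, coeffs):
        # 1 - e^{-sigma^2/2} < 1 - e^{-2 sigma^2}
        assert coeffs.alpha0 < coeffs.beta0

    def test_invariants_satisfied_by_defaults(self, coeffs):
        assert coeffs.beta0 > 0 and coeffs.beta1 > 0
        assert coeffs.alpha0 > 0 and coeffs.alpha1 > 0
        assert coeffs.alpha3 > 0 and coeffs.beta3 > 0

    def test_nematic_amplitude_finite_above_onset(self, coeffs):
        rho2c = coeffs.rho_2c
        for rho in np.linspace(1.01 * rho2c, 2 * rho2c, 7):
            F = nematic_amplitude(rho, coeffs)
            assert 0 < F < np.inf

    def test_override_roundtrip(self):
        c = default_coefficients(alpha2=1.1, gamma3=0.123)
        assert c.alpha2 == 1.1 and c.gamma3 == 0.123

    def test_psi_table_rejected(self, table_bias):
        with pytest.raises(ValueError):
            derive_linear_coefficients(SIGMA, table_bias)


class TestThresholds:
    def test_no_threshold_without_coupling(self):
        c = default_coefficients(alpha2=0.0)
        assert nematic_polar_threshold_hydro(c) is None

    def test_threshold_decreases_with_coupling(self):
        thr = [nematic_polar_threshold_hydro(default_coefficients(alpha2=a))
               for a in (1.4, 1.6, 1.9)]
        assert all(t is not None for t in thr)
        assert thr[0] > thr[1] > thr[2]

    def test_minimal_alpha2_is_the_existence_edge(self, coeffs):
        a_min = minimal_alpha2(coeffs)
        below = default_coefficients(alpha2=0.99 * a_min)
        above = default_coefficients(alpha2=1.01 * a_min)
        assert nematic_polar_threshold_hydro(below) is None
        assert nematic_polar_threshold_hydro(above) is not None

    def test_polar_state_appears_above_threshold(self, coeffs):
        thr = nematic_polar_threshold_hydro(coeffs)
        sol = polar_fixed_point(thr * 1.05, coeffs)
        assert sol is not None and sol[0] > 0


class TestHydroRhs:
    def test_uniform_disordered_stationary(self, coeffs):
        N = 32
        z = np.zeros((N, N), complex)
        f = HydroFields(np.full((N, N), 0.1, complex), z.copy(), z.copy(), 40.0)
        dr, d1, d2 = hydro_rhs(f, coeffs)
        assert np.max(np.abs(dr)) == 0 and np.max(np.abs(d1)) == 0 \
            and np.max(np.abs(d2)) == 0

    def test_uniform_nematic_branch_stationary(self, coeffs):
        N = 32
        rho = 0.2
        F = nematic_amplitude(rho, coeffs)
        f = HydroFields(np.full((N, N), rho, complex),
                        np.zeros((N, N), complex),
                        np.full((N, N), F, complex), 40.0)
        dr, d1, d2 = hydro_rhs(f, coeffs)
        assert np.max(np.abs(d2)) < 1e-14 and np.max(np.abs(d1)) < 1e-14

    def test_spectral_gradient_matches_finite_differences(self, coeffs):
        """Gradients of a smooth test field agree with a high-order
        finite-difference oracle."""
        N, L = 64, 40.0
        x = np.linspace(0, L, N, endpoint=False)
        X, Y = np.meshgrid(x, x, indexing="xy")
        rho = 0.2 + 0.01 * np.sin(2 * np.pi * X / L) * np.cos(4 * np.pi * Y / L)
        f1 = 0.01 * np.exp(1j * 2 * np.pi * (X + 2 * Y) / L)
        f2 = 0.02 * np.exp(-1j * 2 * np.pi * (2 * X - Y) / L)
        fields = HydroFields(rho.astype(complex), f1, f2, L)
        dr, d1, d2 = hydro_rhs(fields, coeffs)

        h = L / N
        # 8th-order central differences
        stencil = [(1 / 280, -4), (-4 / 105, -3), (1 / 5, -2), (-4 / 5, -1),
                   (4 / 5, 1), (-1 / 5, 2), (4 / 105, 3), (-1 / 280, 4)]

        def ddx(f):
            return sum(c * np.roll(f, -s, axis=1) for c, s in stencil) / h

        def ddy(f):
            return sum(c * np.roll(f, -s, axis=0) for c, s in stencil) / h

        drho_fd = -np.real(ddx(f1) - 1j * ddy(f1))
        assert np.max(np.abs(dr - drho_fd)) < 1e-8


class TestRunHydro:
    def test_decay_below_onset(self, coeffs):
        cfg = HydroConfig(coeffs=coeffs, rho_bar=0.10, L=40.0, N=32, dt=0.1,
                          t_end=60.0, out_every=30.0, seed=5)
        snaps = run_hydro(cfg)
        assert np.max(np.abs(snaps[-1]["f2"])) < 0.2 * np.max(np.abs(snaps[0]["f2"]))
        assert np.max(np.abs(snaps[-1]["f1"])) < 0.2 * np.max(np.abs(snaps[0]["f1"]))

    def test_mean_density_exactly_conserved(self, coeffs):
        cfg = HydroConfig(coeffs=coeffs, rho_bar=0.18, L=40.0, N=32, dt=0.1,
                          t_end=30.0, out_every=30.0, seed=6)
        snaps = run_hydro(cfg)
        assert np.mean(snaps[-1]["rho"]) == pytest.approx(0.18, abs=1e-13)

    def test_uniform_nematic_init_stationary(self, coeffs):
        rho = 0.2
        N = 32
        F = nematic_amplitude(rho, coeffs)
        fields = HydroFields(np.full((N, N), rho, complex),
                             np.zeros((N, N), complex),
                             np.full((N, N), F, complex), 40.0)
        cfg = HydroConfig(coeffs=coeffs, rho_bar=rho, L=40.0, N=N, dt=0.05,
                          t_end=50.0, out_every=50.0, seed=0)
        snaps = run_hydro(cfg, fields=fields)
        # preserved to integrator tolerance (O(dt^3) splitting error/step)
        assert np.max(np.abs(snaps[-1]["f2"] - F)) < 1e-7
        assert np.max(np.abs(snaps[-1]["f1"])) < 1e-7

    def test_seeded_initial_condition_deterministic(self, coeffs):
        cfg = HydroConfig(coeffs=coeffs, rho_bar=0.18, L=40.0, N=32, seed=9)
        a, b = initial_fields(cfg), initial_fields(cfg)
        assert np.array_equal(a.rho, b.rho) and np.array_equal(a.f1, b.f1)

    def test_gauge_rotation_covariance(self, coeffs):
        """Rotating the fields (f1 -> i f1, f2 -> -f2) together with a 90-degree
        rotation of the grid maps solutions to solutions."""
        N = 32
        rng = np.random.default_rng(12)
        rho = (0.18 * (1 + 0.02 * rng.standard_normal((N, N)))).astype(complex)
        f1 = 0.002 * (rng.standard_normal((N, N)) + 1j * rng.standard_normal((N, N)))
        f2 = 0.002 * (rng.standard_normal((N, N)) + 1j * rng.standard_normal((N, N)))
        cfg = HydroConfig(coeffs=coeffs, rho_bar=0.18, L=40.0, N=N, dt=0.1,
                          t_end=10.0, out_every=10.0, seed=0)

        def rot(a):  # 90-degree grid rotation matching the phase -i on f1
            return np.rot90(a, k=1)

        out1 = run_hydro(cfg, fields=HydroFields(rho.copy(), f1.copy(), f2.copy(), 40.0))
        out2 = run_hydro(cfg, fields=HydroFields(rot(rho), -1j * rot(f1), -rot(f2), 40.0))
        assert np.max(np.abs(out2[-1]["rho"] - rot(out1[-1]["rho"]))) < 1e-9
        assert np.max(np.abs(out2[-1]["f1"] + 1j * rot(out1[-1]["f1"]))) < 1e-9
        assert np.max(np.abs(out2[-1]["f2"] + rot(out1[-1]["f2"]))) < 1e-9

    def test_measured_growth_matches_linearization(self, coeffs):
        """A small plane-wave perturbation of the uniform nematic branch
        grows/decays at the rate predicted by the linear stability matrix,
        within 2%."""
        rho0, L, N = 0.18, 80.0, 64
        F = nematic_amplitude(rho0, coeffs)
        q = 2 * np.pi * 1 / L  # one perpendicular wavelength in the box
        A = hydro_linear_matrix(rho0, 0.0, F, coeffs, 1j * q)
        w, V = np.linalg.eig(A)
        i = int(np.argmax(w.real))
        s_pred = float(w[i].real)
        v = V[:, i]
        eps = 1e-6
        y = np.linspace(0, L, N, endpoint=False)[:, None] * np.ones((1, N))
        wave = np.exp(1j * q * y)
        rho = np.full((N, N), rho0, complex) + eps * (v[0] * wave).real * 2
        f1 = eps * (v[1] * wave + np.conj(v[2] * wave))
        f2 = np.full((N, N), F, complex) + eps * (v[3] * wave + np.conj(v[4] * wave))
        cfg = HydroConfig(coeffs=coeffs, rho_bar=rho0, L=L, N=N, dt=0.05,
                          t_end=40.0, out_every=20.0, seed=0)
        snaps = run_hydro(cfg, fields=HydroFields(rho, f1, f2, L))
        amp = [np.abs(np.fft.fft2(s["f1"])[1, 0]) for s in snaps]
        s_meas = np.log(amp[-1] / amp[0]) / (snaps[-1]["t"] - snaps[0]["t"])
        assert s_meas == pytest.approx(s_pred, rel=0.02)


class TestClassification:
    def test_disordered_below_onset(self, coeffs):
        assert classify_point_hydro(0.12, coeffs) == "disordered"

    def test_bands_then_polar_with_density(self, coeffs):
        assert classify_point_hydro(0.18, coeffs) == "nematic bands"
        thr = nematic_polar_threshold_hydro(coeffs)
        assert classify_point_hydro(thr * 1.05, coeffs) in ("polar waves", "uniform polar")

    def test_band_instability_is_perpendicular(self, coeffs):
        F = nematic_amplitude(0.18, coeffs)
        sperp, _ = hydro_max_growth(0.18, 0.0, F, coeffs, "perpendicular")
        spar, _ = hydro_max_growth(0.18, 0.0, F, coeffs, "parallel")
        assert sperp > 0 and sperp > spar
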