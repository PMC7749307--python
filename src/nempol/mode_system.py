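"""Spatially uniform truncated angular-Fourier dynamics of the kinetic theory.

With spatial gradients dropped and modes truncated at ``|k| <= kc``, the
Boltzmann equation reduces to a closed ODE system for the complex
amplitudes ``f_k``:

    d f_k / dt = -lambda (1 - e^{-k^2 sigma^2 / 2}) f_k
                 + sum_n I_{n,k} f_n f_{k-n},

with ``f_0 = rho`` (exactly conserved, since ``I_{n,0} = 0``) and
``f_{-k} = conj(f_k)``.  This module provides the right-hand side, its
analytic Jacobian, linear growth rates about disorder, critical densities,
a Newton/relaxation fixed-point solver with symmetry classification, and
the density threshold at which the nematic branch destabilizes toward
polar order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from nempol.collisions import (
    CollisionRuleParams,
    CollisionTable,
    QuadratureSettings,
    build_collision_table,
    default_kernel_prefactor,
)

__all__ = [
    "ModelParams",
    "ModeState",
    "UniformBranch",
    "FixedPointError",
    "order_parameters",
    "uniform_rhs",
    "growth_rate",
    "critical_density",
    "find_uniform_branch",
    "nematic_branch",
    "odd_sector_max_growth",
    "nematic_polar_threshold",
    "branch_scan",
    "uniform_jacobian_blocks",
    "real_jacobian",
    "table_for",
]

#: symmetry-classification threshold on |f_k| / rho (well above solver
#: tolerance, far below physical order amplitudes)
SYMMETRY_TOL = 1e-4


class FixedPointError(RuntimeError):
    """Raised when no uniform fixed point could be located."""


@dataclass(frozen=True)
class ModelParams:
    """Physical parameters of the kinetic model (rescaled units v0=lambda=d=1).

    ``rho_bar`` is the mean density in units of ``lambda/(d v0)``, ``sigma``
    the angular noise standard deviation, ``psi`` the polar bias of the
    collision rule and ``kc`` the angular-mode truncation order.
    """

    rho_bar: float
    sigma: float
    psi: float
    lam: float = 1.0
    v0: float = 1.0
    kc: int = 10
    sigma_c: Optional[float] = None  # collision noise; defaults to sigma
    kernel_prefactor: Optional[float] = None  # defaults to calibrated value

    def __post_init__(self):
        if self.rho_bar < 0.0:
            raise ValueError("rho_bar must be non-negative")
        if self.sigma <= 0.0:
            raise ValueError("sigma must be positive")
        if not (0.0 <= self.psi <= np.pi / 2.0 + 1e-15):
            raise ValueError("psi must lie in [0, pi/2]")
        if self.kc < 4:
            raise ValueError("kc must be at least 4")

    def collision_params(self) -> CollisionRuleParams:
        pref = self.kernel_prefactor
        if pref is None:
            pref = default_kernel_prefactor(lam=self.lam)
        sc = self.sigma if self.sigma_c is None else self.sigma_c
        return CollisionRuleParams(psi=self.psi, sigma_c=sc, kernel_prefactor=pref)

    def lam_k(self, k) -> np.ndarray:
        """Angular-diffusion decay rate ``lambda (1 - e^{-k^2 sigma^2/2})``."""
        k = np.asarray(k)
        return self.lam * (1.0 - np.exp(-0.5 * k**2 * self.sigma**2))


def table_for(params: ModelParams, kmax: Optional[int] = None,
              quadrature: QuadratureSettings = QuadratureSettings()) -> CollisionTable:
    """Build the collision table matching ``params``."""
    return build_collision_table(kmax or params.kc, params.collision_params(), quadrature)


def _check_consistency(params: ModelParams, table: CollisionTable):
    cp = params.collision_params()
    tp = table.params
    if (abs(cp.psi - tp.psi) > 1e-12 or abs(cp.sigma_c - tp.sigma_c) > 1e-12
            or abs(cp.kernel_prefactor - tp.kernel_prefactor) > 1e-9):
        raise ValueError("collision table does not match model parameters")
    if table.kmax < params.kc:
        raise ValueError(f"table kmax={table.kmax} below truncation kc={params.kc}")


@dataclass
class ModeState:
    """Uniform mode amplitudes ``f_0 .. f_kc`` (negative modes by conjugation)."""

    amplitudes: np.ndarray  # complex, length kc+1; amplitudes[0] is the density

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=complex)
        if abs(self.amplitudes[0].imag) > 1e-12 or self.amplitudes[0].real < 0:
            raise ValueError("f_0 must be real and non-negative")

    @property
    def rho(self) -> float:
        return float(self.amplitudes[0].real)

    @property
    def kc(self) -> int:
        return len(self.amplitudes) - 1

    def full_modes(self) -> np.ndarray:
        """Modes ``f_{-kc} .. f_{kc}`` as one array (index offset ``kc``)."""
        return np.concatenate([np.conj(self.amplitudes[:0:-1]), self.amplitudes])

    def rotated(self, phi: float) -> "ModeState":
        """Global rotation by ``phi``: ``f_k -> f_k e^{i k phi}``."""
        k = np.arange(self.kc + 1)
        return ModeState(self.amplitudes * np.exp(1j * k * phi))

    @classmethod
    def disordered(cls, rho: float, kc: int) -> "ModeState":
        amp = np.zeros(kc + 1, dtype=complex)
        amp[0] = rho
        return cls(amp)


@dataclass
class UniformBranch:
    """A uniform fixed point with its symmetry label and stability flags."""

    state: ModeState
    symmetry: str  # "disordered" | "nematic" | "polar"
    residual: float
    stable_uniform: Optional[bool] = None
    unstable_directions: frozenset = frozenset()

    @property
    def f1(self) -> complex:
        return complex(self.state.amplitudes[1])

    @property
    def f2(self) -> complex:
        return complex(self.state.amplitudes[2])


def order_parameters(state: ModeState):
    """Polar vector P, nematic tensor Q and normalized amplitudes of a state.

    ``rho P = (Re f1, Im f1)`` and
    ``rho Q = 1/2 [[Re f2, Im f2], [Im f2, -Re f2]]`` (traceless symmetric).
    """
    rho = state.rho
    if rho <= 0.0:
        raise ValueError("order parameters undefined at zero density")
    f1, f2 = state.amplitudes[1], state.amplitudes[2] if state.kc >= 2 else 0.0
    P = np.array([f1.real, f1.imag]) / rho
    Q = 0.5 * np.array([[f2.real, f2.imag], [f2.imag, -f2.real]]) / rho
    return P, Q, abs(f1) / rho, abs(f2) / rho


def _conv_rhs(F: np.ndarray, table: CollisionTable, kc: int) -> np.ndarray:
    """Collision convolution ``sum_n I_{n,k} F_n F_{k-n}`` for k = 0..kc."""
    I = table.values
    km = table.kmax
    out = np.empty(kc + 1, dtype=complex)
    for k in range(kc + 1):
        n = np.arange(max(-kc, k - kc), min(kc, k + kc) + 1)
        out[k] = np.sum(I[n + km, k + km] * F[n + kc] * F[k - n + kc])
    return out


def uniform_rhs(state: ModeState, params: ModelParams, table: CollisionTable) -> np.ndarray:
    """Time derivatives ``d f_k/dt`` (k = 0..kc) of the uniform mode system.

    ``d f_0/dt`` is identically zero: collisions and angular diffusion
    conserve the local density.
    """
    _check_consistency(params, table)
    kc = state.kc
    if kc > params.kc:
        raise ValueError("state truncation exceeds params.kc")
    F = state.full_modes()
    k = np.arange(kc + 1)
    rhs = -params.lam_k(k) * state.amplitudes + _conv_rhs(F, table, kc)
    rhs[0] = 0.0
    return rhs


def growth_rate(k: int, params: ModelParams, table: CollisionTable) -> float:
    """Linear growth rate ``mu_k`` of mode ``k`` about the disordered state.

    ``mu_k = Re(I_{0,k} + I_{k,k}) rho_bar - lambda (1 - e^{-k^2 sigma^2/2})``.
    """
    if k < 1:
        raise ValueError("growth rate defined for k >= 1")
    s = table.pair_sum(0, k)
    assert abs(s.imag) < 1e-8, "I_{0,k} + I_{k,k} should be real by symmetry"
    return float(s.real * params.rho_bar - params.lam_k(k))


def critical_density(k: int, sigma: float, psi: float, table: CollisionTable,
                     lam: float = 1.0) -> Optional[float]:
    """Critical density ``rho_kc`` where ``mu_k`` changes sign, or None."""
    if k not in (1, 2):
        raise ValueError("critical densities implemented for k in {1, 2}")
    denom = table.pair_sum(0, k).real
    if denom <= 0.0:
        return None
    return lam * (1.0 - np.exp(-0.5 * k**2 * sigma**2)) / denom


def uniform_jacobian_blocks(F: np.ndarray, params: ModelParams, table: CollisionTable,
                            kc: Optional[int] = None):
    """Wirtinger derivatives of the uniform RHS for modes ``k = 1..kc``.

    Returns complex matrices ``A[k-1, m-1] = dG_k/df_m`` and
    ``B[k-1, m-1] = dG_k/dconj(f_m)`` about the mode vector ``F``
    (indexed ``-kc..kc`` with offset ``kc``).
    """
    kc = kc or params.kc
    I = table.values
    km = table.kmax
    A = np.zeros((kc, kc), dtype=complex)
    B = np.zeros((kc, kc), dtype=complex)
    lamk = params.lam_k(np.arange(1, kc + 1))
    for k in range(1, kc + 1):
        for m in range(1, kc + 1):
            a = 0.0 + 0.0j
            if abs(k - m) <= kc:
                a += (I[m + km, k + km] + I[k - m + km, k + km]) * F[k - m + kc]
            if k == m:
                a -= lamk[k - 1]
            A[k - 1, m - 1] = a
            if abs(k + m) <= kc:
                B[k - 1, m - 1] = (I[-m + km, k + km] + I[k + m + km, k + km]) * F[k + m + kc]
    return A, B


def real_jacobian(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Real 2n x 2n Jacobian from Wirtinger blocks, variables (Re f, Im f)."""
    n = A.shape[0]
    J = np.empty((2 * n, 2 * n))
    J[:n, :n] = (A + B).real
    J[:n, n:] = -(A - B).imag
    J[n:, :n] = (A + B).imag
    J[n:, n:] = (A - B).real
    return J


def _pack(amp: np.ndarray, ks: np.ndarray) -> np.ndarray:
    return np.concatenate([amp[ks].real, amp[ks].imag])


def _unpack(x: np.ndarray, ks: np.ndarray, rho: float, kc: int) -> np.ndarray:
    amp = np.zeros(kc + 1, dtype=complex)
    amp[0] = rho
    n = len(ks)
    amp[ks] = x[:n] + 1j * x[n:]
    return amp


def _solve_fixed_point(params: ModelParams, table: CollisionTable, init: ModeState,
                       ks: np.ndarray, tol: float = 1e-11, max_newton: int = 60,
                       strategy: str = "newton") -> ModeState:
    """Fixed point of the dynamics restricted to the modes listed in ``ks``.

    ``strategy="newton"``: damped Newton from ``init``, with a
    time-integration fallback if it fails.  ``strategy="flow"``: integrate
    the (restricted) dynamics from ``init`` toward its attractor in chunks,
    Newton-polishing after each — this selects the fixed point the flow
    actually reaches, which is what branch seeding relies on.  A polished
    point that is linearly unstable within the probed sector (e.g. the
    disordered state above threshold) is rejected and integration
    continues, so slow near-threshold growth is given time to saturate.
    """
    kc = params.kc
    rho = init.rho

    def residual(x):
        amp = _unpack(x, ks, rho, kc)
        return ModeState(amp), uniform_rhs(ModeState(amp), params, table)[ks]

    def newton(x0):
        x = x0.copy()
        for _ in range(max_newton):
            st, r = residual(x)
            rn = np.max(np.abs(r)) if len(r) else 0.0
            if rn < tol:
                return x, rn
            A, Bm = uniform_jacobian_blocks(st.full_modes(), params, table, kc)
            idx = ks - 1
            J = real_jacobian(A[np.ix_(idx, idx)], Bm[np.ix_(idx, idx)])
            rv = np.concatenate([r.real, r.imag])
            try:
                dx = np.linalg.solve(J, rv)
            except np.linalg.LinAlgError:
                break
            step = 1.0
            # damped backtracking to keep Newton from overshooting steep branches
            for _ in range(8):
                _, r2 = residual(x - step * dx)
                if np.max(np.abs(r2)) < max(rn * (1 - 0.25 * step), tol):
                    break
                step *= 0.5
            x = x - step * dx
        st, r = residual(x)
        return x, np.max(np.abs(r)) if len(r) else 0.0

    def ode(t, y):
        _, r = residual(y)
        return np.concatenate([r.real, r.imag])

    def relax(y0, t_span=400.0):
        sol = solve_ivp(ode, (0.0, t_span), y0, method="LSODA", rtol=1e-10, atol=1e-12)
        return sol.y[:, -1]

    def sector_growth(x):
        """Max growth of the probed sector about x (rotation mode deflated)
        and the corresponding unstable direction."""
        amp = _unpack(x, ks, rho, kc)
        A, B = uniform_jacobian_blocks(ModeState(amp).full_modes(), params, table, kc)
        idx = ks - 1
        J = real_jacobian(A[np.ix_(idx, idx)], B[np.ix_(idx, idx)])
        w, V = np.linalg.eig(J)
        g = 1j * ks * amp[ks]
        gv = np.concatenate([g.real, g.imag])
        gn = np.linalg.norm(gv)
        keep = np.ones(len(w), dtype=bool)
        if gn > 1e-12:
            overlaps = np.abs((gv / gn) @ V) / np.linalg.norm(V, axis=0)
            i0 = int(np.argmax(overlaps))
            if abs(w[i0].real) < 1e-6:
                keep[i0] = False
        imax = int(np.argmax(np.where(keep, w.real, -np.inf)))
        vec = V[:, imax].real
        nv = np.linalg.norm(vec)
        return float(w[imax].real), vec / nv if nv > 0 else vec

    x0 = _pack(init.amplitudes, ks)
    if strategy == "flow":
        y = x0
        x, rn = np.full_like(x0, np.nan), np.inf
        t_chunk = 400.0
        for _ in range(16):
            y = relax(y, t_chunk)
            x, rn = newton(y)
            if rn < tol:
                s, vec = sector_growth(x)
                # only accept an attractor of the probed sector; a polish
                # that lands on a sector-unstable fixed point (e.g. unstable
                # disorder, or a nematic state on the way to polar) is
                # rejected, kicked along the unstable direction, and the
                # flow continued
                if s <= 1e-8:
                    break
                # re-seed along the unstable direction only if the flow is
                # still glued to the rejected fixed point; otherwise keep
                # the accumulated escape
                if np.linalg.norm(y - x) < 2e-3 * max(rho, 1e-3):
                    y = x + 1e-3 * max(rho, 1e-3) * vec
                t_chunk = min(2.0 * t_chunk, 3200.0)
    else:
        x, rn = newton(x0)
        if rn >= tol:
            x, rn = newton(relax(x0))
    if rn >= tol:
        raise FixedPointError(f"uniform fixed point did not converge (residual {rn:.2e})")
    return ModeState(_unpack(x, ks, rho, kc))


def _classify_and_gauge(state: ModeState) -> UniformBranch:
    rho = max(state.rho, 1e-300)
    f1, f2 = state.amplitudes[1], state.amplitudes[2]
    polar = abs(f1) / rho > SYMMETRY_TOL
    nematic = abs(f2) / rho > SYMMETRY_TOL
    if polar:
        sym, phi = "polar", -np.angle(f1)
    elif nematic:
        sym, phi = "nematic", -np.angle(f2) / 2.0
    else:
        sym, phi = "disordered", 0.0
        amp = state.amplitudes.copy()
        amp[1:] = 0.0
        state = ModeState(amp)
    return UniformBranch(state=state.rotated(phi), symmetry=sym, residual=0.0)


def find_uniform_branch(params: ModelParams, table: CollisionTable,
                        init: Optional[ModeState] = None, seed: str = "disordered",
                        tol: float = 1e-11, strategy: Optional[str] = None) -> UniformBranch:
    """Locate a uniform fixed point and classify its symmetry.

    ``seed`` selects the initial guess when ``init`` is not given:
    "disordered" (zeros), "nematic" (small f2), "polar" (small f1).  When
    seeding from a small perturbation the solver follows the flow to its
    attractor before polishing with Newton; when an explicit ``init`` is
    given (e.g. branch continuation) it Newton-iterates directly.  The
    returned branch is gauge-fixed so its dominant order parameter is real
    and positive.
    """
    _check_consistency(params, table)
    kc = params.kc
    if strategy is None:
        strategy = "newton" if init is not None else "flow"
    if init is None:
        amp = np.zeros(kc + 1, dtype=complex)
        amp[0] = params.rho_bar
        if seed == "nematic":
            amp[2] = 1e-3 * max(params.rho_bar, 1e-3)
        elif seed == "polar":
            amp[1] = 1e-3 * max(params.rho_bar, 1e-3)
            amp[2] = 1e-3 * max(params.rho_bar, 1e-3)
        elif seed != "disordered":
            raise ValueError(f"unknown seed {seed!r}")
        init = ModeState(amp)
    ks = np.arange(1, kc + 1)
    state = _solve_fixed_point(params, table, init, ks, tol=tol, strategy=strategy)
    branch = _classify_and_gauge(state)
    branch.residual = float(np.max(np.abs(uniform_rhs(branch.state, params, table))))
    return branch


def nematic_branch(params: ModelParams, table: CollisionTable,
                   init: Optional[ModeState] = None, tol: float = 1e-11) -> UniformBranch:
    """Nematic fixed point with odd modes pinned to zero (even-sector solve).

    With an explicit ``init`` (continuation along the branch) Newton is used
    directly; otherwise the even-sector flow is followed from a small seed,
    which cannot stall on the unstable disordered state above ``rho_2c``.
    """
    kc = params.kc
    strategy = "newton" if init is not None else "flow"
    if init is None:
        amp = np.zeros(kc + 1, dtype=complex)
        amp[0] = params.rho_bar
        amp[2] = 1e-3 * max(params.rho_bar, 1e-3)
        init = ModeState(amp)
    ks = np.arange(2, kc + 1, 2)
    state = _solve_fixed_point(params, table, init, ks, tol=tol, strategy=strategy)
    if strategy == "newton" and abs(state.amplitudes[2]) / max(params.rho_bar, 1e-300) < SYMMETRY_TOL:
        rho2c = critical_density(2, params.sigma, params.psi, table, params.lam)
        if rho2c is not None and params.rho_bar > rho2c:
            # Newton stalled on the (unstable) disordered state; follow the flow
            return nematic_branch(params, table, init=None, tol=tol)
    branch = _classify_and_gauge(state)
    branch.residual = float(np.max(np.abs(uniform_rhs(branch.state, params, table))))
    return branch


def odd_sector_max_growth(branch: UniformBranch, params: ModelParams,
                          table: CollisionTable) -> float:
    """Largest eigenvalue real part of the odd-mode linearization about a
    nematic (even-mode) fixed point.

    About a state with only even modes, the uniform Jacobian block-
    diagonalizes by parity; a positive odd-sector growth rate signals the
    onset of polar order on top of the nematic branch.
    """
    kc = params.kc
    F = branch.state.full_modes()
    A, B = uniform_jacobian_blocks(F, params, table, kc)
    idx = np.arange(1, kc + 1, 2) - 1
    J = real_jacobian(A[np.ix_(idx, idx)], B[np.ix_(idx, idx)])
    return float(np.max(np.linalg.eigvals(J).real))


def branch_scan(rhos, sigma: float, psi: float, table: CollisionTable,
                kc: int = 10, lam: float = 1.0, seed: str = "nematic"):
    """Continue a uniform branch over a density grid; returns a DataFrame
    with one row per density (|f1|, |f2|, symmetry), suitable for CSV
    export."""
    import pandas as pd

    rows = []
    prev = None
    for rho in np.asarray(rhos, dtype=float):
        p = ModelParams(rho_bar=rho, sigma=sigma, psi=psi, lam=lam, kc=kc,
                        sigma_c=table.params.sigma_c,
                        kernel_prefactor=table.params.kernel_prefactor)
        init = None
        # continue from the previous point only if it carried order; from a
        # disordered state the seeded flow must be used instead
        if prev is not None and prev.symmetry != "disordered":
            amp = prev.state.amplitudes.copy()
            amp[0] = rho
            init = ModeState(amp)
        try:
            br = find_uniform_branch(p, table, init=init, seed=seed)
            prev = br
            rows.append({"rho_bar": rho, "psi": psi, "sigma": sigma, "kc": kc,
                         "f1_abs": abs(br.f1), "f2_abs": abs(br.f2),
                         "symmetry": br.symmetry})
        except FixedPointError:
            prev = None
            rows.append({"rho_bar": rho, "psi": psi, "sigma": sigma, "kc": kc,
                         "f1_abs": np.nan, "f2_abs": np.nan,
                         "symmetry": "unresolved"})
    return pd.DataFrame(rows)


def nematic_polar_threshold(sigma: float, psi: float, table: CollisionTable,
                            kc: int = 10, rho_max: float = 0.5, n_scan: int = 48,
                            lam: float = 1.0, xtol: float = 1e-8) -> Optional[float]:
    """Density at which the uniform nematic branch destabilizes toward polar
    order, or None if no such crossing exists below ``rho_max``.

    Scans the nematic branch upward in density from just above ``rho_2c``
    (continuing the solution from one density to the next) and bisects the
    first sign change of the odd-sector growth rate.
    """
    pref = table.params.kernel_prefactor
    rho2c = critical_density(2, sigma, psi, table, lam)
    if rho2c is None or rho2c >= rho_max:
        return None

    def branch_at(rho, init):
        p = ModelParams(rho_bar=rho, sigma=sigma, psi=psi, lam=lam, kc=kc,
                        sigma_c=table.params.sigma_c, kernel_prefactor=pref)
        if init is not None:
            amp = init.state.amplitudes.copy()
            amp[0] = rho
            init_state = ModeState(amp)
        else:
            init_state = None
        br = nematic_branch(p, table, init=init_state)
        return p, br

    rhos = np.linspace(rho2c * 1.02, rho_max, n_scan)
    prev = None
    last_s, last_rho = None, None
    for rho in rhos:
        try:
            p, br = branch_at(rho, prev)
        except FixedPointError:
            return None
        if br.symmetry != "nematic":
            prev = None
            continue
        s = odd_sector_max_growth(br, p, table)
        if last_s is not None and last_s < 0.0 <= s:
            carry = br

            def g(r):
                nonlocal carry
                p2, b2 = branch_at(r, carry)
                carry = b2
                return odd_sector_max_growth(b2, p2, table)

            return float(brentq(g, last_rho, rho, xtol=xtol))
        last_s, last_rho = s, rho
        prev = br
    return None
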