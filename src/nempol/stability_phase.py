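"""Linear stability of uniform branches and phase-diagram construction.

A uniform fixed point ``F_k`` of the truncated mode system is perturbed by
plane waves ``delta f_k ~ e^{i q . r + s t}``.  Because a traveling
perturbation breaks the conjugation pairing ``f_{-k} = conj(f_k)``, all
modes ``-kc..kc`` (including the density mode ``k = 0``) enter as
independent perturbation amplitudes.  The linearization couples them
through the collision/diffusion part and the advection term
``-(v0/2) [ i conj(q_c) delta f_{k+1} + i q_c delta f_{k-1} ]`` with
``q_c = q_x + i q_y``.

The wave vector is probed along the two principal directions relative to
the gauge-fixed order (x axis): "parallel" (``q || x``) and
"perpendicular" (``q || y``).  A nematic state unstable to perpendicular
waves forms bands; a polar state unstable to parallel waves forms
traveling waves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from nempol.collisions import CollisionTable
from nempol.mode_system import (
    FixedPointError,
    ModelParams,
    ModeState,
    SYMMETRY_TOL,
    UniformBranch,
    critical_density,
    find_uniform_branch,
    nematic_branch,
    nematic_polar_threshold,
    odd_sector_max_growth,
    real_jacobian,
    table_for,
    uniform_jacobian_blocks,
    uniform_rhs,
)

__all__ = [
    "WavePerturbation",
    "StabilityResult",
    "PhaseDiagram",
    "default_q_grid",
    "spatial_jacobian",
    "max_growth",
    "uniform_max_growth",
    "stability_of",
    "classify_point",
    "phase_diagram",
    "polar_branch_continuation",
    "is_bistable",
    "bistability_edges",
    "polar_transition_psi_edge",
]

#: guard band below zero for calling a growth rate "stable"
STABLE_TOL = -1e-8


@dataclass(frozen=True)
class WavePerturbation:
    """A plane-wave perturbation of magnitude ``|q| > 0`` along a principal
    direction ("parallel" or "perpendicular") of the gauge-fixed order."""

    q: float
    direction: str

    def __post_init__(self):
        if self.q <= 0:
            raise ValueError("|q| must be positive")
        if self.direction not in ("parallel", "perpendicular"):
            raise ValueError("direction must be 'parallel' or 'perpendicular'")

    @property
    def q_c(self) -> complex:
        return complex(self.q) if self.direction == "parallel" else 1j * self.q


@dataclass
class StabilityResult:
    """Maximal growth rates of a branch against uniform and wave
    perturbations along the two principal directions."""

    branch: UniformBranch
    smax_uniform: float
    smax_parallel: float
    smax_perpendicular: float
    argmax_q: dict


def default_q_grid(l_max: float = 200.0, q_max: float = 2.0, n: int = 64) -> np.ndarray:
    """Hybrid log+linear grid of wave numbers in ``[2 pi / l_max, q_max]``."""
    qmin = 2.0 * np.pi / l_max
    half = n // 2
    return np.unique(np.concatenate([
        np.geomspace(qmin, q_max, half),
        np.linspace(qmin, q_max, n - half),
    ]))


def spatial_jacobian(branch: UniformBranch, params: ModelParams, table: CollisionTable,
                     q: WavePerturbation | complex) -> np.ndarray:
    """Linearization matrix over perturbation modes ``-kc..kc`` at wave
    vector ``q`` (a ``WavePerturbation`` or a complex ``q_c = q_x + i q_y``)."""
    if branch.residual > 1e-8:
        raise ValueError("branch is not a converged fixed point")
    q_c = q.q_c if isinstance(q, WavePerturbation) else complex(q)
    kc = params.kc
    I = table.values
    km = table.kmax
    F = branch.state.full_modes()
    dim = 2 * kc + 1
    J = np.zeros((dim, dim), dtype=complex)
    ks = np.arange(-kc, kc + 1)
    lamk = params.lam_k(ks)
    for ki, k in enumerate(ks):
        J[ki, ki] -= lamk[ki]
        for mi, m in enumerate(ks):
            if abs(k - m) <= kc:
                J[ki, mi] += (I[m + km, k + km] + I[k - m + km, k + km]) * F[k - m + kc]
        if ki + 1 < dim:
            J[ki, ki + 1] += -(params.v0 / 2.0) * 1j * np.conj(q_c)
        if ki - 1 >= 0:
            J[ki, ki - 1] += -(params.v0 / 2.0) * 1j * q_c
    return J


def max_growth(branch: UniformBranch, params: ModelParams, table: CollisionTable,
               direction: str, q_grid: Optional[np.ndarray] = None):
    """Maximum over the q-grid of the largest eigenvalue real part."""
    if q_grid is None:
        q_grid = default_q_grid()
    if np.any(np.asarray(q_grid) <= 0):
        raise ValueError("q_grid must be positive")
    smax, qbest = -np.inf, None
    for q in q_grid:
        J = spatial_jacobian(branch, params, table, WavePerturbation(float(q), direction))
        s = float(np.max(np.linalg.eigvals(J).real))
        if s > smax:
            smax, qbest = s, float(q)
    return smax, qbest


def _gauge_vector(branch: UniformBranch, kc: int) -> Optional[np.ndarray]:
    """Real-form generator of the rotation symmetry, ``d/dphi f_k e^{ik phi}``."""
    F = branch.state.amplitudes
    v = 1j * np.arange(1, kc + 1) * F[1:]
    vec = np.concatenate([v.real, v.imag])
    n = np.linalg.norm(vec)
    return vec / n if n > 1e-12 else None


def uniform_max_growth(branch: UniformBranch, params: ModelParams,
                       table: CollisionTable) -> float:
    """Largest real eigenvalue of the mass-conserving uniform linearization.

    The density mode is excluded (mean density is conserved), and for an
    ordered branch the neutral rotation (Goldstone) mode is deflated by
    dropping the eigenvalue whose eigenvector has the largest overlap with
    the rotation generator.
    """
    kc = params.kc
    A, B = uniform_jacobian_blocks(branch.state.full_modes(), params, table, kc)
    J = real_jacobian(A, B)
    w, V = np.linalg.eig(J)
    g = _gauge_vector(branch, kc)
    if g is not None:
        overlaps = np.abs(g @ V) / np.linalg.norm(V, axis=0)
        i0 = int(np.argmax(overlaps))
        if abs(w[i0].real) < 1e-6:
            w = np.delete(w, i0)
    return float(np.max(w.real))


def stability_of(branch: UniformBranch, params: ModelParams, table: CollisionTable,
                 q_grid: Optional[np.ndarray] = None) -> StabilityResult:
    su = uniform_max_growth(branch, params, table)
    spar, qpar = max_growth(branch, params, table, "parallel", q_grid)
    sperp, qperp = max_growth(branch, params, table, "perpendicular", q_grid)
    branch.stable_uniform = su < STABLE_TOL
    dirs = set()
    if spar >= STABLE_TOL:
        dirs.add("parallel")
    if sperp >= STABLE_TOL:
        dirs.add("perpendicular")
    branch.unstable_directions = frozenset(dirs)
    return StabilityResult(branch, su, spar, sperp,
                           {"parallel": qpar, "perpendicular": qperp})


def polar_branch_continuation(psi: float, sigma: float, table: CollisionTable,
                              kc: int = 10, rho_start: Optional[float] = None,
                              rho_stop_factor: float = 0.5, n_steps: int = 30,
                              lam: float = 1.0):
    """Continue the uniform polar branch downward in density.

    Starts from a density where the polar state is the attractor (above
    ``rho_1c`` or above the nematic->polar threshold) and steps down,
    yielding ``(rho, branch, uniformly_stable)`` triples until the branch
    is lost or collapses to disorder.
    """
    pref = table.params.kernel_prefactor
    rho1c = critical_density(1, sigma, psi, table, lam)
    rho2c = critical_density(2, sigma, psi, table, lam)
    if rho_start is None:
        candidates = []
        if rho1c is not None:
            candidates.append(1.1 * rho1c)
        thr = nematic_polar_threshold(sigma, psi, table, kc=kc, rho_max=1.0, lam=lam)
        if thr is not None:
            candidates.append(1.1 * thr)
        if not candidates:
            return []
        rho_start = min(candidates)

    def params_at(rho):
        return ModelParams(rho_bar=rho, sigma=sigma, psi=psi, lam=lam, kc=kc,
                           sigma_c=table.params.sigma_c, kernel_prefactor=pref)

    p = params_at(rho_start)
    try:
        br = find_uniform_branch(p, table, seed="polar")
    except FixedPointError:
        return []
    if br.symmetry != "polar":
        return []
    floor = rho_stop_factor * min(x for x in (rho1c, rho2c, rho_start) if x is not None)
    out = []
    for rho in np.linspace(rho_start, floor, n_steps):
        p = params_at(rho)
        amp = br.state.amplitudes.copy()
        amp[0] = rho
        try:
            cand = find_uniform_branch(p, table, init=ModeState(amp))
        except FixedPointError:
            break
        if cand.symmetry != "polar":
            break
        su = uniform_max_growth(cand, p, table)
        out.append((float(rho), cand, su < STABLE_TOL))
        br = cand
    return out


def is_bistable(psi: float, sigma: float, table: CollisionTable, kc: int = 10,
                lam: float = 1.0) -> bool:
    """Whether stable disorder coexists with a uniformly-stable polar state.

    Bistability requires a density below ``min(rho_1c, rho_2c)`` (where the
    disordered state is linearly stable) at which the continued polar
    branch is still a fixed point, carries polar order, and is stable
    against spatially uniform perturbations.
    """
    rho1c = critical_density(1, sigma, psi, table, lam)
    rho2c = critical_density(2, sigma, psi, table, lam)
    caps = [x for x in (rho1c, rho2c) if x is not None]
    if not caps:
        return False
    rho_dis = min(caps)
    pts = polar_branch_continuation(psi, sigma, table, kc=kc, lam=lam)
    return any(rho < rho_dis and stable for rho, _, stable in pts)


def bistability_edges(sigma: float, kc: int = 10, lam: float = 1.0,
                      psi_lo: float = 0.05 * np.pi, psi_hi: float = 0.25 * np.pi,
                      n_scan: int = 16, xtol: float = 2e-4,
                      table_factory=None) -> Optional[tuple]:
    """The maximal polar-bias interval of kinetic bistability, by bisection.

    Returns ``(psi_lower, psi_upper)`` in radians, or None if no bistable
    bias was found in the scanned range.
    """
    if table_factory is None:
        def table_factory(psi):
            return table_for(ModelParams(rho_bar=0.2, sigma=sigma, psi=psi,
                                         lam=lam, kc=kc), kmax=kc)

    def flag(psi):
        return is_bistable(psi, sigma, table_factory(psi), kc=kc, lam=lam)

    psis = np.linspace(psi_lo, psi_hi, n_scan)
    flags = [flag(p) for p in psis]
    if not any(flags):
        return None
    idx = [i for i, f in enumerate(flags) if f]
    i0, i1 = idx[0], idx[-1]

    def bisect(pa, pb, fa):
        # invariant: flag(pa) == fa != flag(pb)
        while pb - pa > xtol:
            pm = 0.5 * (pa + pb)
            if flag(pm) == fa:
                pa = pm
            else:
                pb = pm
        return 0.5 * (pa + pb)

    lower = psis[i0] if i0 == 0 else bisect(psis[i0 - 1], psis[i0], False)
    upper = psis[i1] if i1 == len(psis) - 1 else bisect(psis[i1], psis[i1 + 1], True)
    return float(lower), float(upper)


def polar_transition_psi_edge(sigma: float, kc: int = 10, lam: float = 1.0,
                              rho_max: float = 2.0, psi_lo: float = 0.02 * np.pi,
                              psi_hi: float = 0.1 * np.pi, xtol: float = 2e-4,
                              table_factory=None) -> Optional[float]:
    """Smallest polar bias at which the nematic branch has a polar
    instability threshold within the scanned density range.

    The density scan extends to ``rho_max = 2.0`` by default, i.e. an order
    of magnitude above the nematic onset; the threshold density grows
    steeply as the bias decreases, so the reported edge refers to this
    range (see the methods note).
    """
    if table_factory is None:
        def table_factory(psi):
            return table_for(ModelParams(rho_bar=0.2, sigma=sigma, psi=psi,
                                         lam=lam, kc=kc), kmax=kc)

    def exists(psi):
        thr = nematic_polar_threshold(sigma, psi, table_factory(psi), kc=kc,
                                      rho_max=rho_max, n_scan=64, lam=lam)
        return thr is not None

    if not exists(psi_hi):
        return None
    if exists(psi_lo):
        return float(psi_lo)
    a, b = psi_lo, psi_hi
    while b - a > xtol:
        m = 0.5 * (a + b)
        if exists(m):
            b = m
        else:
            a = m
    return float(0.5 * (a + b))


@dataclass
class PhaseDiagram:
    """Regime labels on a (density, second-parameter) grid."""

    rho_grid: np.ndarray
    param_grid: np.ndarray
    param_name: str  # "psi" or "alpha2"
    labels: np.ndarray  # object array [i_param, j_rho]
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, pv in enumerate(self.param_grid):
            for j, rho in enumerate(self.rho_grid):
                rows.append({"rho_bar": rho, self.param_name: pv,
                             "label": self.labels[i, j]})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def save_h5(self, path) -> None:
        """Labeled 2D array in a self-describing HDF5 container."""
        import h5py

        labels = sorted({lab for lab in self.labels.ravel()})
        code = {lab: i for i, lab in enumerate(labels)}
        arr = np.vectorize(code.get)(self.labels).astype("i4")
        with h5py.File(path, "w") as f:
            d = f.create_dataset("labels", data=arr)
            d.attrs["label_names"] = [str(x) for x in labels]
            f.create_dataset("rho_grid", data=self.rho_grid)
            f.create_dataset(self.param_name + "_grid", data=self.param_grid)
            for k, v in self.meta.items():
                f.attrs[k] = str(v)


def classify_point(rho_bar: float, psi: float, sigma: float,
                   table: Optional[CollisionTable] = None, kc: int = 10,
                   lam: float = 1.0, q_grid: Optional[np.ndarray] = None,
                   check_bistable: bool = True) -> str:
    """Regime label of the kinetic theory at one ``(rho_bar, psi)`` point.

    Labels follow the mean-field phase diagram: "disordered",
    "nematic bands", "uniform nematic", "polar waves", "uniform polar",
    "bistable", or "unresolved" when no branch could be converged.
    """
    params = ModelParams(rho_bar=rho_bar, sigma=sigma, psi=psi, lam=lam, kc=kc)
    if table is None:
        table = table_for(params)
    rho1c = critical_density(1, sigma, psi, table, lam)
    rho2c = critical_density(2, sigma, psi, table, lam)
    caps = [x for x in (rho1c, rho2c) if x is not None]
    dis_stable = (not caps) or rho_bar < min(caps)

    if dis_stable:
        if check_bistable:
            pts = polar_branch_continuation(psi, sigma, table, kc=kc, lam=lam)
            for rho, _, stable in pts:
                if stable and abs(rho - rho_bar) < 1e-9:
                    return "bistable"
            if any(stable and rho <= rho_bar for rho, _, stable in pts):
                return "bistable"
        return "disordered"

    # ordered regime: try the nematic branch first, switch to polar if the
    # odd sector (or the flow itself) favours polar order
    nem = None
    if rho2c is not None and rho_bar > rho2c:
        try:
            nem = nematic_branch(params, table)
        except FixedPointError:
            nem = None
    if nem is not None and nem.symmetry == "nematic":
        if odd_sector_max_growth(nem, params, table) < STABLE_TOL:
            res = stability_of(nem, params, table, q_grid)
            if res.smax_perpendicular > abs(STABLE_TOL):
                return "nematic bands"
            return "uniform nematic"

    try:
        pol = find_uniform_branch(params, table, seed="polar")
    except FixedPointError:
        return "unresolved"
    if pol.symmetry == "polar":
        res = stability_of(pol, params, table, q_grid)
        if res.smax_parallel > abs(STABLE_TOL) or res.smax_perpendicular > abs(STABLE_TOL):
            return "polar waves"
        return "uniform polar"
    if pol.symmetry == "nematic":
        res = stability_of(pol, params, table, q_grid)
        if res.smax_perpendicular > abs(STABLE_TOL):
            return "nematic bands"
        return "uniform nematic"
    return "unresolved"


def phase_diagram(rho_grid, psi_grid, sigma: float, kc: int = 10, lam: float = 1.0,
                  q_grid: Optional[np.ndarray] = None,
                  check_bistable: bool = True) -> PhaseDiagram:
    """Kinetic (rho_bar, psi) phase diagram; the collision table is built
    once per psi column."""
    rho_grid = np.asarray(rho_grid, dtype=float)
    psi_grid = np.asarray(psi_grid, dtype=float)
    if np.any(np.diff(rho_grid) <= 0) or np.any(np.diff(psi_grid) < 0):
        raise ValueError("grids must be monotone")
    labels = np.empty((len(psi_grid), len(rho_grid)), dtype=object)
    for i, psi in enumerate(psi_grid):
        table = table_for(ModelParams(rho_bar=rho_grid[0] or 0.1, sigma=sigma,
                                      psi=psi, lam=lam, kc=kc), kmax=kc)
        # reuse the polar-branch continuation across the column
        pts = polar_branch_continuation(psi, sigma, table, kc=kc, lam=lam) \
            if check_bistable else []
        rho1c = critical_density(1, sigma, psi, table, lam)
        rho2c = critical_density(2, sigma, psi, table, lam)
        caps = [x for x in (rho1c, rho2c) if x is not None]
        for j, rho in enumerate(rho_grid):
            dis_stable = (not caps) or rho < min(caps)
            if dis_stable:
                if any(stable and r <= rho for r, _, stable in pts):
                    labels[i, j] = "bistable"
                else:
                    labels[i, j] = "disordered"
                continue
            try:
                labels[i, j] = classify_point(rho, psi, sigma, table=table, kc=kc,
                                              lam=lam, q_grid=q_grid,
                                              check_bistable=False)
            except FixedPointError:
                labels[i, j] = "unresolved"
    return PhaseDiagram(rho_grid, psi_grid, "psi", labels,
                        meta={"sigma": sigma, "kc": kc,
                              "bistable_note": "spinodal: rho_1c; flagged cells "
                              "are below it with a metastable polar attractor"})
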