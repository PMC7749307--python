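"""Binary collision rule with a tunable polar bias and its mode-space coefficients.

Self-propelled particles move at constant speed along an orientation
``theta`` and undergo binary aligning collisions.  Two particles whose
incoming angle difference ``|Delta|`` is below ``pi/2 + psi`` align in a
polar fashion (both adopt the average direction); otherwise they align
antipolar (average direction, but pointing in opposite ways).  The bias
angle ``psi in [0, pi/2]`` interpolates between purely nematic alignment
(``psi = 0``) and purely polar alignment (``psi = pi/2``).  Collisions carry
additive Gaussian angular noise of standard deviation ``sigma_c``.

Projecting the gain-minus-loss collision operator of the kinetic Boltzmann
equation onto angular Fourier modes ``f_k = \\int dtheta e^{i k theta} f``
turns it into a quadratic mode coupling ``sum_n I_{n,k} f_n f_{k-n}``.  This
module computes the coefficients ``I_{n,k}`` by deterministic quadrature of
the reduced one-dimensional integral

    I_{n,k} = (1/2pi) \\int_{-pi}^{pi} dDelta K(Delta) e^{-i n Delta}
              [ e^{-k^2 sigma_c^2 / 2} e^{i k h(Delta)} - 1 ],

where ``K`` is the collision kernel and ``h(Delta)`` the rotation
experienced by the first collision partner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
import math

import numpy as np

__all__ = [
    "CollisionRuleParams",
    "CollisionTable",
    "QuadratureSettings",
    "QuadratureError",
    "wrap_angle",
    "collision_outcome",
    "rotation_angle",
    "collision_kernel",
    "collision_coefficient",
    "build_collision_table",
    "default_kernel_prefactor",
]


class QuadratureError(RuntimeError):
    """Raised when the collision quadrature fails to reach its tolerance."""


def wrap_angle(theta):
    """Wrap an angle (or array of angles) into the interval ``(-pi, pi]``."""
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("wrap_angle requires finite input")
    wrapped = np.pi - np.mod(np.pi - theta, 2.0 * np.pi)
    if wrapped.ndim == 0:
        return float(wrapped)
    return wrapped


def rotation_angle(delta, psi: float):
    """Rotation ``h(Delta)`` applied to particle 1 in a collision.

    ``h = Delta/2`` on the polar branch (``|Delta| <= pi/2 + psi``) and
    ``(Delta - pi*sign(Delta))/2`` on the antipolar branch, with the
    convention ``sign(0) = sign(pi) = +1`` (a measure-zero tie-break).
    """
    delta = np.asarray(delta, dtype=float)
    sgn = np.where(delta >= 0.0, 1.0, -1.0)
    polar = np.abs(delta) <= np.pi / 2.0 + psi
    h = np.where(polar, delta / 2.0, (delta - np.pi * sgn) / 2.0)
    if h.ndim == 0:
        return float(h)
    return h


def collision_outcome(theta1: float, theta2: float, psi: float):
    """Post-collision orientations (pre-noise) of two colliding particles.

    Returns a pair of angles in ``(-pi, pi]``.  On the polar branch both
    particles leave along the average direction; on the antipolar branch
    they leave along opposite directions with the same average axis.
    """
    if not (0.0 <= psi <= np.pi / 2.0 + 1e-15):
        raise ValueError(f"psi must lie in [0, pi/2], got {psi}")
    delta = wrap_angle(theta2 - theta1)
    h = rotation_angle(delta, psi)
    out1 = wrap_angle(theta1 + h)
    if abs(delta) <= np.pi / 2.0 + psi:
        out2 = out1
    else:
        out2 = wrap_angle(out1 + np.pi)
    return out1, out2


def collision_kernel(delta, prefactor: float = 1.0):
    """Collision rate kernel ``prefactor * |sin(Delta/2)|``.

    The dilute-limit kernel for spherical particles is proportional to the
    relative speed of the pair, ``2 v0 |sin(Delta/2)|``; the overall scale is
    absorbed into ``prefactor`` (and with it the absolute density scale of
    the phase diagram).
    """
    return prefactor * np.abs(np.sin(np.asarray(delta, dtype=float) / 2.0))


@dataclass(frozen=True)
class CollisionRuleParams:
    """Parameters of the biased binary collision rule.

    Attributes
    ----------
    psi:
        Polar bias angle in ``[0, pi/2]``.
    sigma_c:
        Standard deviation of the Gaussian collision noise (``sigma'``);
        conventionally set equal to the angular diffusion noise ``sigma``.
    kernel_prefactor:
        Positive scale of the collision kernel (dimensionless after the
        rescaling ``v0 = lambda = d = 1``).
    """

    psi: float
    sigma_c: float
    kernel_prefactor: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.psi <= np.pi / 2.0 + 1e-15):
            raise ValueError(f"psi must lie in [0, pi/2], got {self.psi}")
        if self.sigma_c < 0.0:
            raise ValueError("sigma_c must be non-negative")
        if self.kernel_prefactor <= 0.0:
            raise ValueError("kernel_prefactor must be positive")


@dataclass(frozen=True)
class QuadratureSettings:
    """Gauss-Legendre settings for the reduced collision integral.

    The integrand is analytic except at the branch points
    ``Delta = +-(pi/2 + psi)`` (polar/antipolar switch) and at ``Delta = 0``
    (kink of ``|sin(Delta/2)|``), so the integral is split there and each
    smooth segment integrated with a fixed-order rule.  Convergence is
    checked by doubling the order.
    """

    order: int = 128
    tol: float = 1e-10
    check: bool = True


def _segments(psi: float):
    thr = np.pi / 2.0 + psi
    pts = [-np.pi, -thr, 0.0, thr, np.pi]
    return [(a, b) for a, b in zip(pts[:-1], pts[1:]) if b - a > 1e-14]


def _quad_nodes(psi: float, order: int):
    """Gauss-Legendre nodes/weights over (-pi, pi], split at branch points."""
    x, w = np.polynomial.legendre.leggauss(order)
    nodes, weights = [], []
    for a, b in _segments(psi):
        mid, half = 0.5 * (a + b), 0.5 * (b - a)
        nodes.append(mid + half * x)
        weights.append(half * w)
    return np.concatenate(nodes), np.concatenate(weights)


def _table_values(kmax: int, params: CollisionRuleParams, order: int) -> np.ndarray:
    """Raw table ``I[n+kmax, k+kmax]`` at a given quadrature order."""
    nodes, weights = _quad_nodes(params.psi, order)
    kern = collision_kernel(nodes, params.kernel_prefactor)
    h = rotation_angle(nodes, params.psi)
    ns = np.arange(-kmax, kmax + 1)
    ks = np.arange(-kmax, kmax + 1)
    # bracket[k, j] = exp(-k^2 sc^2/2) exp(i k h_j) - 1
    damp = np.exp(-0.5 * ks[:, None] ** 2 * params.sigma_c**2)
    bracket = damp * np.exp(1j * ks[:, None] * h[None, :]) - 1.0
    phase = np.exp(-1j * ns[:, None] * nodes[None, :])  # [n, j]
    wk = weights * kern
    return (phase * wk[None, :]) @ bracket.T / (2.0 * np.pi)  # [n, k]


def collision_coefficient(
    n: int,
    k: int,
    params: CollisionRuleParams,
    quadrature: QuadratureSettings = QuadratureSettings(),
) -> complex:
    """Mode-coupling coefficient ``I_{n,k}`` of the collision operator."""
    vals = _table_values(max(abs(n), abs(k), 1), params, quadrature.order)
    kmax = max(abs(n), abs(k), 1)
    val = vals[n + kmax, k + kmax]
    if quadrature.check:
        vals2 = _table_values(kmax, params, 2 * quadrature.order)
        err = abs(vals2[n + kmax, k + kmax] - val)
        if err > quadrature.tol:
            raise QuadratureError(
                f"collision quadrature error {err:.2e} above tolerance for (n={n}, k={k})"
            )
        val = vals2[n + kmax, k + kmax]
    return complex(val)


@dataclass(frozen=True)
class CollisionTable:
    """Table of collision coefficients ``I_{n,k}`` for ``|n|, |k| <= kmax``.

    ``values`` is indexed ``[n + kmax, k + kmax]``.  The table satisfies
    ``I_{n,0} = 0`` (mass conservation) and ``I_{-n,-k} = conj(I_{n,k})``
    (reality of the angular distribution).
    """

    kmax: int
    values: np.ndarray
    params: CollisionRuleParams

    def value(self, n: int, k: int) -> complex:
        if abs(n) > self.kmax or abs(k) > self.kmax:
            raise KeyError(f"(n={n}, k={k}) outside table of kmax={self.kmax}")
        return complex(self.values[n + self.kmax, k + self.kmax])

    def pair_sum(self, n: int, k: int) -> complex:
        """Symmetrized coupling ``I_{n,k} + I_{k-n,k}`` (the physical object)."""
        return self.value(n, k) + self.value(k - n, k)

    def save(self, path) -> None:
        """Write the table to an HDF5 container with parameter metadata."""
        import h5py

        with h5py.File(path, "w") as f:
            dset = f.create_dataset("I", data=self.values)
            dset.attrs["kmax"] = self.kmax
            dset.attrs["psi"] = self.params.psi
            dset.attrs["sigma_c"] = self.params.sigma_c
            dset.attrs["kernel_prefactor"] = self.params.kernel_prefactor

    @classmethod
    def load(cls, path) -> "CollisionTable":
        import h5py

        with h5py.File(path, "r") as f:
            dset = f["I"]
            params = CollisionRuleParams(
                psi=float(dset.attrs["psi"]),
                sigma_c=float(dset.attrs["sigma_c"]),
                kernel_prefactor=float(dset.attrs["kernel_prefactor"]),
            )
            return cls(kmax=int(dset.attrs["kmax"]), values=dset[...], params=params)


def build_collision_table(
    kmax: int,
    params: CollisionRuleParams,
    quadrature: QuadratureSettings = QuadratureSettings(),
) -> CollisionTable:
    """Compute all ``I_{n,k}`` with ``|n|, |k| <= kmax`` by quadrature."""
    if kmax < 2:
        raise ValueError("kmax must be at least 2")
    vals = _table_values(kmax, params, quadrature.order)
    if quadrature.check:
        vals2 = _table_values(kmax, params, 2 * quadrature.order)
        err = np.max(np.abs(vals2 - vals))
        if err > quadrature.tol:
            raise QuadratureError(f"collision table quadrature error {err:.2e}")
        vals = vals2
    return CollisionTable(kmax=kmax, values=vals, params=params)


@lru_cache(maxsize=None)
def default_kernel_prefactor(sigma: float = 0.2, rho_ref: float = 0.16, lam: float = 1.0) -> float:
    """Kernel prefactor anchoring the density scale of the model.

    Chosen such that the purely nematic model (``psi = 0``) at noise
    ``sigma`` has its nematic transition density at ``rho_ref``:
    ``rho_2c = lam (1 - e^{-2 sigma^2}) / Re(I_{0,2} + I_{2,2}) = rho_ref``.
    All bias thresholds are invariant under this global density rescaling.
    """
    base = CollisionRuleParams(psi=0.0, sigma_c=sigma, kernel_prefactor=1.0)
    vals = _table_values(2, base, 256)
    s = float(np.real(vals[0 + 2, 2 + 2] + vals[2 + 2, 2 + 2]))  # I_{0,2} + I_{2,2}
    if s <= 0.0:
        raise RuntimeError("nematic coupling non-positive; cannot calibrate kernel")
    return lam * (1.0 - math.exp(-2.0 * sigma**2)) / (rho_ref * s)
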