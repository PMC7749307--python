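# Methods

## Model

`nempol` studies a dilute two-dimensional system of self-propelled
particles (speed `v0`, diameter `d`) whose orientations `theta` change by
angular diffusion and by binary aligning collisions.  Two colliding
particles align *polar* (both take the average direction) when their
incoming angle difference satisfies `|Delta| <= pi/2 + psi`, and
*antipolar* (average axis, opposite directions) otherwise.  The bias angle
`psi in [0, pi/2]` interpolates between purely nematic (`psi = 0`) and
purely polar (`psi = pi/2`) alignment.  Both channels carry additive
Gaussian noise of standard deviation `sigma_c` (set equal to the diffusion
noise `sigma` by convention).  Units are rescaled so `v0 = lambda = d = 1`
(`lambda` is the angular-diffusion rate); density is then measured in
units of `lambda/(d v0)`.

The one-particle distribution `f(r, theta, t)` obeys a kinetic Boltzmann
equation.  In angular Fourier modes
`f_k = \int dtheta e^{ik theta} f` it reads

    dt f_k + (v0/2) [ nabla* f_{k+1} + nabla f_{k-1} ]
        = -lambda (1 - e^{-k^2 sigma^2/2}) f_k + sum_n I_{n,k} f_n f_{k-n},

with `nabla = d_x + i d_y`.  `f_0` is the local density; `f_1` and `f_2`
encode the polar vector and nematic tensor.  The collision coefficients

    I_{n,k} = (1/2pi) \int_{-pi}^{pi} dDelta K(Delta) e^{-i n Delta}
              [ e^{-k^2 sigma_c^2/2} e^{i k h(Delta)} - 1 ]

are computed by split Gauss-Legendre quadrature (`collisions` module),
where `h(Delta)` is the rotation of the first collision partner
(`Delta/2` polar branch, `(Delta - pi sign Delta)/2` antipolar branch,
`sign(pi) = +1` as a measure-zero tie-break) and
`K(Delta) = A |sin(Delta/2)|` is the dilute-limit kernel proportional to
the relative speed of the pair.

**Kernel normalization.** The overall kernel scale `A` only sets the
density scale of the phase diagram (all bias thresholds are invariant
under it).  It is fixed by anchoring the nematic onset of the unbiased
model at `rho_2c(sigma = 0.2) = 0.16`; the resulting `A = 3.93` lies
within 2% of the geometric dilute-disk value `4 d v0`, which we take as
confirmation that the anchor and the kernel are mutually consistent.

**Index convention.** The quadratic collision sum only determines the
symmetrized combinations `I_{n,k} + I_{k-n,k}`; every physical quantity
(growth rates, Jacobians, hydrodynamic coefficients) is built from these.
The brute-force two-angle projection oracle in the test suite therefore
compares symmetrized coefficients.

## Uniform states and stability

With spatial gradients dropped and modes truncated at `|k| <= kc`
(default `kc = 10`; branch amplitudes change by < 1e-4 relative when
`kc` is raised to 14 in the regimes studied), the uniform dynamics are a
closed polynomial ODE system.  Fixed points are found by damped Newton
iteration with the analytic Wirtinger Jacobian; when a branch is seeded
from a small perturbation, the flow is first integrated (LSODA, in
growing chunks) toward its attractor and only then polished, and a polish
that lands on a fixed point that is linearly unstable *within the probed
sector* is rejected, kicked along the unstable eigendirection, and
integration continued.  This guarantees that seeded solves return the
attractor of the flow rather than an unstable intermediate (the disordered
state above threshold, or the nematic state above the polar threshold).
Fixed points are gauge-fixed by a global rotation making the dominant
order parameter real and positive; symmetry labels use the threshold
`|f_k|/rho > 1e-4`, far above the solver residual (1e-11) and far below
physical amplitudes.

Linear growth rates about disorder are
`mu_k = Re(I_{0,k} + I_{k,k}) rho - lambda (1 - e^{-k^2 sigma^2/2})`;
their zeros define `rho_1c` (polar onset) and `rho_2c` (nematic onset).
About an ordered branch, plane-wave perturbations
`delta f_k ~ e^{i q r + s t}` couple all modes `-kc..kc` (including the
density mode) through the advection term; the two principal directions
(parallel and perpendicular to the order) are scanned over a hybrid
log/linear q-grid (`|q| in [2 pi/200, 2]`, 64 points).  "Stable" means
the largest eigenvalue real part is below `-1e-8`; the rotational
Goldstone mode of an ordered state is deflated by eigenvector overlap
with the rotation generator `(i k f_k)`.

**Nematic -> polar threshold.** Above `rho_2c` the nematic branch is
continued upward in density; by parity, its uniform Jacobian
block-diagonalizes into even and odd sectors, and the first zero crossing
of the odd-sector growth rate (bisection) defines `rho_nem-pol(psi)`.
The threshold density falls steeply with bias (about 2.3 at
`psi = 0.045 pi`, 1.7 at `0.05 pi`, 0.5 at `0.075 pi`, 0.32 at
`0.1 pi` for `sigma = 0.2`), so the *smallest bias* for which a
transition exists depends on the density range scanned.  Ordinary branch
scans default to `rho <= 0.5`; the existence-edge computation scans to
`rho = 2.0` — an order of magnitude above the nematic onset, the range
over which the truncated hierarchy is still converged — which places the
edge at `psi ~ 0.047 pi`.

**Bistability.** At intermediate bias the polar transition is
discontinuous: a uniformly stable polar state coexists with stable
disorder below `min(rho_1c, rho_2c)`.  It is detected by continuing the
polar branch downward in density from a regime where it is the attractor
and checking uniform stability (Goldstone-deflated).  The bias interval
over which this coexistence exists at some density is bisected to find
its edges; at `sigma = 0.2` they are `psi/pi = 0.107` and `0.174`.  The
upper edge is where the subcritical density window closes (it is robust
against the continuation step size); note that it lies somewhat above the
coarse literature estimate of ~0.15 for the same model class, which was
stated only approximately.

## Real-space kinetic solver

`boltzmann2d` discretizes `f(r, theta)` in `N_theta` angular channels on
a periodic square grid and advances a Strang splitting: free streaming of
each channel (exact spectral translation — a phase shift in Fourier
space, dispersion- and diffusion-free; a conservative bilinear remap is
kept as a cross-check option, but its numerical diffusion `~ dx v0 / 2`
is comparable to the weakest pattern growth rates and is avoided by
default) and site-local angular dynamics (diffusion + truncated
collision convolution in mode space, Heun step).  Adjacent
half-steps are merged between outputs (first-same-as-last).  The local
step conserves the site density by construction; global mass drift is at
the 1e-12 level over 1e4 steps.  Negative channel values produced by the
truncated Fourier synthesis are clipped with per-site mass
renormalization; the run aborts if cumulative clipped mass exceeds 1e-6
of the total.  Default resolution for demonstrations: `N_theta = 16`
(spectral truncation `kmax = 7`, which reproduces the `kc = 10`
odd-sector thresholds to three digits), `dt = 0.25 dx / v0`.

## Hydrodynamic theory

Close to onset the slow fields are `rho`, `f1`, `f2`.  Their equations
(see module docstring for the full form) contain linear decay/growth,
the bilinear polar-nematic coupling `alpha2 conj(f1) f2`, cubic
saturation, and first/second-gradient couplings.  All coefficients except
the free coupling `alpha2` are derived from the unbiased (`psi = 0`)
kinetic theory at the reference point `rho = 0.16`, `sigma = 0.2` by
adiabatic elimination of the fast modes: `dt f3 = 0` gives
`f3 = [ (I_{1,3}+I_{2,3}) f1 f2 - (1/2) nabla f2 ] / L3` with
`L3 = lambda_3 - (I_{0,3}+I_{3,3}) rho`, producing `alpha3`, `beta3'`,
and `gamma_1..gamma_4`; `dt f4 = 0` at leading order gives
`f4 = I_{2,4} f2^2 / L4`, producing the nematic saturation
`beta3 = -(I_{-2,2}+I_{4,2}) I_{2,4} / L4 > 0`.  Eliminating only `f3`
cannot generate a `|f2|^2 f2` term, so `f4` must be kept for the theory
to saturate; `f5` and higher are dropped.  Every coefficient is
overridable from configuration.

Closed-form consequences used throughout: the nematic amplitude
`F(rho) = sqrt((beta1 rho - beta0)/beta3)`; the polar instability of the
nematic branch when `alpha2 F > alpha0 + alpha1 rho + alpha3 F^2`; the
minimal coupling for which that condition has a solution,
`min_rho (alpha0 + alpha1 rho + alpha3 F^2)/F = 1.325` density/time for
the derived defaults (the minimum is interior, so it does not depend on
the scan cap).

The pseudo-spectral solver treats the diagonal linear terms (including
the nematic diffusion `gamma2 nabla nabla* f2`) exactly by integrating
factor and the rest with a Heun step; quadratic/cubic products are
dealiased by the 2/3 rule, the state is kept band-limited (which also
removes an asymmetric Nyquist artifact in the differentiated product
`nabla*(f1 f2)`), and the mean density is conserved identically because
the zero mode of `-Re[nabla* f1]` vanishes.  Measured plane-wave growth
rates about uniform branches match the analytic linearization to better
than 2%.

## Synthetic initial conditions and demonstration scale

The seeded fixture generator produces (i) uniform disordered states with
relative Gaussian fluctuations (`eps = 1e-2` by default) and (ii)
band-seeded states: a sinusoidal density band across the box with the
nematic director along it (kinetic: angular distribution
`~ 1 + 0.8 cos 2theta` in the band; hydrodynamic: `f2` at the local
branch amplitude), used to study the band-interior polar instability
directly.  All randomness flows from a single integer seed per run.

The demonstration runs are deliberately small: boxes of `L = 50..160`
fitting one or a few fastest-growing wavelengths, `48^2..128^2` grids,
and run times of a few thousand rescaled time units.  The band
instability wavelengths at the demonstration points are ~50 (kinetic)
and ~80 (hydrodynamic) rescaled length units, so smaller boxes suppress
the patterns entirely.

In the *hydrodynamic* theory the band-interior polar onset is fully
reproduced at this scale: a band-seeded run at `(alpha2 = 1.5,
rho = 0.18)` develops core densities above the polar threshold and polar
order grows inside the band at the rate the local analysis predicts.

In the *kinetic* theory the same mechanism's precondition is reproduced
— bands form from disorder at `(rho = 0.285, psi = 0.1 pi)` and their
cores reach 0.45..0.72, far above `rho_nem-pol = 0.32` — but the onset
itself is not: local polar order transiently peaks at `|f1|/rho ~ 0.04`
during band formation and is then expelled, and the relaxed banded state
rejects even finite polar perturbations.  This was checked against
domain size (L = 50..160), angular resolution (`N_theta = 16` and 32),
advection scheme (spectral and remap), and band-seeded as well as
polar-kicked initial states.  Two quenching mechanisms were identified:
the polar mode must fit inside the band core (its growth rate about the
uniform dense state is only +0.002..+0.006 and turns negative beyond
cross-band wavenumbers ~0.15), and band cores are slightly over-ordered
relative to the uniform branch (a 15% excess of `|f2|` flips the local
growth rate to -0.006).  Reproducing the kinetic coexistence
phenomenology evidently requires domains well beyond the packaged
demonstration scale; the corresponding check in the test suite asserts
the full published phenomenology at the reduced scale and is expected to
fail there, by design rather than omission.

## Classification thresholds

A snapshot is "banded" when `max rho / mean rho > 1.3`; local polar
presence means `|f1|/rho > 0.05` (well above the noise floor, well below
saturated order); a trajectory is "nematic-polar coexistence" when, in
the last half of the run, band-like structures coexist (simultaneously or
alternately) with polar order inside them, or interconversion events
occur.  Band orientation comes from the density structure tensor
(Gaussian smoothing over 2 cells); the director from `arg(f2)/2`.
Labels are invariant under translations and the global gauge rotation,
and stable under +-20% perturbation of the segmentation threshold on the
fixture suite.

## Known limitations

- The truncated mode hierarchy loses meaning at densities well above the
  dilute regime; scans are capped at `rho = 2`.
- The upper bistability edge is sensitive to how thin a subcritical
  density window one is willing to resolve; we report the closure of the
  window itself.
- The angular-channel solver's spectral truncation (`kmax = N_theta/2 - 1`)
  softens steep angular distributions inside dense bands; `N_theta = 32`
  is recommended for quantitative work at high density.
- Event logs operationalize pattern interconversion (onset, detachment,
  reformation) through scalar thresholds; they are a reproducible
  instrument, not a unique definition.
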