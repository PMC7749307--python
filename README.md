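# nempol

Kinetic and hydrodynamic theory of self-propelled particles whose binary
collisions align nematically with a tunable polar bias — the setting in
which high-density *patterns* (nematic bands, polar traveling waves) can
locally cross symmetry-breaking thresholds and interconvert.

## Who this is for

Active-matter theorists and modelers of cytoskeletal motility assays who
want to compute, from a single collision rule, the mean-field phase
diagram (disorder / nematic / polar / bistable), the linear stability of
uniform states against plane waves (band and wave formation), full
real-space solutions of the kinetic Boltzmann equation, and the companion
polar-nematic hydrodynamic field theory — plus diagnostics that classify
the resulting spatiotemporal patterns.

## The model in brief

Particles move at constant speed `v0` and collide pairwise: incoming
angle differences below `pi/2 + psi` align polar, larger ones antipolar
(`psi = 0`: purely nematic rule; `psi = pi/2`: purely polar).  In angular
Fourier modes `f_k(r, t)` the kinetic equation reads

    dt f_k + (v0/2)[nabla* f_{k+1} + nabla f_{k-1}]
        = -lambda (1 - e^{-k^2 sigma^2/2}) f_k + sum_n I_{n,k} f_n f_{k-n},

with collision coefficients `I_{n,k}` computed by quadrature from the
rule above.  Linear growth rates
`mu_k = Re(I_{0,k} + I_{k,k}) rho - lambda(1 - e^{-k^2 sigma^2/2})`
define the onset densities `rho_1c` (polar) and `rho_2c` (nematic); a
truncated mode system (`|k| <= kc = 10`) yields the ordered branches, the
density `rho_nem-pol(psi)` at which nematic order destabilizes toward
polar order, and a bistable bias window where stable disorder coexists
with a metastable polar state.  The hydrodynamic theory evolves
`(rho, f1, f2)` with a bilinear coupling `alpha2 conj(f1) f2` as the key
free parameter; all other coefficients derive from the `psi = 0` kinetic
theory.  See `docs/methods.md` for the full equations and numerical
choices.

## Worked example

```python
import numpy as np
from nempol.mode_system import (ModelParams, table_for, critical_density,
                                nematic_polar_threshold)

sigma, psi = 0.2, 0.1 * np.pi
table = table_for(ModelParams(rho_bar=0.2, sigma=sigma, psi=psi))
print("rho_2c      =", critical_density(2, sigma, psi, table))
print("rho_nem-pol =", nematic_polar_threshold(sigma, psi, table, rho_max=1.0))
```

prints

```
rho_2c      = 0.2522215325443737
rho_nem-pol = 0.32056514724227075
```

i.e. at bias `psi = 0.1 pi` and noise `sigma = 0.2`, disorder gives way
to nematic order at density 0.252, and the uniform nematic state itself
becomes polar-unstable at density 0.321.  A kinetic simulation at mean
density 0.285 — between the two — forms nematic bands whose cores exceed
0.321 and locally break symmetry toward polar order.  The same
computation from the shell:

```sh
nempol thresholds --sigma 0.2 --psi-over-pi 0.1
```

```json
{
  "rho_1c": null,
  "rho_2c": 0.2522215325443737,
  "rho_nem_pol": 0.32056514724227075
}
```

Simulations and pattern classification run through the workflow layer,
e.g.

```python
from nempol.workflows import RunConfig, workflow_coexistence_demo
report = workflow_coexistence_demo(RunConfig(
    workflow="coexistence-hydro", rho_bar=0.18, alpha2=1.5,
    L=100.0, N=80, dt=0.2, t_end=4000.0, seed=21,
    band_seed=True, noise_eps=0.0056))
print(report["label"])
```

prints `nematic-polar coexistence` (a few minutes on one core): the
seeded nematic band's core density exceeds the polar threshold 0.201 and
polar order builds up inside the band.

or via the CLI subcommands `nempol phase-diagram | simulate-kinetic |
simulate-hydro | classify`.

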