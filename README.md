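# mechanoscale

Steady-state solver and analysis toolkit for *mechanogen* gradients —
diffusing molecules that induce cytoskeletal contractility in an assembly of
adherent cells — where long-range elastic interactions between contractile
cells feed back on the molecule's degradation and make the gradient's decay
length scale with the size of the system.

## Who this is for

Physicists and quantitative biologists studying mechanochemical feedback in
cell cultures or developing tissue: how a locally injected, contractility-
inducing signal can form a concentration profile whose range is set not by
molecular kinetics but by the system size, in the spirit of morphogen-
gradient scaling.

## The model

Cells are isotropic contractile force dipoles with dimensionless
contractility `psi = min(phi, 1)`, where `phi = chi c` is the dimensionless
mechanogen concentration. In a finite elastic medium, dipole–dipole
interactions act through the boundary and are separation independent,
`V(x, x') = V0 / L^d` — positive for free (zero-stress) and negative for
clamped (zero-displacement) boundaries (zero for a free 1D chain). When
mechanogen degradation is promoted by the local strain, eliminating the
strain gives a closed steady-state equation for `phi(r)` (lengths in units
of the molecular scale `lambda0 = sqrt(D/k_deg)`, source radius `a =
lambda0`):

```
phi'' + (d-1)/r phi' = phi^2 / lambda0^2  +  s * phi / lambda^2,   s = +1 free / -1 clamped
1 / lambda^2 = |V0| * phibar / lambda0^2              (self-consistency)
```

with a source flux `-dphi/dr|_(r=a) = j = 1/r0` and `phibar` the volume
average of the profile. Because `phibar` depends on the solution, the decay
length `lambda(R)` must be found self-consistently; the package does this by
inward shooting from the outer boundary wrapped in an accelerated fixed-point
iteration. Matched asymptotics (inner `a^2/(r r0)`, intermediate
`2 a^2/r^2`, outer `A a^2 e^(-r/lambda)/r` with `A ~ 1/lambda`) yield the
scaling laws `lambda ~ L^(1/2)` (1D), `~ R` up to log corrections (2D) and
`~ R` (3D) at large flux, and `lambda ~ R^(d/4)` in the linearized
small-flux regime.

## Worked example

```python
from mechanoscale import ModelParams, calibrate_V0, self_consistent_solve

base = ModelParams.with_source_scale(
    50.0, dimension=3, boundary="free", system_size=20000.0, interaction_mag=1.0
)
v0 = calibrate_V0(20000.0, 1000.0, base)   # anchor: lambda(20000a) = 1000a
for R in (5000.0, 10000.0, 20000.0):
    sol = self_consistent_solve(
        base.replace(system_size=R, interaction_mag=v0),
        lambda_init=1000.0 * R / 20000.0,
    )
    print(f"R = {R:7.0f}a   lambda* = {sol.lambda_star:7.1f}a   "
          f"mean phi = {sol.mean_phi:.3e}   iters = {sol.iterations}")
```

prints

```
R =    5000a   lambda* =   285.9a   mean phi = 1.280e-08   iters = 4
R =   10000a   lambda* =   530.5a   mean phi = 3.718e-09   iters = 4
R =   20000a   lambda* =  1000.0a   mean phi = 1.046e-09   iters = 1
```

The decay length grows nearly in proportion to the system radius
(`285.9 : 530.5 : 1000` against sizes `1 : 2 : 4`): the gradient *scales*.
The deviation from exact proportionality is the finite-size crossover
between the nonlinear and linear regions of the profile.

The same computation is available from the shell:

```
mechanoscale fig2 --out results/        # three profiles + collapse CSVs + summary JSON
mechanoscale sweep --dimension 1 --boundary clamped \
    --size 2000 --size 8000 --size 32000 --flux 0.2 --calibrate 32000:300
mechanoscale case-i --dimension 3 --size 100 --size 200 --size 400
```

## Layout

- `mechanoscale.model` — dimensionless problem types, ODE right-hand sides,
  weak-coupling (purely biochemical degradation) closed forms.
- `mechanoscale.elastic` — discrete spring-chain dipole interactions and the
  spherically symmetric continuum strain trace.
- `mechanoscale.solver` — inward shooting, self-consistency fixed point,
  interaction-strength calibration, independent collocation oracle.
- `mechanoscale.asymptotics` — matched piecewise solutions, prefactor
  matching, scaling-exponent fits, collapse transform.
- `mechanoscale.exact1d` — the exact 1D clamped solution and its
  symbolic-residual gate.
- `mechanoscale.experiments` / `mechanoscale.cli` — reproducible drivers and
  the command-line interface.

See `docs/methods.md` for the numerical methods and their assumptions.
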