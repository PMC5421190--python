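# spherenf

Pattern formation in a delayed neural field on the sphere.

`spherenf` implements linear and weakly nonlinear analysis, symmetry
classification, and direct numerical simulation for the neural field model

```
∂u/∂t (t, r) = −u(t, r) + ∫_{S²} w(r·r′) f( u(t − τ(r·r′), r′) ) dr′
```

posed on the unit sphere, with

- a firing-rate nonlinearity `f(u) = α / (1 + exp(−β (u − δ)))`,
- a difference-of-exponentials ("wizard hat") connectivity kernel
  `w(s) = J₁ exp(−θ/σ₁) + J₂ exp(−θ/σ₂)` where `θ = arccos s` is the great-circle
  distance, and
- a space-dependent transmission delay `τ(s) = τ₀ + θ/c` combining a fixed
  synaptic delay with a finite propagation speed.

Because the kernel and the delay depend only on the great-circle distance, the
model is equivariant under the full orthogonal group O(3). That single fact
organizes everything in this package: eigenmodes of the linearization are
spherical harmonics of fixed degree `n` (each eigenvalue has multiplicity
`2n + 1`), bifurcating branches are classified by their isotropy subgroups, and
the emergent patterns seen in simulation are the standing and travelling
planforms predicted by that classification.

## What the package computes

**Linear stability (`model_core`, `harmonics`, `spectral`).** Homogeneous
steady states `û = w₀ f(û)`, their linearization, and the characteristic
equation per harmonic degree,

```
E_n(λ) = λ + 1 − κ G_n(λ) = 0,      G_n(λ) = 2π ∫_{−1}^{1} w(s) e^{−λ τ(s)} P_n(s) ds,
```

with `κ = f′(û)`. `G_n` is a Funk–Hecke transform evaluated by Gauss–Legendre
quadrature in the polar angle; roots of the transcendental equation `E_n = 0`
are found by Newton iteration from a grid of seeds and certified by
argument-principle contour counts.

**Bifurcation analysis (`bifurcation`).** Fold lines and Hopf curves in the
plane of lumped gains `(κJ₁, κJ₂)`, stability maps, the first Lyapunov
coefficient `l₁` of the degree-0 Hopf bifurcation (detecting the
generalized-Hopf point where it changes sign), and a codimension-two
double-Hopf solver that locates simultaneous degree-0/degree-1 criticality
under the balanced-kernel convention `w₀ = 0`, returning residual certificates.

**Weakly nonlinear dynamics (`amplitude`).** The normal form of the
double-Hopf interaction between the homogeneous oscillation and the degree-1
modes, its reduction to a three-dimensional real amplitude system, closed-form
enumeration of all first-octant equilibria (at most six), their stability and
isotropy classification, and numerical integration of both systems.

**Planforms (`planforms`).** The catalog of maximal isotropy branches for
critical degrees 1–6 (10 branches at degree 4: 6 standing, 4 travelling),
explicit fixed-subspace vectors at degree 4, synthesis of the corresponding
real fields, and numerical verification of each branch's spatiotemporal
symmetries.

**Simulation (`mesh`, `simulator`).** Direct integration of the delayed field
equation on a geodesic icosphere with per-edge discrete delays, Heun time
stepping, a ring buffer of firing-rate history, degree-power diagnostics, and
a standing-vs-travelling wave discriminator for the dominant degree.

## Worked example

Reproduce the degree-4 Turing–Hopf instability and watch the predicted pattern
emerge in simulation:

```python
import numpy as np
from spherenf import (
    DelayParams, FiringParams, LinearizationContext, ModelParams,
    SimConfig, calibrate_couplings, compute_spectrum, simulate,
    standing_wave_ratio,
)

# sharp wizard-hat kernel, lumped gains just beyond the degree-4 instability
sigmas = (2/9, 1/6)
delay = DelayParams(tau0=3.0, c=0.8)
ctx = LinearizationContext.from_lumped_gains(29.50, -51.38, sigmas, delay, n_max=5)
spec = compute_spectrum(ctx).to_frame()
print(spec[spec.re > 0])          # one pair, degree 4, lambda ~ 0.0102 + 0.755i

# raw parameters realizing those gains with a steep sigmoid
firing = FiringParams(alpha=1.0, beta=8.0, delta=0.0)
conn, eq = calibrate_couplings(29.50, -51.38, firing, sigmas, delay,
                               select="leading")
params = ModelParams(firing, conn, delay)

# direct simulation from a small random perturbation of the steady state
cfg = SimConfig(dt=0.05, t_final=450.0, mesh_level=3,
                initial=("random", 1e-3), seed=1, save_every=20)
traj = simulate(cfg, params)
post = traj.diagnostics[traj.diagnostics.time >= 250.0]
powers = post[[c for c in post.columns if c.startswith("power_")]].mean()
print(powers.idxmax())            # power_4: the pattern lives on degree 4
```

The same analyses are available from the command line:

```bash
spherenf spectrum    --config config.json --out out/   # eigenvalue scatter
spherenf hopf-curves --config config.json --out out/   # gain-plane curves
spherenf normal-form --config config.json --out out/   # generalized Hopf
spherenf codim2      --config config.json --out out/   # double-Hopf point
spherenf amplitude   --config config.json --out out/   # amplitude equilibria
spherenf planform    --config config.json --out out/   # planform gallery
spherenf simulate    --config config.json --out out/   # direct simulation
```

Each command reads a JSON config (flags override individual entries; unknown
keys are rejected) and writes CSV/JSON/PLY artifacts plus a `manifest.json`
recording the resolved configuration, so identical configs reproduce
identical outputs. Ready-to-run configs for every command live in
`examples/` — for instance:

```bash
spherenf spectrum --config examples/spectrum_degree4.json --out out/
```

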