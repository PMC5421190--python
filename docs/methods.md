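# Numerical methods and conventions

This note records the numerical choices behind `spherenf`, in the order the
analyses build on one another.

## Model and notation

The field `u(t, r)` on the unit sphere obeys

```
∂u/∂t = −u + ∫_{S²} w(r·r′) f( u(t − τ(r·r′), r′) ) dr′,
```

with sigmoid `f(u) = α / (1 + e^{−β(u−δ)})`, kernel
`w(s) = J₁ e^{−θ/σ₁} + J₂ e^{−θ/σ₂}` (`θ = arccos s`), and delay
`τ(s) = τ₀ + θ/c`. The maximal delay is `h = τ₀ + π/c`. A homogeneous steady
state solves `û = w₀ f(û)` with `w₀` the total kernel mass; its linearization
is diagonal in spherical harmonics with characteristic function

```
E_n(λ) = λ + 1 − κ G_n(λ),   κ = f′(û),
G_n(λ) = 2π ∫_{−1}^{1} w(s) e^{−λτ(s)} P_n(s) ds.
```

"Lumped gains" means the pair `(κJ₁, κJ₂)`: the linear problem depends on the
firing rate only through these products, so linear analyses are parameterized
by them directly (`LinearizationContext.from_lumped_gains`), while nonlinear
analyses carry the raw `(α, β, δ, J₁, J₂)`.

## Polar-angle quadrature

Every integral of the form `∫ w(s) g(s) ds` is evaluated by Gauss–Legendre
quadrature **in the polar angle** `θ = arccos s`, i.e.

```
∫_{−1}^{1} F(s) ds = ∫_0^π F(cos θ) sin θ dθ ≈ (π/2) Σᵢ wᵢ F(cos θᵢ) sin θᵢ.
```

The kernel `e^{−arccos(s)/σ}` and the delay factor `e^{−λ θ(s)/c}` are analytic
in `θ` but have square-root singularities in `s` at `s = ±1`; quadrature in
`s` converges slowly (and, for sharp kernels such as `σ = 2/9`, unacceptably
so), while quadrature in `θ` converges spectrally. This substitution is used
consistently in `harmonics.funk_hecke`, the tabulated nodes inside
`LinearizationContext`, the fold/Hopf machinery in `bifurcation`, and the
scalar reduction `simulate_homogeneous`. Default order is 256 nodes; the
adaptive `funk_hecke` doubles the order until two consecutive estimates agree.

## Root finding and certification

Roots of `E_n(λ) = 0` in a rectangle of the complex plane are located by
Newton iteration started from a grid of seeds, deduplicated, and filtered by
residual. The count is certified against the argument principle: the winding
number of `E_n` around the rectangle's boundary (sampled densely per side)
must equal the number of distinct roots found. `compute_spectrum` applies
this per degree; `rightmost_eigenvalue` reports the leading root and its
degree.

## Bifurcation machinery

- **Fold lines.** `E_n(0) = 0` is linear in the lumped gains, giving a line
  `a·κJ₁ + b·κJ₂ = 1` per degree with coefficients equal to the degree-`n`
  kernel transforms of the two exponentials.
- **Hopf curves.** For each frequency `ω`, `E_n(iω) = 0` splits into real and
  imaginary parts, a 2×2 linear system for `(κJ₁, κJ₂)`; sweeping `ω` traces
  the curve. Points are certified by re-evaluating the residual.
- **Balanced-kernel convention.** Nonlinear normal-form analyses close the
  underdetermined continuation with the constraint `w₀ = 0` (kernel mass
  zero), which pins `û = 0` and makes `κ = f′(0)`. The codimension-two
  double-Hopf solver then solves the five-unknown system {Re/Im `E₀(iω₀)`,
  Re/Im `E₁(iω₁)`, balance} by a hybrid Newton method and reports residual
  certificates for all five equations.
- **First Lyapunov coefficient.** The degree-0 Hopf normal-form coefficient
  is evaluated from the cubic coefficient

  ```
  g21 = (1 + iω₀) / (8π κ (1 − κ G₀′(iω₀))) · ( f‴(û) + f″(û)² [ Q₀(2iω₀) + 2 Q₀(0) ] ),
  ```

  with resolvent factor `Q₀(μ) = G₀(μ) / (μ + 1 − κ G₀(μ))`, and
  `l₁ = Re g21 / ω₀`. Before evaluation the critical root `iω₀` is re-polished
  by Newton *inside the evaluating context's own quadrature*, so that
  certificate and coefficient are computed with identical discretizations.
  The generalized-Hopf point is the sign change of `l₁` along the balanced
  Hopf branch, bracketed and bisected in `δ`.

## Amplitude system

The double-Hopf interaction of the homogeneous mode `w ∈ ℂ` and the degree-1
modes `z ∈ ℂ³` reduces, in the rotation-invariant coordinates
`x₁ = |w|²`, `x₂ = |z₀² − 2 z₋₁ z₁|`, `x₃ = |z|²`, to the cubic system

```
ẋ₁ = 2x₁(ρ₀ + ã₁x₁ + ã₂x₃)
ẋ₂ = 2x₂(ρ₁ + (b̃₁+b̃₂)x₃ + b̃₃x₁)
ẋ₃ = 2x₃(ρ₁ + b̃₁x₃ + b̃₃x₁) + 2b̃₂x₂²
```

(tildes denote real parts). Its first-octant equilibria admit closed forms:
the origin, two pure modes, and up to three mixed states — at most six in
total. The closed-form enumeration is cross-checked by an independent
multistart root search. One subtlety: the `x₁` and `x₂` components of the
field vanish identically on their zero faces, so Newton iterates started in
the interior never reach boundary equilibria; the multistart therefore seeds
the origin, the two invariant axes, and the two invariant faces explicitly in
addition to random interior points.

Stability is read from the explicit Jacobian. In the strong cross-coupling
regime (mutual suppression dominating self-saturation, `ã₂b̃₃ > ã₁b̃₁`),
exactly the two pure-mode equilibria are attractors — the bistability that
makes the full model's behavior near the double-Hopf point depend on initial
data. This is a property of that regime, not of every all-negative
coefficient set.

## Planforms

`planforms` stores the maximal-isotropy branch catalog for critical degrees
1–6, with branch counts 2, 5, 6, 10, 11, 15. For degree 4 the fixed-subspace
vector of each branch (length 9, coefficients over `m = −4…4`) is stored
explicitly, and `verify_branch` checks every generating spatiotemporal
symmetry numerically: for a generator `(γ, ψ)` the synthesized field must
satisfy `u(t, γ⁻¹ r) = u(t + ψT, r)` to a residual `< 1e−8`. The tetrahedral
branch deserves a note: with the fixed vector
`(√7, 0, √12 i, 0, −√10, 0, √12 i, 0, √7)` the three-fold rotation about
`(1,1,1)` pairs with phase `2T/3` (the conjugate reading of the vector pairs
with `T/3`); both are verified numerically to 2e−14.

## Mesh simulator

- **Mesh.** Geodesic icospheres (subdivided icosahedra) with
  `20·4^k` triangles. Quadrature weights assign each vertex one third of the
  spherical area (van Oosterom–Strackee solid angle) of its incident
  triangles, rescaled to sum to `4π` exactly.
- **Coupling.** The kernel matrix `W_ij = w_ij · weight_j` is corrected
  (constant-preserving) so every row sums to the exact kernel mass `w₀`; this
  makes homogeneous states exact discrete equilibria (preserved to 1e−10 in
  tests) and removes the dominant quadrature bias from the delayed integral.
- **Delays.** Each vertex pair has its own discrete delay `τ_ij/dt`, split
  into integer and fractional parts; history is interpolated linearly.
  The ring buffer stores **firing-rate snapshots** `f(u)` rather than `u`, so
  delayed terms interpolate `f∘u` in time instead of applying `f` to an
  interpolated field. Both choices are O(dt²); storing `f(u)` saves one
  full sigmoid evaluation of a vertex×vertex matrix per right-hand side.
- **Stepping.** Heun's method (explicit trapezoidal), with `dt` capped at
  `h/20` and `τ₀/2`.
- **Diagnostics.** Degree powers `Σ_m |⟨Y_nm, u⟩|²` per saved frame; the
  activity-weighted first moment ("center of mass"); and a standing-wave
  discriminator: stack the real and imaginary parts of the dominant degree's
  coefficient history into a matrix and take the ratio of its second to first
  singular values — a standing pattern keeps one complex line (ratio → 0)
  while a rotating one sweeps a two-dimensional subspace (ratio → 1).

## Accuracy cross-checks

The test suite ties the layers together: Funk–Hecke transforms against
brute-force double surface integrals (1e−6); characteristic roots against
argument-principle counts; the scalar homogeneous reduction reproduces the
spectral growth rate `Re λ` to 0.09%; level-2/level-3 mesh runs agree with
the scalar reduction to 7e−4 / 1e−4 (mesh quadrature error of the delayed
integral); and the reduced amplitude system commutes with the full normal
form under integration to 1e−6.
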