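# Methods

## Model and assumptions

The solver integrates the coupled chemotaxis–Navier–Stokes system for an
incompressible suspension of oxytactic cells in two dimensions:

```
q_t + u·∇q − Δq + α ∇·(q r(c) ∇c) = 0          (cells)
c_t + u·∇c − ζ Δc + β r(c) q      = 0          (oxygen)
u_t + (u·∇)u − Sc Δu + Sc ∇p      = −(0, Sc γ q)   (momentum)
∇·u = 0
```

in nondimensional form (lengths scaled by the chamber depth, time by the
cell-diffusion time, densities by a reference cell density, oxygen by its
interface saturation value).  The cut-off
`r(c) = (tanh((c − 0.3)/ε) + 1)/2` models cells becoming inactive below the
oxygen survival threshold 0.3.  Assumptions inherited from the model: the
suspension is dilute (cells affect the fluid only through buoyancy), cell
diffusion is isotropic with unit dimensionless coefficient, and the chamber
is closed except for the flat fluid–air interface at the top, where oxygen
is saturated (`c = 1`) and the chemotactic and diffusive cell fluxes cancel.

## Spatial discretization

A uniform MAC staggered grid: `p, ψ, q, c` at cell centres (`Nx × Ny`),
`v1` at vertical faces (`(Nx+1) × Ny`), `v2` at horizontal faces
(`Nx × (Ny+1)`).  All derivatives are second-order central stencils at each
variable's own points; the divergence and pressure gradient are the
compact staggered forms (the discrete curl of any nodal stream function is
exactly divergence-free).  Interpolation between staggered locations uses
two- and four-point arithmetic averages.

Boundaries enter through ghost layers:

* velocity: Dirichlet no-slip — on-grid at each component's wall-normal
  faces, reflected ghosts (`ghost = 2·wall − interior`) tangentially;
* scalars, bottom and sides: zero-gradient copies (for cell-centred
  unknowns the mirrored reflection equals the adjacent interior value, so
  this closure is second order);
* oxygen, top: the ghost cell itself is set to the saturated value 1
  (`ghost_mode='literal'`, the default); a reflected variant
  (`ghost = 2·1 − interior`) is available as `'reflected'`.  Both are
  provided because the interface condition can be read either way; the
  difference is O(h) in the ghost but did not visibly change any
  experiment;
* cells, top: two closures are provided (see "Chemotaxis term and top
  closure" below).

## Time stepping

Let `δt` be the step; histories are initialized by duplication
(`u^{-1} := u^0`, `q^{-1} := q^0`) and `p^{-1/2} = ψ^{-1/2} = 0`, so only
the first step is formally first order.

**Step 1 (velocity).**  Explicit predictor
`ũ = u^{n-1} + δt [ −(u*·∇)u* − Sc ∇p* + Sc Δu^{n-1} − f(q*) ]` with
`u* = (3/2)u^{n-1} − (1/2)u^{n-2}`, `q*` likewise, and
`p* = p^{n-3/2} + ψ^{n-3/2}`; then the ADI correction
`(I − (Sc δt/2) δxx) ū = ũ − (Sc δt/2) δxx u^{n-1}` followed by the same in
y, which together make the viscous term Crank–Nicolson one direction at a
time.  Every solve is a batch of tridiagonal systems of length ≤ max(Nx,
Ny)+1.

**Step 2 (pressure).**  The increment solves the factorized equation

```
(I − δxx)(I − δyy) ψ = −∇h·u^n / (Sc δt)
```

as two one-dimensional sweeps with homogeneous Neumann closures, then

```
p^{n-1/2} = p^{n-3/2} + ψ − (χη/2) ∇h·(u^n + u^{n-1}),   χ = 1/2.
```

The factorized operator replaces the Poisson operator of classical
projection; it dominates the Laplacian symbol, which is what makes the
stabilization unconditionally usable while leaving an O(δt) divergence
that vanishes under refinement (verified by a dedicated test).  The
`1/Sc` scaling of the right-hand side makes the increment equation
dimensionally consistent with the `Sc ∇p` momentum term: the
pressure-correction feedback then has unit gain.  Without it the coupled
iteration amplifies divergence by a factor O(Sc) per step — with
`Sc = 500` the baseline bioconvection run overflows within two steps,
which we verified directly.  For `Sc = 1` (the verification study) the two
scalings coincide.

**Steps 3–4 (scalars).**  Lie splitting by direction; for a pass of size τ:

```
x: (I − τζ δxx) c̄ = c⁰ − τ v1 δx c⁰ − w_x τ β r(c⁰) q_half [+ w_x τ f_c]
y: (I − τζ δyy) c  = c̄ − τ v2 δy c̄ − w_y τ β r(c̄) q_half [+ w_y τ f_c]
```

and analogously for `q` (unit diffusivity, chemotaxis instead of the
reaction), with the cell update consuming the freshly updated oxygen of the
same pass.  The reaction weights default to `(w_x, w_y) = (1/2, 1/2)` so
the total consumption per pass matches the PDE; applying the full term in
both sweeps (`'literal'`) or only the first (`'first'`) remain switchable
diagnostics — the literal weights converge to a doubled-consumption
equation and destroy the convergence order, which the temporal study
exposes.  `q_half` is the cell density extrapolated to the midpoint of the
pass sub-interval from the two step-level histories: coefficients
`(3/2, −1/2)` for the full pass, `(5/4, −1/4)` and `(7/4, −3/4)` for the
two half passes.  The convecting velocity is taken at each sub-interval's
endpoint: `u^n` for the full pass and the second half pass, and the
half-time velocity `(u^{n-1} + u^n)/2` for the first half pass — one
consistent one-step map family, which is what the extrapolation needs.

**Step 5 (extrapolation).**  The scalar pair is advanced once with `δt`
and twice with `δt/2`; `2·(half) − (full)` cancels the leading O(δt)
splitting error.  The velocity/pressure pair is already second order and is
computed once per step.  Histories rotate with the extrapolated fields.
A fixed-grid self-convergence study measures temporal orders ≈ 1.9/1.8
for `q/c` with the extrapolation and ≈ 1.1/1.0 without it.

## Chemotaxis term and top closure

`∇·(q r(c) ∇c)` is discretized in conservative face-flux form:
`F_{i+1/2} = ((qr)_i + (qr)_{i+1})/2 · (c_{i+1} − c_i)/h` and the term is
the face-flux divergence, which telescopes exactly.  At the top boundary
the zero-total-flux interface condition is imposed in its integral
(finite-volume) form: both the diffusive and chemotactic fluxes through
boundary faces are set to zero, so total cell mass is conserved to
round-off (`q_top_closure='flux'`, the default with the conservative
form).

Two literal alternatives are kept as switches for comparison with other
published discretizations of this system: the derivative-product chemotaxis
`(δx q) r(c) (δx c)` (`chemo_form='literal'`) and the exponential interface
ghost `q_ghost = q·exp(α(1 − c))` entering the implicit solve as a linear
ghost multiplier (`q_top_closure='exp'`).  Both have documented defects:
the product form omits the `q ∂(r ∂c)` part of the divergence and therefore
transports no cells where `q` is uniform (no surface layer forms from the
layered initial data), and the exponential ghost acts as a boundary mass
source — at the baseline study's resolution it doubles the total cell mass
by `t = 0.01`.  They are retained for comparison, not used by the defaults.

## Verification (manufactured solutions)

Exact fields on `[-1,1]^2` (all vanishing at `t = 0`):

```
q = c = (x − x²)² (y − y²)² t,   p = sin(πy) cos(πx) sin t,
v1 = π sin(2πy) sin²(πx) sin t,  v2 = −π sin(2πx) sin²(πy) sin t,
```

the unique reading of the study's fields that is exactly divergence-free
(checked symbolically at construction).  The exact fields do not satisfy
the homogeneous system, so forcing terms — the symbolic residuals of each
equation — are derived once with sympy and added to the discrete equations
at the time levels their terms are centred at: the momentum forcing at
`t^{n-1/2}` (the predictor/CN pair is centred there; evaluating it at
`t^{n-1}` is first-order accurate and measurably degrades the joint order),
and the scalar forcings split between sweeps with the reaction weights,
evaluated at each sub-interval's midpoint.

Boundary data is exact: Dirichlet for the velocity and exact-valued ghost
closures for the scalars (the chosen fields have nonzero normal
derivatives, so homogeneous Neumann closures would solve a different
problem).  One subtlety matters for the order: the *intermediate* field of
a split step differs from the exact solution by O(τ) at the boundary, so
the x-sweep imposes *corrected intermediate data*
`c̄ = c − τζ c_yy + τ v2 c_y + w_y τ β r q − w_y τ f_c` (and the analogous
expression for `q̄`), evaluated on the exact fields with the reaction and
forcing taken at the sub-interval midpoint.  With plain exact ghosts the
boundary error is O(τ) and the observed temporal order of the scalars
collapses to one; with the corrected data the error is O(τ²) locally and
the scheme measures second order.

Errors are discrete l2 norms over each field's own points; pressure is
compared at its native half time level `T − δt/2`.  Orders are least-squares
slopes of `log(error)` vs `log(h)` over all grids with the coupling
`δt = 0.1 min(hx, hy)`.  The study of record uses `N ∈ {25, 50, 100}`
(chosen to keep the full suite to minutes on one CPU); measured slopes are
1.97 (q), 2.04 (c), 2.00 (v1, v2), 2.00 (p).  The temporal study uses a
fixed 24² grid with `δt ∈ {1/80, …, 1/640}` and self-convergence
differences, which cancel the fixed spatial error exactly.

## Experiments and their initial conditions

The bioconvection chamber is `(-3, 3) × (0, 1)` with the top open to air.
The generator provides the perturbed-layer data

```
q0 = 1 where y > 0.499 − 0.01 sin((x − 1.5)π), else 0.5;  c0 = 1;  u0 = 0
```

and a random layer `q0 = 0.8 + 0.2·U(0,1)` per cell (seeded, reproducible).
The study resolution is `hx = 0.02, hy = 0.005, δt = 1e-4`; presets cover
`ζ ∈ {5, 25, 50}` at `(α, Sc, η, β, γ) = (10, 500, 1, 50, 5000)` and the
weaker-forcing pairs `(β, γ) = (10, 1000), (30, 3000)` at `ζ = 5`.

These synthetic conditions emulate the canonical laboratory setup (an
initially well-oxygenated uniform suspension with a slightly disturbed
density interface); they do not emulate cell-scale granularity, surface
tension or meniscus effects, evaporation, or three-dimensional flow, so
conclusions from these runs speak to the 2D continuum model only.

The quantitative diagnostic is the plume front depth — the lowest cell
centre with `q ≥ 0.75` (midway between layer and background) — and the
*first midline crossing*: the first time the front, after having been at or
above `y = 0.5`, drops below it.  The retraction requirement matters
because the prescribed interface perturbation spans `0.489–0.509` and
therefore already dips below the midline at `t = 0`; without it the
statistic would fire on the initial condition rather than on plume descent.

### Stability of the baseline regime

With the conservative, mass-conserving discretization the three `ζ` presets
behave differently, and the package's tests encode what we measured:

* `ζ = 25` and `ζ = 50` develop the full instability: the chemotactic
  surface layer forms, destabilizes and crosses the midline at `t ≈ 0.103`
  and `t ≈ 0.090` respectively (150 × 100 grid, `δt = 2e-4`), with larger
  oxygen diffusivity giving a thicker surface layer and a faster descent —
  the expected monotone trend in `ζ`.
* At the baseline `ζ = 5` the layer that forms is very thin
  (its thickness scales like `ζ/(α β)`-ish through the oxygen gradient) and
  sits against the no-slip interface, where long-wavelength buoyant flow is
  strongly suppressed; the perturbation and the velocity decay
  monotonically to at least `t = 0.25` at the full study resolution.  The
  fluid response was cross-checked against an independent sparse MAC Stokes
  solve (agreement to 4+ digits) and the density–velocity feedback has the
  correct unstable phase (downflow under heavy columns,
  correlation −0.98); the configuration is simply linearly stable under
  this discretization of the governing equations.  The acceptance runner
  therefore reports the simulated horizon as a lower bound on the baseline
  crossing time rather than a crossing.  The literal scheme switches do
  produce early descent in this regime, but through the boundary mass
  source documented above, which we do not consider a reproduction of the
  physics.

## Numerical choices and limitations

* Tridiagonal solves: Thomas forward/backward sweeps vectorized across the
  batch, no pivoting (every system the scheme builds is strictly diagonally
  dominant); a pivot-magnitude guard (`1e-14` relative) raises with the
  offending system index instead of continuing.  Constant-coefficient
  factorizations are cached per (κ, h, n, closure) and reused every step.
* ε (cut-off sharpness) defaults to 0.01: the source models use an
  effectively sharp switch at `c = 0.3`, and 0.01 resolves the tanh over a
  few grid cells at study resolutions.
* Convection is explicit and central: no upwinding, no flux limiting, no
  positivity preservation (small undershoots near sharp fronts are
  expected); a warning is emitted once if the convective Courant number
  exceeds one.
* The stabilized pressure leaves `∇·u ≠ 0` at finite `δt` (decreasing under
  refinement); diagnostics record its l2 norm every step.
* Snapshot schedule matches requested times to the nearest step; runs are
  bit-reproducible for a fixed configuration and seed.
* Corner ghost cells are filled x-rule-then-y-rule; no stencil in the
  scheme reads them, the order is fixed only for reproducibility.
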