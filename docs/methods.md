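# Methods

`pdeocp` solves open-loop optimal control problems for spatially
distributed biological systems by the direct route: semi-discretize the
PDE in space (method of lines), parameterize the time-varying controls
by a small number of coefficients (control vector parameterization,
CVP), and attack the resulting bound-constrained nonlinear program with
a hybrid global–local strategy. Two case studies are built in: boundary
control of a 1D bacterial-chemotaxis model and multi-actuator
suppression of spiral waves in a 2D FitzHugh–Nagumo (FHN) excitable
medium, the latter optimized on a proper-orthogonal-decomposition (POD)
reduced-order model.

## Models

### Chemotaxis (1D)

Cell density z(ξ,t) and chemoattractant concentration c(ξ,t) on the
unit tube ξ ∈ [0, 1]:

    ∂z/∂t = D ∂²z/∂ξ² − μ ∂/∂ξ [ z/(1+c)² ∂c/∂ξ ],
    ∂c/∂t = ∂²c/∂ξ² + z²/(1+z²),

with D = 0.33 (cell diffusion), μ = 80 (chemotactic sensitivity), both
dimensionless, and initial state z ≡ 1, c ≡ 0. All boundaries are
zero-flux except the chemoattractant at ξ = 1, where a semi-permeable
membrane exchanges attractant with an external reservoir at
concentration u(t) ∈ [0, 1]:

    ∂c/∂ξ (1, t) = u(t) − c(1, t).

Two targets are posed for the final-time density z(ξ, 1): OCP1, a
Gaussian z_T(ξ) = 2.2 exp(−25(ξ−0.5)²) + 0.1, and OCP2, the uniform
profile z_T ≡ 1, with the cost

    J = L/(2 n_ξ) Σ_j (z_j(t_f) − z_T,j)².

At μ = 80 the uniform state is strongly Turing-unstable (the k = 2π
perturbation mode grows at rate ≈ 13.6 on the unit horizon), which is
what makes the control problem sharply multimodal: small control
differences are amplified into completely different final patterns.

**Boundary mass budget.** The stated boundary data (z_ξ = 0 together
with the Robin condition on c) leave the *advective* cell flux at the
membrane, μ z/(1+c)² c_ξ = μ z(1)/(1+c(1))² (u − c(1)), nonzero
whenever u ≠ c(1). Whether that flux is realised or suppressed is a
genuine modelling fork, and it decides which objective values are
attainable at all: the Gaussian target carries cell mass
∫z_T dξ ≈ 0.880 against an initial mass of 1.000, and a short
Cauchy–Schwarz argument shows any exactly mass-conserving dynamics has
J₁ ≥ 7.2×10⁻³ regardless of the control. `ChemotaxisSystem` therefore
exposes the fork explicitly through `scheme`:

- `'literal'` (default for the control problems): conservative interior
  flux differences plus the signed advective wall flux written above.
  Feeding the reservoir (u > c(1)) advects cells out through the
  membrane; a starved reservoir draws the wall value back in. This is
  the literal transcription of the printed boundary data and the only
  stable variant whose optima reach the 10⁻³–10⁻⁴ range; its OCP1
  optima form a central aggregate of amplitude ≈ 2.3 at ξ = 0.5 with
  ≈ 10 % of the cell mass shed.
- `'conservative'`: zero wall flux; discrete cell mass is conserved to
  machine precision for every control (the weighted Laplacian is
  symmetric with vanishing column sums, and the transport term is a
  telescoping flux difference). Used for the conservation and
  grid-convergence test suites.
- `'upwind'`: outflow-only wall flux (a cell-free reservoir cannot
  advect cells in). Physically the cleanest leak, but bound-limited
  shedding makes its landscape markedly harder.
- `'nodal'`: product-rule evaluation at the nodes. Matches the PDE to
  4th order in the interior but is not conservative; at these
  resolutions the wall aggregation regime is unstable, so it is kept
  only as a documented variant.

**Discretization.** Uniform grids with both endpoints, trapezoidal
quadrature, and reflection-closed (ghost-point) finite-difference
stencils of order 2 or 4; the Robin slope datum enters the boundary
rows affinely, so each operator is a matrix plus a boundary vector
scaled by u − c(1) at evaluation time. The default is the 4th-order
stencil on 41 nodes, which in the mass-conserving variant agrees with a
2nd-order/121-node solution to a few percent in max-norm in the regimes
the optimizer visits. (Under controls that pile all cells into a
wall layer thinner than the mesh no 41-node scheme remains faithful;
grid-agreement checks therefore use representative optimization-regime
controls.)

**Time integration.** LSODA with rtol = atol = 10⁻⁸ on the interleaved
state [z₀, c₀, z₁, c₁, …], whose Jacobian is banded with half-bandwidth
4; the right-hand side is JIT-compiled. Piecewise-linear controls are
integrated in one sweep (the RHS is continuous); piecewise-constant
controls restart the integrator at element boundaries. A step cap
(mxstep = 6000) bounds the cost of pathological control regions; a
capped or non-finite run surfaces as the 10⁶ penalty cost so that
stochastic search simply routes around it.

### FitzHugh–Nagumo (2D)

Activator v and inhibitor w on [0, 200]²:

    ∂v/∂t = ∇²v + (α − v)(v − 1)v − w + u(ξ, t),
    ∂w/∂t = ε(βv − γw − δ),

with α = 0.1, ε = 0.01, β = 0.5, γ = 1, δ = 0, zero-flux edges, and six
equal-width vertical actuator bands each driven by an independent
current u_k(t) ∈ [−1, 1]. The inhibitor kinetics are written in the
standard activator–inhibitor orientation (w relaxes toward βv/γ on the
slow time scale): that refractory tail is what lets a broken front curl
into a persistent spiral, and what makes the travelling excitation a
pulse that exits the domain rather than a filling front.

The step initial condition (v = 1 for ξ₁ ≤ 10) launches a plane pulse
travelling in +ξ₁ at speed ≈ 0.44. `break_front` zeroes the upper half
plane (ξ₂ ≥ 100), mimicking a conduction block; the free end re-enters
and winds into a rotating spiral that sustains excitation indefinitely.
Defaults chosen from this phenomenology (the source protocol states
none of them): the block is applied at t_break = 200 (leading edge just
left of mid-domain), the spiral winds a further t_spin = 200 before the
control horizon starts, and the desired pattern is the unbroken-front
state at t_target = 240. The regular grid defaults to 49×49 (≈ 2400
nodes, ≈ 4800 ODEs); pulse propagation fails below roughly 33 nodes per
axis, so coarser grids are rejected for dynamical studies. Explicit
adaptive Runge–Kutta at rtol = 10⁻⁶ integrates both the full model and
the ROM (the diffusion CFL scale on these grids is mild, so implicit
methods buy nothing).

## POD reduced-order model

Snapshot protocol (all from simulation, reproducible from one seed):
(a) the plane-front run, u = 0, sampled every 10 time units on
[0, 200] (21 snapshots); (b) the spiral, sampled every 10 over the 200
units after the block (20); (c) 15 runs from the spiral state with the
60-unit horizon split into 10 segments of 6, each segment driving every
band with an i.i.d. uniform[−1, 1] value, sampled at segment ends
(150). Snapshots are not mean-centred.

The POD bases diagonalise the two-point correlation kernel of each
ensemble. On a quadrature grid this is done by the method of snapshots:
eigendecompose the ℓ×ℓ weighted Gram matrix G = XᵀWX/ℓ and lift each
eigenvector to a spatial mode φᵢ = X aᵢ /√(ℓ sᵢ), orthonormal under the
quadrature inner product; energies are the variances sᵢ in descending
order, and each mode's sign is fixed by making its largest-magnitude
entry positive. The Galerkin ROM precomputes the projected Laplacian
P_A and band-injection map U_A; the nonlinear kinetics are evaluated by
full reconstruction on the grid each step (no empirical interpolation),
which keeps the ROM exact on the span of the basis — with the complete
basis it reproduces full-order trajectories to solver tolerance.

Mode counts: the published choice of 85 activator and 28 inhibitor
modes gives ≈ 5 % relative L2 front-tracking error on the default grid
and is the default. With our ensembles the 99.95 % energy criterion
alone selects fewer modes (≈ 39/22), which under-resolve front
translation (a linear basis represents a moving front poorly — energy
criteria are optimistic for transport-dominated fields); the energy
rule remains available when explicit counts are not given.

## Control parameterization and refinement

Controls are ρ coefficients per channel, either piecewise-constant on ρ
equal elements or continuous piecewise-linear through ρ equispaced node
values; decision vectors are the channel-major flattening (6 bands × 10
elements = 60 variables for FHN). Refinement splits every element, so
it reproduces the incumbent control *exactly*: ρ → factor·ρ for PC and
ρ → factor·(ρ−1)+1 for PL (7 → 13 node values). Re-sampling at
factor·ρ equispaced nodes instead would shift interior kinks of a
bang-bang-like optimum and was observed to change its cost by two
orders of magnitude — exact lifting is what makes
refine-then-polish monotone.

## Optimization

All solvers treat the cost as a black box: unpack the decision vector,
simulate, evaluate the final-time objective (failures → 10⁶ penalty).

- **Local (`local_solve`)**: SLSQP with bound-respecting
  central-difference gradients at step 10⁻⁵ in scaled variables, and
  restarts from its own endpoint while the decrease is material.
  Forward differences at the usual square-root-of-eps step sit below
  the integrator noise floor and stall far from optimality on these
  simulation-backed costs; central differences plus restarts descend
  reliably through the narrow curved valleys the chemotaxis instability
  produces.
- **Multistart (`multistart`)**: uniform seeded starts, each polished
  locally; summarised as a unit-bin histogram of log₁₀ J — the standard
  multimodality diagnostic.
- **Hybrid (`hybrid_solve`)**: scatter search. A seeded diverse pool
  initialises a reference set of the best plus the most mutually
  distant members (maximin in scaled space); pairwise combinations
  along connecting segments (interpolation and extrapolation, with a
  go-beyond step while an offspring keeps improving on its parent)
  refresh the set, subject to a minimum-distance filter; stalled sets
  regenerate their worst half with fresh diverse members; the local
  solver polishes the incumbent every 10 improvements. 70 % of the
  evaluation budget feeds this global phase; the remainder funds a
  deep final polish of the winner. Identical seeds give bit-identical
  results.
- **Refinement driver (`refine_and_polish`)**: lift the incumbent
  control exactly to the finer level and polish locally; by
  construction the refined cost never exceeds the coarse one.

## Problem sizes used by the shipped experiments

The acceptance script and the heavier test fixtures run the full
10-repetition protocol for both chemotaxis problems at ρ = 7
piecewise-linear with a 2 000-evaluation budget per run (plus a
1 500-evaluation refinement polish at ρ = 13), and the multistart study
at 50 starts per interpolation type; these sizes keep a complete
reproduction on a single CPU core in the tens of minutes. Larger
budgets improve the attained objectives only marginally (the landscape,
not the budget, is the binding constraint — see below).

## What the synthetic experiments do and do not show

Everything here is generated by the package's own simulators; no
external data enters. Passing tests therefore certify internal
consistency — discretization orders, conservation identities, POD
optimality and exactness-on-span, optimizer contracts and
reproducibility — not agreement with laboratory chemotaxis or cardiac
preparations.

Two caveats deserve emphasis. First, the chemotaxis boundary physics is
genuinely underdetermined: the printed boundary data conserve cell mass
if transcribed with a closed wall, yet the benchmark objective values
for the Gaussian target are only attainable when the wall exchanges
mass (the conserving bound is J₁ ≥ 7.2×10⁻³). Our literal-flux default
reaches J₁ ≈ 1.7×10⁻³ at ρ = 7 — the same central-aggregate morphology,
but about 7× above the published best, and two independent global
probes (large-budget differential evolution and iterated SQP descent)
converge to the same basin with the control railing at u = 1, i.e. the
remaining gap is a property of this discrete problem's shedding
capacity, not of the search. Second, the reservoir-tracking optimum of
the uniform-target problem (u = 0.5 t, J ≈ 10⁻¹⁹ here) sits in a
needle-thin basin — a ±0.05 control perturbation raises J by six orders
of magnitude — so stochastic search lands near, not on, it. Both
observations are consequences of the μ = 80 instability and hold for
any faithful transcription of the stated equations.

## Numerical choices and degenerate inputs

- Trapezoidal weights double as the POD mass matrix; modes with energy
  below 10⁻¹³ of the leading one are discarded (rank cutoff).
- All-zero snapshot ensembles, non-finite fields, mismatched shapes and
  out-of-horizon control evaluations raise immediately rather than
  propagate.
- Objective ties in the reference set break toward the earlier member;
  mode signs, refset membership and all random draws are functions of
  the seed only, so every experiment is bit-reproducible.
- Grids require at least 3 nodes per axis; FHN dynamical studies should
  use ≥ 33 to propagate the pulse.

## Known limitations

- The chemotaxis wall-flux fork (above) caps how closely the published
  Gaussian-target objective can be matched; the conserving variant is
  provably unable to reach it, and the literal variant lands within an
  order of magnitude.
- POD with raw snapshots represents travelling fronts inefficiently;
  mode counts well beyond the nominal energy criterion are needed for
  front tracking, and no hyper-reduction (DEIM) is implemented, so ROM
  right-hand sides cost a full reconstruction per call.
- The scatter-search internals (reference-set size, trigger rule,
  regeneration) follow standard practice but are not tuned per problem;
  on the chemotaxis landscapes roughly one seeded run in three stalls
  in a poor basin, which the 10-run protocol absorbs.
- Single-threaded throughout; the FHN full-order model at the default
  grid is comfortably simulable but too slow for direct optimization,
  which is the point of the ROM.
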