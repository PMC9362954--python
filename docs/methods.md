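# Methods

## Model

The state is a point (x, y) on the simplex x, y ≥ 0, x + y ≤ 1; z = 1 − x − y
is free space. The vector field is

    ẋ = x[(1 − x − y) f_C − ξ] + μ(y − x)
    ẏ = y[(1 − x − y) f_D − ξ] + μ(x − y)

with f_C = (1 − σ₁)x − σ₁y + σ₁ and f_D = (β − σ₂)x + ((2p − 1)η − σ₂)y + σ₂.
All quantities are dimensionless; time is the ODE's intrinsic unit.

Assumptions worth keeping in mind:

* well-mixed, infinite population (deterministic densities, no demographic
  noise, no spatial or network structure);
* ecological (birth/death) and evolutionary (game/mutation) dynamics share
  one time scale;
* free space is purely altruistic: it gates births multiplicatively and adds
  σ₁/σ₂ to fitness while never earning payoff itself;
* mutation is symmetric and state-independent.

## Parameters

| name | meaning | domain | notes |
|------|---------|--------|-------|
| ξ  | death rate | (0, 1] | equal for both strategies |
| β  | temptation payoff T | (1, 2) | same in both games; keeps 2R > S + T |
| η  | mutual-defection payoff magnitude | (0, 1) | +η in the PD, −η in the SD |
| p  | probability of playing the PD | [0, 1] | p = 1/2 zeroes the mixed payoff (2p−1)η |
| μ  | bidirectional mutation rate | [0, 1] | μ = 0 recovers the mutation-free model |
| σ₁ | free-space benefit to cooperators | [0, 1] | |
| σ₂ | free-space benefit to defectors | [0, 1] | |

Validation is strict by default; `unchecked=True` accepts any finite values
(some analyses probe boundaries and parameter planes extend to them), and
the flag is carried on the instance. Boundary values of the printed
domains (e.g. μ = 0, ξ = 1) are legal.

## Integration

Classical fixed-step RK4 with δt = 0.01 and a cap of 2×10⁶ steps (total
time 20,000), storing the final point to decide the asymptotic state; this
is the reference protocol behind every label map and sweep. On top of it
the integrator adds an optional early stop when the per-step change in both
coordinates falls below 10⁻¹² (`convergence_tol`; 0 disables it). The stop
freezes exponentially decaying tails at ~10⁻⁹ density instead of ~10⁻¹⁷, far
below the 10⁻³ classification threshold, so it changes no attractor label
while cutting grid-scan cost by roughly an order of magnitude; the test
suite compares stopped and exhaustive runs directly. Grid experiments
default to a desk-scale budget of 2×10⁵ steps.

The inner loop is JIT-compiled (numba) because grid scans integrate up to
10⁴ trajectories; batch entry points vectorize over initial conditions and
per-cell parameters. A non-finite state aborts with the failing step index:
the continuous system is bounded, so blow-up can only mean an invalid
unchecked parameter set or a bug. Step adequacy is checked against an
adaptive DOP853 solve (rtol 10⁻¹²) in the tests.

Final states are classified with threshold 10⁻³ per coordinate
(extinction / defector-free / cooperator-free / coexistence). The model's
reported equilibria have coordinates either exactly 0 or ≥ 0.0899, so the
threshold sits two orders of magnitude clear on both sides; it is exposed
as `tol` everywhere.

## Equilibria

* μ = 0: E₀ is exact; E₁ and E₂ are quadratic-formula roots kept in (0, 1]
  (branches tagged "plus"/"minus"); E₃ substitutes the linear relation
  y(x) from f_C = f_D into z·f_C = ξ and takes the real roots of the
  resulting quadratic inside the open simplex. Degenerate denominators
  ((2p−1)η + σ₁ − σ₂ ≈ 0, σ₁ = 1, p = 1/2) reduce the equations' degree and
  are solved as such rather than divided through, since parameter sweeps
  cross these measure-zero lines.
* μ > 0: single-species rest points cannot exist (the mutation flux
  repopulates an empty strategy), so the solver returns E₀ plus interior
  roots from a multistart Newton iteration (`scipy.optimize.root`, analytic
  Jacobian) seeded on an n×n simplex grid, deduplicated at distance 10⁻⁷.
* σ₁ = σ₂ = μ = 0: the axis families have fully closed forms
  ({0, (1 ± √(1 − 4ξ))/2} on the x-axis and the analogue with a = (2p−1)η on
  the y-axis), exposed separately; p = 1/2 is reported as a degenerate-empty
  family with a flag. The axis flow's implicit time solution is provided as
  the conserved quantity `axis_time_invariant` (complex-safe for ξ < 1/4)
  and verified along trajectories in the tests.

Every returned equilibrium is polished by a few Newton steps and must have
RK4 right-hand-side residual ≤ 10⁻⁹; this single invariant is the oracle
behind all equilibrium routines.

## Stability

The Jacobian is analytic (matched against central finite differences at
10⁻⁶ in the tests). Two verdicts are computed at each equilibrium:

* eigenvalue verdict: margin = max Re λ of the Jacobian; stable iff
  margin < 0; |margin| ≤ 10⁻⁸ is reported "marginal" rather than forced to a
  side, because the closed-form conditions are strict inequalities.
* closed-form verdict: the printed inequality pairs for E₀ (σᵢ < ξ when
  μ = 0; 2(ξ+μ) > σ₁+σ₂ together with μ² < (ξ+μ−σ₁)(ξ+μ−σ₂) when μ > 0),
  E₁, and E₂. For interior points the published multi-line conditions are
  the trace/determinant pair of the 2×2 Jacobian expanded (parts of the
  printed expansion are typographically truncated in the source text), so
  the implementation uses {tr J < 0, det J > 0} directly; the expanded
  σ = 0 fragments are reproduced verbatim in the tests and shown equal.

Agreement of the two routes on ≥1000 non-marginal random draws per family
is the central correctness check of the stability layer.

`stability_threshold` bisects the margin of a named family along one
parameter (Brent, 10⁻⁶), with a 101-point pre-scan that also catches margins
sitting exactly on zero at a grid point.

## Experiments

* Basin scans iterate a grid of initial conditions (cells with
  x₀ + y₀ > 1 marked invalid); phase diagrams iterate a parameter plane from
  one fixed start, default (0.35, 0.35). Both are deterministic by
  construction and carry full provenance metadata, including a multistability
  caveat: near stability boundaries the simulated label depends on the
  chosen start and legitimately disagrees with the analytic curves.
* Stability curves are zero contours of a family's margin field over the
  grid axes (marching squares via `skimage.measure.find_contours`); cells
  where the family is absent are filled as unstable, so spurious fragments
  can only appear along family-existence boundaries.
* Sweeps record the final (x, y) per parameter value. `find_transition`
  brackets a sign change of x_final − y_final (density crossing) or
  x_final + y_final − tol (extinction onset) on a coarse pre-scan and
  bisects to 10⁻⁴. Bisection assumes the long-run state varies continuously
  between transitions, which holds away from basin boundaries for a fixed
  start.

## Numerical choices and caveats

* Extinction-onset sweeps measure where a trajectory's final density drops
  below tol within the step budget. Near the boundary the leading
  eigenvalue vanishes linearly, so finite time biases the located onset by
  ≈ 5.7/(T·|dλ/dθ|); at the reference budget T = 20,000 this is a few 10⁻⁴
  in the swept parameter. Tests that compare against analytic thresholds at
  10⁻³ use the full budget.
* The model is genuinely hysteretic in places: at ξ = 0.25, μ = 0.5,
  σ₂ = 0.25 a stable coexistence branch is born in a saddle-node at
  σ₁ ≈ 0.237, below the analytic extinction boundary σ₁ = 0.25. A sweep
  from (0.35, 0.35) therefore locates the survival onset at the saddle-node,
  while a sweep from a small seed (0.001, 0.001) measures the analytic
  boundary itself; both behaviors are asserted in the tests.
* One published equilibrium coordinate is reported here from the printed
  formula rather than the printed number: the stable defector-free root at
  the bistable reference parameters evaluates to 0.347597, while 0.34751
  circulates; the companion root 0.0899 matches to all printed digits.
* Basin/phase fixtures encode each figure panel's caption parameters; where
  a panel's axis pairing is not stated outright it was inferred from the
  fixed-parameter lists, which affects only the fixture configs.

## What a green test establishes

The test suite exercises the deterministic model under the stated parameter
domains: closed-form roots, residual and simplex invariants, closed-form vs
eigenvalue stability agreement, integrator step adequacy, and the label
structure of scaled-down grids (21×21 instead of 101×101, 2×10⁵ steps
instead of 2×10⁶). It does not certify full-resolution figure
reproductions, behavior outside the legal domains, or any stochastic,
finite-population, or spatial extension of the model — those are out of
scope by design.
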