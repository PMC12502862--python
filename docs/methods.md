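# Methods

## Model and assumptions

The chain is a discrete worm-like chain of N rigid bonds of length l_b
(natural units: l_b = 1, k_BT = 1), joints r_0 … r_N with r_0 fixed at the
origin. The energy has three additive terms, each with a single defining
code location (`polymer.energy_terms`):

* **bending** Σ κ(1 − t_{i−1}·t_i) over interior joints — always ≥ 0, zero
  iff all consecutive tangents are parallel; for stiff chains the
  persistence length is ≈ κ l_b;
* **stretching** −f l_b Σ (t_i·x̂) — a constant force f along x applied
  through every bond, equal to −f·x_N for the anchored chain;
* **shear** −γ l_b Σ z_i (t_i·x̂) — a linear shear-gradient coupling in
  which the *starting* joint's height z_i multiplies the bond's x-tangent.
  A bond-midpoint height would be an equally defensible discretization; the
  starting-joint convention is chosen and fixed here.

Self-avoidance is a hard sphere of radius l_b/2 on every joint: any
non-consecutive joint pair closer than l_b is forbidden. There are no
torsional terms and no interactions beyond the hard spheres. Temperature
enters only through the Metropolis rule. The shear term is a *static*
energy coupling — the model describes equilibrium sampling under an
effective driven Hamiltonian, not hydrodynamics.

End-to-end distance is R² = |r_N − r_0|² (all N+1 joints participate;
with N bonds the last joint is r_N). Gyration quantities are computed in
centroid form, O(N): Rg² is the mean squared distance of joints from their
centroid and R_xz the centroid-referenced mean of (x_i − x̄)(z_i − z̄); the
pair-average form (half the mean over all joint pairs) is mathematically
identical and asserted in the tests. Normalized inversion targets divide
R² by L² and, by default, Rg² and R_xz also by L² (dimensionless); the
exponent is configurable (`norm_exponent=1` gives per-contour-length
normalization) because plotted conventions vary.

## Monte Carlo sampling

Two non-local moves, attempted with equal probability:

* **crankshaft** — pick joints a < b (b ≥ a+2), rotate the joints strictly
  between them about the a–b axis by a uniform angle in [−α, α];
* **pivot** — pick a pivot joint p uniformly, rotate the tail p+1 … N about
  an isotropically random axis through r_p.

Both are rigid rotations, so bond lengths are preserved exactly; joint 0
never moves. A proposal with a hard-sphere overlap is rejected outright;
otherwise Metropolis acceptance min(1, e^(−ΔE)) applies. One sweep = N
attempted moves. The move amplitude default is α = π/2 (acceptance ≈ 40–55%
across the studied parameter range; no auto-tuning is performed, so runs
are exactly reproducible from the seed). The initial state is the straight
rod along x̂, which is overlap-free. The inner loop is numba-compiled;
numpy reference implementations of each move back the per-move API and the
tests. Overlap checking is the O(k·N) moved-segment-versus-rest scan with a
1e−12 slack so exactly-touching spheres never trigger; a brute-force
all-pairs oracle is kept in the tests.

Schedule defaults (full protocol): 2·10⁴ equilibration sweeps, 10⁴ sampling
sweeps retaining one configuration every 10² sweeps. These reproduce the
closed-form equilibrium statistics (tangent correlation coth κ − 1/κ,
⟨R²⟩ = N, the Langevin force–extension law) within their Monte Carlo
standard errors; the test suite asserts all three at 3 blocked standard
errors. Statistical errors are estimated by block averaging (20 blocks)
to be robust to residual sample correlation.

## Scattering

I(Q) = |Σ_j e^{iQ·r_j}|²/M² over the M = N+1 joints (the anchored joint is
a scatterer too; the M² normalization makes the choice invisible at Q = 0).
Computed through separable complex phase factors, O(n_grid · M), never the
O(M²) pair sum — but exactly equal to it, which the tests assert at 1e−10.
By construction I(0) = 1, 0 ≤ I ≤ 1 and I(Q) = I(−Q). Maps are averaged
over retained MC samples only; no orientational average is taken, because
the anisotropy *is* the signal. The Q grid is uniform and symmetric on
[−q_max, q_max]² with an odd point count so the origin is on the grid, and
the spacing is held at 2π/L at every scale: q_max = (n_per_axis − 1)·π/L,
which at the full protocol's 51 points gives the [−50π/L, 50π/L] range.
No instrument model is included (no resolution smearing, no incoherent
background, no absolute calibration).

## Dataset protocol

Parameter triples are drawn uniformly: κ ~ U(2, 20), f ~ U(0, 0.5),
γL ~ U(0, 2) (γ = γL/L is what the simulation consumes). One MC run per
triple; its ensemble map is flattened (row-major, Q_x outer) into a row of
F, and the targets are the three energy parameters plus ensemble-mean
normalized conformation variables. Per-row seeds derive deterministically
from (master seed, row index), so any row reproduces in isolation. Failed
rows would be excluded with a logged reason recorded in the manifest, never
silently. Maps are clean simulated curves; a multiplicative-noise hook
exists but is off by default. The 70/30 train/test split is a uniformly
random disjoint row partition (1680 rows → 1176/504).

Scales ("profiles"):

| profile | rows | N | grid | configs/map | purpose |
|---|---|---|---|---|---|
| smoke | 20 | 20 | 11×11 | 20 | seconds; shape/contract checks |
| desk | 240 | 50 | 21×21 | 200 | minutes; all quantitative desk tests |
| paper | 1680 | 200 | 51×51 | 100 | full protocol; hours, row-parallel |

The desk schedule (2000 equilibration sweeps, 8000 sampling sweeps at
interval 40) was calibrated by measuring integrated autocorrelation times
of the conformation observables across the parameter range (8–21 sweeps):
interval 40 makes the 200 retained configurations approximately
independent, which is the schedule's design goal.

## SVD feasibility analysis

F is decomposed directly (thin SVD, no mean centering — a centering flag
exists for comparison); squared singular values are proportional to the
variance captured per axis. Each right singular vector's largest-magnitude
entry is made positive so projections are reproducible across linear-algebra
backends. A rapidly decaying spectrum (desk scale: σ_10/σ_0 ≈ 0.01) and
smooth variation of the targets in (FV0, FV1, FV2) coordinates indicate
that a continuous inverse map exists.

## Gaussian-process inversion

One scalar GP regressor per target, kernel
k(x, x′) = exp(−d²/2l²) + σ²δ with d the Euclidean distance between
flattened maps. Conventions, stated explicitly because they decide how the
reported numbers read:

* **σ convention.** The kernel diagonal carries σ²; the *reported* number
  is σ (the standard deviation, the square root of a sklearn-style
  `noise_level`).
* **Inputs** are raw intensities — no log transform, no feature
  standardization — so correlation lengths are comparable across targets.
* **Targets** are standardized internally to zero mean and unit variance
  (predictions mapped back). The kernel has unit amplitude, so the target
  must be O(1) for the (l, σ) landscape to be well conditioned; this is the
  `normalize_y` convention of sklearn's GP regressor, and the constant
  prior mean equals the training-target mean either way. Reported (l, σ)
  and log marginal likelihoods refer to the standardized target.
* **Optimization.** L-BFGS-B on the negative log marginal likelihood in
  (log l, log σ) with analytic gradients, bounds l ∈ [10⁻², 10³],
  σ ∈ [10⁻⁸, 1], from the initial point plus 5 seeded log-uniform restarts.
  A fixed 1e−10 diagonal jitter stabilizes the Cholesky factorization near
  the σ lower bound (sklearn's alpha convention); the standalone
  log-marginal-likelihood function defaults to zero jitter so a genuinely
  singular covariance surfaces as an error.
* The estimator follows the scikit-learn contract (get_params/set_params,
  underscore-suffixed fitted attributes) and composes with sklearn
  pipelines; sklearn's own GP regressor with the equivalent kernel is used
  in the tests as an independent oracle (agreement to ~1e−8 in the marginal
  likelihood and ~1e−3 in optimized hyperparameters), never as the
  implementation.

Models remember the training grid's hash; prediction on a map sampled on a
different Q grid is refused rather than silently interpolated.

## What the synthetic data does and does not show

The generator *is* the study protocol: it emulates equilibrium ensembles of
a single ideal-bonded, hard-sphere chain under uniform stretch and linear
shear coupling, with exact Poisson-free "detector" statistics (maps are
noiseless apart from finite-ensemble MC error). It does not emulate
instrument resolution, incoherent background, polydispersity,
concentration effects, charged-monomer interactions or nonuniform flow
profiles. Passing tests therefore demonstrate the internal consistency of
the forward model and the invertibility of *simulated* maps; applying the
trained regressors to measured detector images additionally requires the
experimental system to be well described by this Hamiltonian and the data
to be regridded onto the training grid.

## Numerical choices and degenerate inputs

Bond lengths are validated at 1e−9 relative tolerance; overlap uses strict
inequality with 1e−12 slack. Chains need ≥ 1 bond (≥ 3 for crankshaft
moves and full simulations). Q grids must be strictly increasing with an
odd point count. r² raises on zero reference variance instead of returning
a conventional value. A constant training target drives σ to its lower
bound and predictions to the constant. The SVD raises on non-finite
entries. All randomness flows from explicit integer seeds (numba's
MT19937 inside the MC kernel, numpy Generators elsewhere; per-row and
per-stage seeds spawned below 2³¹).

## Known limitations

* At desk scale the κ inversion is information-limited: with N = 50 the
  sampled κ ∈ [2, 20] reaches persistence lengths of 0.4·L, where maps of
  stiff chains become nearly degenerate. Held-out r² for κ lands around
  0.87–0.93 depending on the seed (the acceptance script reports the exact
  value for its seed), while f, γL and the conformation targets reach
  0.94–0.999. At the full protocol scale (N = 200, persistence ≤ 0.1·L)
  the κ maps are far better separated.
* The two-scale hyperparameter pattern — longer correlation lengths and
  smaller noise for conformation targets than for energy targets — is
  reproduced at desk scale and asserted in the tests.
* The full 1680 × 2601 protocol is supported (`--profile paper`, rows
  embarrassingly parallel via `n_jobs`) but takes hours on one CPU; the
  test suite verifies its shapes and runs the complete method at desk
  scale instead.
* Equilibrium sampling only: no dynamics, no parallel tempering, no
  cluster moves; at N ≈ 200 the O(N) energy recomputation and O(k·N)
  overlap scan per move are fast enough that cell lists are unnecessary.
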