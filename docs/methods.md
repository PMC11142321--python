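# Methods

This note documents the models, algorithms, parameter choices and
numerical conventions implemented in `dss`, and what the synthetic
studies do and do not demonstrate about real data.

## Linear models from snapshots

`fit_lti` solves `min_A ‖X′ − A X‖` over all consecutive snapshot pairs
(exact dynamic mode decomposition on the raw states), through the SVD
pseudoinverse of `X`.  A Tikhonov term (`ridge ≥ 0`, default 0) and an
optional SVD truncation rank (projected DMD, default off) regularize
ill-conditioned snapshot matrices.  `fit_ltv` fits one propagator per
transition from a sliding window of `window` transitions ending at the
current step (windows near the start slide right so every fit sees a
full window).  Per-step fitting from a single trajectory is
underdetermined, so each `A(t)` is the minimum-norm solution; with
`window = 1` it is the rank-one map aligned with the observed
transition, and with `window = T` every `A(t)` equals the LTI fit.
Defaults (`window=1`, `ridge=0`) favor fidelity to the observed
transitions over smoothness; users with noisy data should raise both.

**State-transition convention.**  `Φ(t₀,t) = A(t−1)⋯A(t₀)` with
`Φ(t₀,t₀) = I` (empty product).  With this convention the
finite-horizon Gramian `Go(t₀,t) = Σₖ Φ(t₀,k)ᵀC(k)ᵀC(k)Φ(t₀,k)`
contains the bare `C(t₀)ᵀC(t₀)` term at `k = t₀`, matching the standard
LTV Gramian, and the identity `Go = OᵀO` holds exactly for the stacked
observability matrix of the same horizon.  An alternative convention
that starts the product at `A(t₀)` would drop that first term and break
the identity; we do not use it.

Time stamps are carried through but the model index is the snapshot
index: non-uniformly sampled series are accepted and modeled per
transition, not per unit of physical time.

## Observability metrics

* `M1` counts singular values of `O` with `σₖ/σ₁ > rel_tol`.  The
  default `rel_tol = 1e-6` is shared with the functional-mode cutoff so
  that "directions counted by M1" and "modes retained for estimation"
  agree.  There is no canonical value; the cell-cycle study below shows
  the qualitative conclusions (single sensors look rank-deficient,
  greedy saturates at full rank) are stable across nearby tolerances.
* `M2 = x(0)ᵀ Go x(0)` equals the cumulative output energy
  `Σₜ ‖y(t)‖²` for stable LTI systems — an identity the tests verify by
  direct simulation.
* `M3 = trace(Go)` is linear in per-(time, state) contributions
  `wᵢⱼ = ‖row j of Φ(t₀,i)‖²`, which is what makes the LP formulation
  exact.

Infinite-horizon Gramians are only defined for stable systems; an
unstable request raises an error naming the offending eigenvalue rather
than silently truncating.  Finite-horizon and LTV Gramians cover
unstable or time-varying models (transcriptomics models are typically
not stability-checked).

## Benchmark systems

### Andronov–Hopf oscillator

The normal form `ẋ₁ = αx₁ − x₂ − x₁(x₁²+x₂²)`,
`ẋ₂ = x₁ + αx₂ − x₂(x₁²+x₂²)` with analytic Jacobian.  For `α < 0` the
origin is globally attracting ("dead"); for `α > 0` a stable limit
cycle of radius `√α` exists ("alive").  Default readout measures `x₁`.

### Fission-yeast cell-cycle network

A 13-state ODE in the Novak–Tyson tradition: the mitotic kinase
Cdc13/Cdc2 in four forms (active `G2K`, Tyr15-phosphorylated `PG2K`,
and their Rum1-bound trimers `G2R`, `PG2R`), the G1/S kinase Cig2/Cdc2
(`G1K`) and its trimer (`G1R`), free Rum1 (`R`), five ultrasensitive
Goldbeter–Koshland switches (`IE`, `UbE`, `UbE2`, `Wee1`, `Cdc25`, each
a fraction active), and exponentially growing cell `mass` that drives
kinase synthesis.  The parameter set is pinned in
`dss.benchmarks.NOVAK_TYSON_PARAMS`; it was calibrated once so that the
network produces relaxation oscillations with a mass doubling time near
140 min and a Cig2 kinase peak of amplitude comparable to the mitotic
kinase, and is not altered by any study.  `novak_tyson_trajectory`
implements division (mass halves when `G2K` falls back below 0.2 after
exceeding 0.4 — mitotic exit), keeping trajectories on a bounded
attractor.  Jacobians are evaluated by complex-step differentiation of
the rational vector field, accurate to machine precision; systems
without a Jacobian fall back to central differences with step
`1e-6·(1+|xᵢ|)`.

The model is stiff (Rum1 binding at rate 100/min and Michaelis
constants of 0.01), so the fixed-step RK4 integrator uses `dt = 0.005`
min for this system.

### Local observability

`local_observability_matrix` stacks `C, CJ, CJ², …` with `J` the
Jacobian at the evaluation state — the observability matrix of the
linearization, exact for linear systems and at equilibria.  For stiff
networks the raw stack is useless for effective-rank comparisons: row
norms scale as `‖J‖ᵏ` (here `‖J‖ ≈ 20/min`), so `σ₁` is set by the
fastest binding mode and every ratio `σₖ/σ₁` collapses below any
tolerance even with all sensors measured.  The `sample_interval`
option therefore builds the stack from the sampled-time propagator
`A_d = expm(J·Δt)` — the observability matrix of the system observed
every `Δt` — whose powers stay commensurate.  The cell-cycle study
uses `Δt = 0.5` min: long enough to damp the fast binding modes
(relaxation times ≲ 0.05 min), short enough that the 13-block stack
spans 6 min, well inside the window where the frozen linearization is
self-consistent against the ≈150 min cycle.

### Empirical Gramians

Two simulation-based constructions are provided, with different
purposes:

1. **State-perturbation Gramian** (`empirical_gramian`): trajectories
   from `x₀ ± ε eᵢ` give output differences `dᵢ(t)`, and
   `Go = (1/4ε²) Σₜ dᵢ(t)ᵀdⱼ(t) dt` (two-sided perturbations,
   left-endpoint quadrature, default `ε = 1e-3`).  This n×n matrix
   measures sensitivity of the outputs to the initial state and
   converges to the Lyapunov-equation Gramian for stable linear systems
   (verified in the tests at 5% Frobenius error).  Near a limit cycle
   its trace is dominated by phase response, which diverges near the
   phaseless point at the origin — so initial conditions close to the
   unstable equilibrium receive arbitrarily large values.
2. **Output-energy Gramian** (`output_energy_gramian`): the p×p data
   Gramian `Σₜ y(t)y(t)ᵀ dt` of a single simulation, whose trace is the
   signal energy the sensors actually collect.  This is the measure the
   bifurcation study uses, because it captures the phenomenon of
   interest — how much information a *given trajectory* delivers to a
   fixed sensor — without the phase-response singularity.

**Hopf study configuration** (`hopf_observability_sweep`): α on a
symmetric grid in [−1, 1]; initial conditions uniform in ±1, ±2, ±4
(8 per bound); `dt = 0.05`; horizon 2000 time units, i.e. hundreds of
cycle periods, so steady-state behavior dominates the transient on the
alive side while the dead side has fully decayed.  Visibility rises
monotonically in α with an alive/dead ratio ≈ 3·10³ between the grid
extremes.  Dispersion across initial conditions is reported scale-free
(coefficient of variation, and variance of log₁₀ M3) because the means
differ by three orders of magnitude across the grid: on the stable side
the initial condition sets the decaying signal's energy (CV ≈ 0.65–0.9),
while on the alive side all trajectories are drawn onto the same limit
cycle and deliver nearly identical energy (CV ≈ 10⁻³).

### Cell-cycle greedy study

States are sampled from simulated data: one long dividing trajectory
from the standard initial condition, burn-in discarded, 100 time points
drawn uniformly at random (seeded).  Greedy selection maximizes the
mean effective rank (`rel_tol = 1e-6`) of the sampled-time local
observability stack across those states, adding sensors until no
candidate strictly improves the metric.  With the pinned parameter set
the study reproduces the qualitative phenomenology robustly: any single
sensor leaves the system effectively unobservable (mean M1 ≈ 7–9 of
13 despite formally nonzero singular values), the greedy trajectory is
monotone with strongly diminishing returns, and a handful of sensors
(4–5, led by the CDK-complex states) suffices to reach full effective
rank 13.  Which member of the kinase/trimer family is selected first is
sensitive to the exact parameterization and should not be read as a
biological prediction.

## Sensor selection

* **Greedy** adds the admissible candidate with the largest metric at
  each step; ties break toward the earliest candidate in input order
  (deterministic).  The stopping rule requires strict improvement
  (threshold 0, configurable).  With no budget the greedy trajectory
  reaches the all-sensor metric.
* **Eigenproblem ranking** diagonalizes the data Gram matrix
  `G = Φ X₀ X₀ᵀ Φᵀ` (forward propagation of initial-state second
  moments; a single column `x(0)` gives the rank-one case).  The top
  eigenvectors are optimal dense measurement directions; because
  experiments measure genes, not linear combinations, each state is
  scored by eigenvalue-weighted squared loadings
  `sᵢ = Σⱼ Dⱼ vⱼ[i]²` and states are ranked by score.  The raw
  eigenvectors are returned for users who can measure directions.
* **Linear program** maximizes `Σ δᵢⱼ wᵢⱼ` over `0 ≤ δᵢⱼ ≤ 1` with
  per-time budget rows `Σⱼ δᵢⱼ ≤ p(i)` and, when a cluster map is
  present, at-most-one-per-cluster rows (HiGHS, tolerance 1e-9).  With
  budgets only, the constraint matrix is totally unimodular so a vertex
  optimum is integral; cluster rows can in principle produce fractional
  vertices, which are rounded largest-δ-first subject to budget and
  cluster feasibility.
* **Dynamic sensor selection** re-solves the chosen problem at every
  time point and emits the per-time `C(t)`.  Constrained energy
  maximization uses the ranking heuristic: solve unconstrained, then
  keep top-ranked sensors that satisfy the constraints.

## Estimation and functional observability

`x̂ = O†Y` by minimum-norm least squares; no regularization is applied
by default (the noise model of any particular assay is the user's
choice).  When ground truth is available, per-state relative errors use
the floor `|x̂ᵢ − xᵢ|/(|xᵢ| + 1e-8·scale)` so zero-expression genes do
not divide by zero; the median over states summarizes a run.
`functional_modes` retains rows of `Vᵀ` with `σₖ/σ₁ > 1e-6` (shared
with M1) and reconstructs through `VΣ⁻¹UᵀY`, identical to `O†Y` at the
same cutoff.  The rank test `rank([O; F]) = rank(O)` runs both ranks at
a shared tolerance scaled by `‖O‖₂`; one-hot rows of `F` are reported
per state as targeted observability.

The two-model reprogramming workflow (select biomarkers on a focused
sub-model, observe the full model) is a composition of `dss select` and
`dss estimate` on different model files, not a separate algorithm.

## Chromatin-informed constraints

Contacts are converted to dissimilarity `d = 1 − c/c_max` (simple and
monotone; `1/(1+c)` and log-scaling available), clustered by
average-linkage agglomeration on the precomputed dissimilarity, and cut
at the cluster count in `k_range` (default 2–10) maximizing the
silhouette score on the same dissimilarity, ties to the smallest k.
Average linkage is sensitive to minimal-dissimilarity "bridge" edges
between blocks; the planted-contact generator therefore models noise as
additive random-ligation background (exponential, mean
`noise_frac · within`) rather than level swaps, which matches how
spurious contacts arise in real maps.  Bin-to-gene aggregation of raw
Hi-C is out of scope: input is already gene-by-gene.

## Synthetic data: what it does and does not show

The generators emulate the *structure* of the motivating datasets —
regime switches in dynamics, non-negative expression with
multiplicative log-normal noise (clipped at zero, recorded as such),
block-structured contact maps, zero-mean multichannel traces — with
ground truth always returned for recovery tests.  They do not model
RNA-seq count statistics (library size, negative binomial dispersion),
dropout, batch effects, or genome-wide dimensionality; passing tests
demonstrate the correctness and the comparative behavior of the
algorithms (e.g. dynamic beats fixed selection under regime switches),
not performance guarantees on any particular assay.

## Problem sizes and numerical settings

Studies are sized to run comfortably on one CPU: 100 sampled cell-cycle
states (the phenomenology is unchanged between 100 and 1000), 24 Hopf
initial conditions per α at horizon 2000, 20 seeds for the dynamic-vs-
fixed comparison, 30-gene contact matrices, and enumeration oracles up
to 2¹² schedules.  LP tolerance 1e-9; Gramian symmetry enforced to
1e-8 relative and PSD checked to −1e-10; singular-value cutoffs as
above; all generators bit-reproducible under (spec, seed).

## Known limitations

* LTV models fitted with `window=1` are rank-one per step: they
  interpolate the training trajectory exactly but extrapolate only
  along it.
* Local observability uses the linearization; it is a first-order
  statement and inherits the usual caveats away from equilibria.
* The cell-cycle network is a reconstruction in the Novak–Tyson
  tradition with a pinned, calibrated parameter set; sensor identities
  at the family level (which CDK complex ranks first) are
  parameter-sensitive.
* Observer design beyond least squares (Kalman/Luenberger/functional
  observer gains) and enrichment analysis of functional modes are out
  of scope.
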