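# dss — observability-guided biomarker selection

`dss` is a Python toolkit for choosing which variables of a biological
system to measure.  Given time-series data — gene expression snapshots,
neural recordings, any multichannel trace — it learns a linear model of
the dynamics, quantifies how much information each candidate sensor
(biomarker) carries through *observability* analysis, selects sensor
sets under experimental constraints, and reconstructs the unmeasured
variables from the selected sensors.  Its distinguishing feature is
**dynamic sensor selection (DSS)**: re-choosing the measured variables
at every time point, so that observability is maximized even when the
underlying dynamics shift between biological regimes.

## The framework

A system with state `x(t) ∈ ℝⁿ` and measurements `y(t) = C x(t) ∈ ℝᵖ`
(p ≪ n) is *observable* when the output sequence determines the state.
For discrete-time linear dynamics `x(t+1) = A(t) x(t)` the stacked map
from the initial state to the outputs is the observability matrix

    O = [ C(t₀); C(t₀+1) Φ(t₀, t₀+1); … ; C(t) Φ(t₀, t) ],

with state-transition matrix `Φ(t₀,t) = A(t−1)⋯A(t₀)`, `Φ(t₀,t₀) = I`.
Because biological models are ill-conditioned, binary rank tests
(Kalman, PBH) are graded into three measures built on `O` and the
observability Gramian `Go = OᵀO` (equivalently a Lyapunov-equation
solution for stable LTI systems):

* **M1 (directions)** — effective rank of `O`: the number of singular
  values with `σₖ/σ₁` above a tolerance; how many state-space
  directions the sensors actually resolve.
* **M2 (energy)** — `x(0)ᵀ Go x(0)`: the output energy a given initial
  state releases into the sensors.
* **M3 (visibility)** — `trace(Go)`: the average visibility of all
  state directions.

Sensor selection maximizes a measure subject to experimental
constraints (per-time budgets, forbidden sensors, at most one gene per
chromatin cluster).  Three solvers are provided: greedy search,
eigenproblem ranking of the data Gram matrix `Φ x(0) x(0)ᵀ Φᵀ` (energy
metric), and a linear program over relaxed measurement indicators
`0 ≤ δᵢⱼ ≤ 1` (visibility metric, whose trace objective is linear).
Unmeasured genes are reconstructed by minimum-norm least squares
`x̂ = O†Y`; the SVD `O = UΣVᵀ` exposes the functionally observable
modes (retained rows of `Vᵀ`), with the rank test
`rank([O; F]) = rank(O)` deciding whether arbitrary mode matrices `F`
are recoverable.

Nonlinear benchmark systems (the Andronov–Hopf oscillator and a
13-state fission-yeast cell-cycle network) support local observability
via linearization and empirical Gramians built purely from simulation.

## Worked example

Select time-varying sensors for a gene-expression system whose dominant
observable gene switches mid-course (a regime shift), then estimate the
full initial state from the single selected biomarker per time point:

```python
import numpy as np
from dss import *

spec = GeneratorSpec(kind="ltv-switch", n=5, horizon=8, switch_times=(4,), seed=3)
model, regimes = regime_switch_ltv(spec, favored_states=(0, 3))
x0 = np.random.default_rng(3).uniform(0.5, 2.0, 5)
data = simulate(model, x0, 8)

sched, result = dss_schedule(model, method="lp", objective="m3",
                             constraints=ConstraintSet(budget=1))
print("per-time sensors:", sched.sensor_sets())
print("visibility objective:", round(result.objective, 4))

O = ltv_observability_matrix(model, sched, 0, 8)
Y = stack_outputs(data, sched, 0, 8)
report = estimate_initial_state(O, Y, truth=x0)
print("median per-gene error:", f"{report.median_error:.3e}")
print("retained functional modes:", functional_modes(O).n_modes, "of", 5)
```

Output:

```
per-time sensors: [['x0'], ['x0'], ['x0'], ['x0'], ['x0'], ['x3'], ['x3'], ['x3'], ['x3']]
visibility objective: 2.1118
median per-gene error: 2.466e-01
retained functional modes: 2 of 5
```

The linear program re-selects the sensor exactly at the regime boundary
(gene `x0` while the first regime dominates, `x3` afterwards).  With a
budget of one sensor per time point the observability matrix retains
two functional modes out of five, so the median per-gene error of the
minimum-norm estimate is 25% — and across 20 seeded regime-switching
systems the dynamic schedule reaches roughly a third of the estimation
error of the best fixed sensor chosen by the energy metric
(median-of-medians 0.058 vs 0.203; see `dss.dss_vs_fixed_study`).

The same workflows are scriptable from the shell:

```sh
dss fit --data expr.tsv --kind ltv --out model.json
dss select --model model.json --objective m3 --method lp \
    --budget-per-time 3 --clusters clusters.tsv --out schedule.json
dss estimate --model model.json --schedule schedule.json \
    --data expr.tsv --truth expr.tsv --report report.json
dss bench --system andronov_hopf --alpha=-1.0,0.0,1.0 --out bench.json
```

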