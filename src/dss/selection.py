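"""Static and dynamic sensor (biomarker) selection.

The sensor-selection problem is ``max_sensors M subject to experimental
constraints`` for an observability metric M.  Three solvers are
provided:

* greedy search, adding at each step the admissible candidate that most
  increases the metric (optimal when there is no budget, near-optimal
  with diminishing returns);
* eigenproblem ranking: the top eigenvectors of a data-derived Gram
  matrix G(t) = Phi x(0) x(0)' Phi' are the energy-optimal measurement
  directions; genes are scored by eigenvalue-weighted squared loadings;
* a linear program for the visibility metric M3, whose trace objective
  is linear in the relaxed measurement indicators delta_ij in [0, 1].

Dynamic sensor selection (DSS) re-solves the problem at every time
point, producing a time-varying measurement matrix C(t).  Constraints
cover per-time budgets, forbidden sensors, and at-most-one-gene-per-
chromatin-cluster rules derived from Hi-C contact maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .metrics import ObsMatrix, SensorSchedule, metric_rank
from .models import LinearModel, SnapshotSeries, state_transition

__all__ = [
    "ConstraintSet",
    "SelectionResult",
    "greedy_select",
    "greedy_local_rank",
    "build_gram",
    "rank_sensors_eigen",
    "trace_coefficients",
    "lp_select_m3",
    "dss_schedule",
    "InfeasibleConstraintsError",
]


class InfeasibleConstraintsError(ValueError):
    """Raised when the constraint set admits no feasible schedule."""


@dataclass
class ConstraintSet:
    """Experimental constraints on sensor selection.

    budget : sensors allowed per time step -- a single int or a per-time
        sequence.
    cluster_map : gene name -> cluster id; at most one gene may be
        measured per cluster per time step.  Genes absent from the map
        are unconstrained.
    forbidden : sensors that can never be measured.
    """

    budget: int | Sequence[int] | None = None
    cluster_map: Mapping[str, object] | None = None
    forbidden: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.forbidden = frozenset(self.forbidden)
        if isinstance(self.budget, (int, np.integer)) and self.budget < 1:
            raise ValueError("budget must be >= 1")

    def budget_at(self, t: int, default: int) -> int:
        if self.budget is None:
            return default
        if isinstance(self.budget, (int, np.integer)):
            return int(self.budget)
        if t >= len(self.budget):
            raise InfeasibleConstraintsError(
                f"budget sequence of length {len(self.budget)} does not "
                f"cover time {t}")
        return int(self.budget[t])

    def admissible(self, candidate, chosen: Sequence) -> bool:
        """Can `candidate` join `chosen` within one time step?"""
        if candidate in chosen or candidate in self.forbidden:
            return False
        if self.cluster_map is not None and candidate in self.cluster_map:
            cl = self.cluster_map[candidate]
            for c in chosen:
                if self.cluster_map.get(c, object()) == cl:
                    return False
        return True


@dataclass
class SelectionResult:
    """Outcome of a selection run.

    ``chosen`` is a flat list for static selection or a per-time list of
    lists for DSS.  ``metric_trajectory`` records the metric value after
    each greedy addition.  ``delta`` / ``delta_binary`` hold the relaxed
    and rounded LP indicators; ``eigenvalues`` / ``eigenvectors`` /
    ``scores`` come from the eigenproblem ranking.
    """

    chosen: list
    metric_trajectory: list = field(default_factory=list)
    objective: float | None = None
    delta: np.ndarray | None = None
    delta_binary: np.ndarray | None = None
    eigenvalues: np.ndarray | None = None
    eigenvectors: np.ndarray | None = None
    scores: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)


def greedy_select(evaluator: Callable[[list], float], candidates: Sequence,
                  budget: int, constraints: ConstraintSet | None = None,
                  min_increase: float = 0.0,
                  stop_on_no_improvement: bool = True) -> SelectionResult:
    """Iterative greedy maximization of ``evaluator`` over sensor sets.

    At each step the admissible candidate giving the largest metric is
    added (ties broken toward the earliest candidate in the input
    order).  Stops at ``budget`` sensors, or earlier when no candidate
    improves the metric by more than ``min_increase``.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate set")
    constraints = constraints or ConstraintSet()
    admissible0 = [c for c in candidates if constraints.admissible(c, [])]
    if budget > len(admissible0):
        raise ValueError(
            f"budget {budget} exceeds {len(admissible0)} admissible candidates")
    chosen: list = []
    trajectory: list[float] = []
    current = -np.inf
    while len(chosen) < budget:
        best, best_val = None, -np.inf
        for c in candidates:
            if not constraints.admissible(c, chosen):
                continue
            val = evaluator(chosen + [c])
            if val > best_val:
                best, best_val = c, val
        if best is None:
            break
        if stop_on_no_improvement and np.isfinite(current) \
                and best_val - current <= min_increase:
            break
        chosen.append(best)
        trajectory.append(float(best_val))
        current = best_val
    return SelectionResult(chosen=chosen, metric_trajectory=trajectory,
                           objective=trajectory[-1] if trajectory else None)


def greedy_local_rank(system, states: np.ndarray,
                      budget: int | None = None,
                      rel_tol: float = 1e-6,
                      sample_interval: float | None = None,
                      order: int | None = None,
                      constraints: ConstraintSet | None = None
                      ) -> tuple[SelectionResult, dict]:
    """Greedy sensor selection on the averaged effective rank (M1) of
    local observability matrices over a sample of system states.

    For each sampled state the linearization propagator (optionally the
    sampled-time form expm(J dt)) and its powers are precomputed once;
    a candidate sensor set is then scored by the mean effective rank of
    the stacked rows it selects, and sensors are added greedily until
    the metric stops improving.  Returns the selection result and the
    per-sensor single-sensor scores.
    """
    import scipy.linalg

    from .benchmarks import finite_difference_jacobian

    names = list(system.state_names)
    n = system.n
    order = order or n
    states = np.atleast_2d(np.asarray(states, dtype=float))
    powers = []
    for x in states:
        if system.jacobian is not None:
            J = np.asarray(system.jacobian(x), dtype=float)
        else:
            J = finite_difference_jacobian(system.vector_field, x)
        if sample_interval is not None:
            J = scipy.linalg.expm(J * sample_interval)
        pows = np.empty((order, n, n))
        pows[0] = np.eye(n)
        for k in range(1, order):
            pows[k] = pows[k - 1] @ J
        powers.append(pows)

    def mean_effective_rank(sensor_names: list) -> float:
        idx = [names.index(s) for s in sensor_names]
        total = 0
        for pows in powers:
            O = pows[:, idx, :].reshape(-1, n)
            s = np.linalg.svd(O, compute_uv=False)
            if s[0] > 0:
                total += int(np.sum(s / s[0] > rel_tol))
        return total / len(powers)

    result = greedy_select(mean_effective_rank, names,
                           budget=budget or n, constraints=constraints)
    singles = {nm: mean_effective_rank([nm]) for nm in names}
    return result, singles


def build_gram(model: LinearModel, X0: np.ndarray, t0: int, t: int
               ) -> np.ndarray:
    """Data Gram matrix G = Phi X0 X0' Phi' with Phi = Phi(t0, t).

    Columns of X0 are initial states at t0; a single column reproduces
    the rank-one x(0) x(0)' form.
    """
    X0 = np.asarray(X0, dtype=float)
    if X0.ndim == 1:
        X0 = X0[:, None]
    if X0.shape[0] != model.n_states:
        raise ValueError("X0 row count must equal model dimension")
    Phi = state_transition(model, t0, t)
    M = Phi @ X0
    return M @ M.T


def rank_sensors_eigen(G: np.ndarray, k: int,
                       state_names: Sequence[str] | None = None,
                       sym_tol: float = 1e-8) -> SelectionResult:
    """Rank candidate sensors from the eigendecomposition G C' = C' D.

    The top-k eigenvectors are the optimal (dense) measurement
    directions for the energy metric; each state i receives the score
    s_i = sum_j D_j v_j[i]^2 (eigenvalue-weighted squared loadings) and
    states are returned ranked by score.
    """
    G = np.asarray(G, dtype=float)
    scale = max(1.0, np.max(np.abs(G)))
    if np.max(np.abs(G - G.T)) > sym_tol * scale:
        raise ValueError("Gram matrix is not symmetric")
    n = G.shape[0]
    if not 1 <= k <= n:
        raise ValueError("k must lie in 1..n")
    evals, evecs = np.linalg.eigh(0.5 * (G + G.T))
    order = np.argsort(evals)[::-1][:k]
    D = evals[order]
    V = evecs[:, order]
    scores = (V**2) @ np.clip(D, 0.0, None)
    ranking = np.argsort(-scores, kind="stable")
    chosen = [state_names[i] for i in ranking] if state_names \
        else [int(i) for i in ranking]
    return SelectionResult(chosen=chosen, eigenvalues=D, eigenvectors=V,
                           scores=scores, objective=float(np.sum(D)))


def trace_coefficients(model: LinearModel, t0: int, t_end: int) -> np.ndarray:
    """Per-(time, state) visibility coefficients.

    Measuring state j at time i contributes
    w_ij = trace(Phi(t0,i)' e_j e_j' Phi(t0,i)) = ||row j of Phi(t0,i)||^2
    to trace(Go(t0, t_end)); returned as a (t_end-t0+1, n) array.
    """
    if t_end < t0:
        raise ValueError("t_end must be >= t0")
    n = model.n_states
    W = np.empty((t_end - t0 + 1, n))
    Phi = np.eye(n)
    for i in range(t0, t_end + 1):
        W[i - t0] = np.sum(Phi * Phi, axis=1)
        if i < t_end:
            Phi = model.matrix_at(i) @ Phi
    return W


def lp_select_m3(coefficients: np.ndarray,
                 constraints: ConstraintSet | None = None,
                 state_names: Sequence[str] | None = None,
                 tol: float = 1e-9) -> SelectionResult:
    """Maximize M3 = sum_ij delta_ij w_ij by linear programming.

    Relaxed indicators 0 <= delta_ij <= 1 with per-time budget rows
    sum_j delta_ij <= p(i) and, when a cluster map is present,
    at-most-one-gene-per-cluster rows.  With budget constraints only the
    constraint matrix is totally unimodular, so a vertex optimum is
    integral; fractional solutions (possible under cluster rows) are
    rounded largest-delta-first subject to feasibility.
    """
    W = np.asarray(coefficients, dtype=float)
    T, n = W.shape
    constraints = constraints or ConstraintSet()
    names = list(state_names) if state_names else [f"x{j}" for j in range(n)]

    nvar = T * n
    c = -W.ravel()
    bounds = [(0.0, 1.0)] * nvar
    for j, name in enumerate(names):
        if name in constraints.forbidden or j in constraints.forbidden:
            for i in range(T):
                bounds[i * n + j] = (0.0, 0.0)
    rows, rhs = [], []
    for i in range(T):
        p = constraints.budget_at(i, default=n)
        r = np.zeros(nvar)
        r[i * n:(i + 1) * n] = 1.0
        rows.append(r)
        rhs.append(float(p))
    clusters: dict[object, list[int]] = {}
    if constraints.cluster_map:
        for j, name in enumerate(names):
            key = name if name in constraints.cluster_map else j
            if key in constraints.cluster_map:
                clusters.setdefault(constraints.cluster_map[key], []).append(j)
        for members in clusters.values():
            if len(members) < 2:
                continue
            for i in range(T):
                r = np.zeros(nvar)
                r[[i * n + j for j in members]] = 1.0
                rows.append(r)
                rhs.append(1.0)
    res = linprog(c, A_ub=np.array(rows), b_ub=np.array(rhs), bounds=bounds,
                  method="highs",
                  options={"primal_feasibility_tolerance": tol,
                           "dual_feasibility_tolerance": tol})
    if not res.success:
        raise InfeasibleConstraintsError(
            f"linear program failed: {res.message}")
    delta = res.x.reshape(T, n)

    # round largest-delta first, re-checking budget and cluster feasibility
    cmap = constraints.cluster_map or {}
    delta_bin = np.zeros_like(delta)
    chosen: list[list] = []
    for i in range(T):
        p = constraints.budget_at(i, default=n)
        order = np.argsort(-delta[i], kind="stable")
        picked: list[int] = []
        used_clusters: set = set()
        for j in order:
            if delta[i, j] <= tol or len(picked) >= p:
                continue
            key = names[j] if names[j] in cmap else j
            cl = cmap.get(key)
            if cl is not None and cl in used_clusters:
                continue
            picked.append(int(j))
            if cl is not None:
                used_clusters.add(cl)
        delta_bin[i, sorted(picked)] = 1.0
        chosen.append([names[j] for j in sorted(picked)])
    return SelectionResult(
        chosen=chosen,
        objective=float(np.sum(delta * W)),
        delta=delta,
        delta_binary=delta_bin,
        diagnostics={"lp_status": res.status,
                     "rounded_objective": float(np.sum(delta_bin * W))},
    )


def _pick_top(order: Sequence[int], p: int, names: Sequence[str],
              constraints: ConstraintSet) -> list[int]:
    """Greedy heuristic: walk a ranking, keeping the top entries that
    satisfy forbidden/cluster rules, until p sensors are picked."""
    picked: list[int] = []
    chosen_names: list = []
    for j in order:
        if len(picked) >= p:
            break
        if constraints.admissible(names[j], chosen_names):
            picked.append(int(j))
            chosen_names.append(names[j])
    return picked


def dss_schedule(model: LinearModel, method: str = "lp",
                 objective: str = "m3",
                 constraints: ConstraintSet | None = None,
                 data: SnapshotSeries | None = None,
                 t0: int = 0, t_end: int | None = None,
                 rank_tol: float = 1e-6) -> tuple[SensorSchedule, SelectionResult]:
    """Dynamic sensor selection: re-solve the selection problem at every
    time point and emit the resulting time-varying C(t).

    method='eigen' ranks sensors per time from the data Gram matrix
    (energy metric, x(0) taken from ``data``); method='lp' maximizes the
    visibility metric with the linear program; method='greedy' runs a
    per-time greedy on the requested objective.  Constrained selection
    keeps the top-ranked sensors that satisfy the constraints.
    """
    constraints = constraints or ConstraintSet()
    if t_end is None:
        if model.horizon is not None:
            t_end = t0 + model.horizon
        elif data is not None:
            t_end = t0 + data.n_transitions
        else:
            raise ValueError("t_end required for an LTI model without data")
    names = list(model.state_names)
    n = model.n_states
    T = t_end - t0 + 1
    default_budget = 1

    if method == "lp":
        if objective != "m3":
            raise ValueError("the linear program solves the m3 objective")
        W = trace_coefficients(model, t0, t_end)
        cons = constraints if constraints.budget is not None else \
            ConstraintSet(budget=default_budget,
                          cluster_map=constraints.cluster_map,
                          forbidden=constraints.forbidden)
        result = lp_select_m3(W, cons, state_names=names)
        sched = SensorSchedule(delta=result.delta_binary, state_names=names)
        return sched, result

    per_time: list[list[str]] = []
    for i in range(t0, t0 + T):
        p = constraints.budget_at(i - t0, default=default_budget)
        if method == "eigen":
            if objective not in ("m2",):
                raise ValueError("eigen ranking solves the m2 objective")
            if data is None:
                raise ValueError("eigen method needs snapshot data for x(0)")
            X0 = data.values[:, t0:t0 + 1]
            G = build_gram(model, X0, t0, i)
            ranking = rank_sensors_eigen(G, k=min(n, max(p, 1)),
                                         state_names=names)
            order = [names.index(s) for s in ranking.chosen]
            picked = _pick_top(order, p, names, constraints)
        elif method == "greedy":
            Phi = state_transition(model, t0, i)
            if objective == "m3":
                scores = np.sum(Phi * Phi, axis=1)
                order = list(np.argsort(-scores, kind="stable"))
                picked = _pick_top(order, p, names, constraints)
            elif objective == "m2":
                if data is None:
                    raise ValueError("m2 greedy needs snapshot data for x(0)")
                z = Phi @ data.values[:, t0]
                order = list(np.argsort(-(z**2), kind="stable"))
                picked = _pick_top(order, p, names, constraints)
            elif objective == "m1":
                def rank_of(rows: list) -> float:
                    idx = [names.index(r) for r in rows]
                    O = ObsMatrix(Phi[idx, :], source="ltv")
                    return float(metric_rank(O, rank_tol))
                res = greedy_select(rank_of, names, budget=p,
                                    constraints=constraints,
                                    stop_on_no_improvement=False)
                picked = [names.index(s) for s in res.chosen]
            else:
                raise ValueError(f"unknown objective {objective!r}")
        else:
            raise ValueError(f"unknown method {method!r}")
        per_time.append([names[j] for j in picked])
    sched = SensorSchedule(sensors=per_time, state_names=names)
    W = trace_coefficients(model, t0, t_end)
    obj = float(np.sum(sched.delta * W)) if sched.delta is not None else None
    return sched, SelectionResult(chosen=per_time, objective=obj)
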