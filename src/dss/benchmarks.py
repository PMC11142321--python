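"""Nonlinear benchmark systems and simulation-based observability.

Two classic systems exercise the local/empirical observability machinery:

* the Andronov-Hopf normal form, whose supercritical bifurcation at
  ``alpha = 0`` models the quiescence-proliferation transition (stable
  spiral = "dead", limit cycle = "alive");
* a 13-state fission-yeast cell-cycle network in the Novak-Tyson
  tradition (twelve protein/complex states plus cell mass), used for
  sensor-selection studies on a realistically ill-conditioned model.

Local observability at a state x is assessed with the observability
matrix of the linearization: rows C, C J(x), C J(x)^2, ...  Jacobians
are analytic when a system supplies one and central finite differences
otherwise.  Empirical observability Gramians are built purely from
simulated +/- perturbations of the initial state, so they apply to any
nonlinear system without solving Lyapunov equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.linalg

from .metrics import Gramian, ObsMatrix
from .models import SnapshotSeries

__all__ = [
    "NonlinearSystem",
    "EmpiricalGramianConfig",
    "IntegrationBlowupError",
    "andronov_hopf",
    "novak_tyson",
    "integrate_ode",
    "local_observability_matrix",
    "empirical_gramian",
    "output_energy_gramian",
    "hopf_observability_sweep",
    "novak_tyson_trajectory",
    "novak_tyson_state_sample",
    "sample_states",
    "finite_difference_jacobian",
    "complex_step_jacobian",
]


class IntegrationBlowupError(RuntimeError):
    """Raised when a trajectory leaves the finite range; carries the time
    reached before divergence."""

    def __init__(self, t: float):
        self.t = t
        super().__init__(f"integration diverged (non-finite state) at t={t:.6g}")


@dataclass
class NonlinearSystem:
    """Autonomous ODE dx/dt = f(x, theta) with linear readout y = C x."""

    n: int
    vector_field: Callable[[np.ndarray], np.ndarray]
    readout: np.ndarray
    state_names: Sequence[str]
    jacobian: Callable[[np.ndarray], np.ndarray] | None = None
    parameters: dict = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        self.readout = np.atleast_2d(np.asarray(self.readout, dtype=float))
        if self.readout.shape[1] != self.n:
            raise ValueError("readout column count must equal dimension n")
        self.state_names = list(self.state_names)
        if len(self.state_names) != self.n:
            raise ValueError("state_names length must equal dimension n")

    def with_readout(self, C: np.ndarray) -> "NonlinearSystem":
        return NonlinearSystem(self.n, self.vector_field, C,
                               self.state_names, self.jacobian,
                               dict(self.parameters), self.name)


@dataclass
class EmpiricalGramianConfig:
    """Settings for simulation-based Gramians: perturbation size eps,
    number of integration steps (horizon), step dt, and a uniform
    initial-condition sampler (bound b means x0_i ~ U[-b, b])."""

    eps: float = 1e-3
    horizon: int = 1000
    dt: float = 0.05
    ic_bound: float = 1.0
    ic_count: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("perturbation eps must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.horizon < 1:
            raise ValueError("horizon must be a positive step count")

    def sample_initial_conditions(self, n: int) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        return rng.uniform(-self.ic_bound, self.ic_bound,
                           size=(self.ic_count, n))


# ---------------------------------------------------------------------------
# benchmark systems


def andronov_hopf(alpha: float, readout: np.ndarray | None = None
                  ) -> NonlinearSystem:
    """Andronov-Hopf normal form:

        dx1/dt = alpha x1 - x2 - x1 (x1^2 + x2^2)
        dx2/dt = x1 + alpha x2 - x2 (x1^2 + x2^2)

    alpha < 0: globally stable focus at the origin; alpha > 0: stable
    limit cycle of radius sqrt(alpha).  Default sensor measures x1.
    """

    def f(x):
        x1, x2 = x[..., 0], x[..., 1]
        r2 = x1 * x1 + x2 * x2
        return np.stack([alpha * x1 - x2 - x1 * r2,
                         x1 + alpha * x2 - x2 * r2], axis=-1)

    def jac(x):
        x1, x2 = x[0], x[1]
        r2 = x1 * x1 + x2 * x2
        return np.array([
            [alpha - r2 - 2 * x1 * x1, -1 - 2 * x1 * x2],
            [1 - 2 * x1 * x2, alpha - r2 - 2 * x2 * x2],
        ])

    C = np.array([[1.0, 0.0]]) if readout is None else readout
    return NonlinearSystem(2, f, C, ["x1", "x2"], jacobian=jac,
                           parameters={"alpha": alpha}, name="andronov_hopf")


#: Pinned parameter set for the fission-yeast cell-cycle benchmark.
#: Michaelis constants J* are dimensionless fractions; first-order rates
#: are per minute; mu gives a mass doubling time near 140 min.
NOVAK_TYSON_PARAMS: dict[str, float] = {
    "k1": 0.03,      # Cdc13/Cdc2 synthesis (mass-proportional)
    "k2p": 0.03, "k2pp": 1.0,     # Cdc13 proteolysis, basal / UbE-driven
    "k3": 100.0, "kr3": 0.1,      # Rum1-kinase association / dissociation
    "k4p": 0.1, "k4pp": 2.0,      # Rum1 degradation, basal / CDK-driven
    "k5": 0.04,                   # Cig2/Cdc2 synthesis
    "k6p": 0.02, "k6pp": 1.0,     # Cig2 proteolysis, basal / UbE2-driven
    "k7": 0.03, "k8": 0.01,       # Rum1 synthesis / basal turnover
    "kweep": 0.05, "kweepp": 1.0,   # Tyr15 phosphorylation (Wee1)
    "k25p": 0.02, "k25pp": 5.0,     # Tyr15 dephosphorylation (Cdc25)
    "eps_g1": 0.25,  # potency of Cig2 kinase relative to MPF
    "ka": 0.25, "Ja": 0.01, "kb": 0.05, "Jb": 0.01,   # IE activation
    "kc": 1.0, "Jc": 0.01, "kd": 0.1, "Jd": 0.01,     # UbE activation
    "ke": 0.4, "Je": 0.01, "kf": 0.1, "Jf": 0.01,     # UbE2 activation
    "kg": 1.0, "Jg": 0.01, "kh": 1.3, "Jh": 0.01,     # Wee1 switching
    "ki": 1.0, "Ji": 0.01, "kj": 0.1, "Jj": 0.01,     # Cdc25 switching
    "mu": 0.005,     # exponential mass growth
}

NOVAK_TYSON_STATES = ["G2K", "PG2K", "G2R", "PG2R", "G1K", "G1R", "R",
                      "IE", "UbE", "UbE2", "Wee1", "Cdc25", "mass"]

#: Physiological sampling box for random-state observability studies:
#: protein/complex concentrations in [0, 1], switch fractions in [0, 1],
#: mass in [0.5, 2] (arbitrary units, one mass doubling).
NOVAK_TYSON_BOX = [(0.0, 1.0)] * 7 + [(0.0, 1.0)] * 5 + [(0.5, 2.0)]


def novak_tyson(params: dict[str, float] | None = None,
                readout: np.ndarray | None = None) -> NonlinearSystem:
    """13-state fission-yeast cell-cycle network (Novak-Tyson lineage).

    States: the mitotic kinase Cdc13/Cdc2 in its four forms (active G2K,
    Tyr15-phosphorylated PG2K, and their Rum1-bound trimers G2R, PG2R),
    the G1/S kinase Cig2/Cdc2 (G1K) and its trimer (G1R), free Rum1 (R),
    five ultrasensitive regulatory switches (IE, UbE, UbE2, Wee1, Cdc25,
    each a fraction active in [0, 1]), and exponentially growing cell
    mass.  Kinase synthesis scales with mass; proteolysis of Cdc13 and
    Cig2 is driven by the ubiquitination switches; Rum1 binds and
    inhibits both kinases and is itself destabilized by CDK activity;
    Wee1/Cdc25 toggle the inhibitory Tyr15 phosphorylation of MPF.

    The Jacobian is evaluated by complex-step differentiation of the
    (rational, hence analytic) vector field, which is accurate to
    machine precision.
    """
    p = dict(NOVAK_TYSON_PARAMS)
    if params:
        p.update(params)

    def f(x):
        (G2K, PG2K, G2R, PG2R, G1K, G1R, R,
         IE, UbE, UbE2, Wee1, Cdc25, mass) = x
        V2 = p["k2p"] + p["k2pp"] * UbE
        V6 = p["k6p"] + p["k6pp"] * UbE2
        Vwee = p["kweep"] + p["kweepp"] * Wee1
        V25 = p["k25p"] + p["k25pp"] * Cdc25
        cdk = G2K + p["eps_g1"] * G1K
        V4 = p["k4p"] + p["k4pp"] * cdk
        out = np.empty(13, dtype=x.dtype)
        out[0] = (p["k1"] * mass - V2 * G2K - Vwee * G2K + V25 * PG2K
                  - p["k3"] * R * G2K + (p["kr3"] + V4) * G2R)
        out[1] = (Vwee * G2K - V25 * PG2K - V2 * PG2K
                  - p["k3"] * R * PG2K + (p["kr3"] + V4) * PG2R)
        out[2] = (p["k3"] * R * G2K - (p["kr3"] + V4 + V2) * G2R
                  - Vwee * G2R + V25 * PG2R)
        out[3] = (p["k3"] * R * PG2K - (p["kr3"] + V4 + V2) * PG2R
                  + Vwee * G2R - V25 * PG2R)
        out[4] = (p["k5"] - V6 * G1K - p["k3"] * R * G1K
                  + (p["kr3"] + V4) * G1R)
        out[5] = p["k3"] * R * G1K - (p["kr3"] + V4 + V6) * G1R
        out[6] = (p["k7"] - (p["k8"] + V4) * R
                  - p["k3"] * R * (G2K + PG2K + G1K)
                  + p["kr3"] * (G2R + PG2R + G1R)
                  + V2 * (G2R + PG2R) + V6 * G1R)
        out[7] = (p["ka"] * G2K * (1 - IE) / (p["Ja"] + 1 - IE)
                  - p["kb"] * IE / (p["Jb"] + IE))
        out[8] = (p["kc"] * IE * (1 - UbE) / (p["Jc"] + 1 - UbE)
                  - p["kd"] * UbE / (p["Jd"] + UbE))
        out[9] = (p["ke"] * cdk * (1 - UbE2) / (p["Je"] + 1 - UbE2)
                  - p["kf"] * UbE2 / (p["Jf"] + UbE2))
        out[10] = (p["kg"] * (1 - Wee1) / (p["Jg"] + 1 - Wee1)
                   - p["kh"] * G2K * Wee1 / (p["Jh"] + Wee1))
        out[11] = (p["ki"] * G2K * (1 - Cdc25) / (p["Ji"] + 1 - Cdc25)
                   - p["kj"] * Cdc25 / (p["Jj"] + Cdc25))
        out[12] = p["mu"] * mass
        return out

    def jac(x):
        return complex_step_jacobian(f, np.asarray(x, dtype=float))

    C = readout
    if C is None:
        C = np.zeros((1, 13))
        C[0, 0] = 1.0
    return NonlinearSystem(13, f, C, list(NOVAK_TYSON_STATES), jacobian=jac,
                           parameters=p, name="novak_tyson")


# ---------------------------------------------------------------------------
# simulation


def _rk4_batch(f, X: np.ndarray, steps: int, dt: float) -> np.ndarray:
    """Fixed-step RK4 applied to a (batch, n) array of states; returns a
    (steps+1, batch, n) trajectory array."""
    out = np.empty((steps + 1,) + X.shape)
    out[0] = X
    x = X
    for k in range(steps):
        k1 = f(x)
        k2 = f(x + 0.5 * dt * k1)
        k3 = f(x + 0.5 * dt * k2)
        k4 = f(x + dt * k3)
        x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(x)):
            raise IntegrationBlowupError((k + 1) * dt)
        out[k + 1] = x
    return out


def _batched_field(system: NonlinearSystem):
    """Vector field applied along the last axis of a batch array."""
    def fb(X):
        if X.ndim == 1:
            return np.asarray(system.vector_field(X))
        return np.apply_along_axis(
            lambda row: np.asarray(system.vector_field(row)), -1, X)
    # the Hopf field is natively vectorized; use it directly
    try:
        probe = np.zeros((2, system.n))
        out = np.asarray(system.vector_field(probe))
        if out.shape == probe.shape:
            return lambda X: np.asarray(system.vector_field(X))
    except Exception:
        pass
    return fb


def integrate_ode(system: NonlinearSystem, x0: np.ndarray, t_end: float,
                  dt: float) -> SnapshotSeries:
    """Fixed-step 4th-order Runge-Kutta trajectory sampled every dt."""
    x0 = np.asarray(x0, dtype=float).ravel()
    if x0.size != system.n:
        raise ValueError("x0 length does not match system dimension")
    if dt <= 0 or t_end <= 0:
        raise ValueError("t_end and dt must be positive")
    steps = int(round(t_end / dt))
    f = lambda x: np.asarray(system.vector_field(x), dtype=float)
    out = np.empty((steps + 1, system.n))
    out[0] = x0
    x = x0
    for k in range(steps):
        k1 = f(x)
        k2 = f(x + 0.5 * dt * k1)
        k3 = f(x + 0.5 * dt * k2)
        k4 = f(x + dt * k3)
        x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(x)):
            raise IntegrationBlowupError((k + 1) * dt)
        out[k + 1] = x
    times = np.arange(steps + 1) * dt
    return SnapshotSeries(out.T, system.state_names, times)


# ---------------------------------------------------------------------------
# Jacobians


def finite_difference_jacobian(f, x: np.ndarray, rel_step: float = 1e-6
                               ) -> np.ndarray:
    """Central-difference Jacobian with step rel_step * (1 + |x_i|)."""
    x = np.asarray(x, dtype=float)
    f0 = np.asarray(f(x), dtype=float)
    J = np.empty((f0.size, x.size))
    for i in range(x.size):
        h = rel_step * (1.0 + abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        J[:, i] = (np.asarray(f(xp)) - np.asarray(f(xm))) / (2 * h)
    return J


def complex_step_jacobian(f, x: np.ndarray, h: float = 1e-20) -> np.ndarray:
    """Machine-precision Jacobian of an analytic vector field via the
    complex-step trick Im(f(x + i h e_k)) / h."""
    x = np.asarray(x, dtype=float)
    n = x.size
    f0 = np.asarray(f(x.astype(complex)))
    J = np.empty((f0.size, n))
    for k in range(n):
        xc = x.astype(complex)
        xc[k] += 1j * h
        J[:, k] = np.imag(np.asarray(f(xc))) / h
    return J


# ---------------------------------------------------------------------------
# local observability and empirical Gramians


def local_observability_matrix(system: NonlinearSystem, x: np.ndarray,
                               order: int, max_rows: int = 10000,
                               jacobian: np.ndarray | None = None,
                               sample_interval: float | None = None
                               ) -> ObsMatrix:
    """Observability matrix of the linearization at x.

    With J = df/dx evaluated at x, the rows are the blocks
    C, C J, C J^2, ..., C J^(order-1): the gradients of the iterated
    Lie derivatives of the readout along f, propagated through the
    Jacobian (exact for linear systems and at equilibria; the
    first-order local approximation elsewhere).  The Jacobian is taken
    from the system when supplied, else by central finite differences.

    When ``sample_interval`` is given, the blocks use the sampled-time
    propagator Ad = expm(J * sample_interval) instead of J itself:
    the observability matrix of the system observed at that sampling
    interval.  The continuous stack mixes row scales as ||J||^k, which
    swamps effective-rank comparisons for stiff networks; the sampled
    form keeps blocks commensurate and is the recommended mode for
    effective-rank studies.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    C = system.readout
    if order * C.shape[0] > max_rows:
        raise ValueError(
            f"order {order} would create more than {max_rows} rows")
    x = np.asarray(x, dtype=float).ravel()
    if jacobian is not None:
        J = np.asarray(jacobian, dtype=float)
    elif system.jacobian is not None:
        J = np.asarray(system.jacobian(x), dtype=float)
    else:
        J = finite_difference_jacobian(system.vector_field, x)
    if sample_interval is not None:
        if sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        J = scipy.linalg.expm(J * sample_interval)
    rows = [C]
    for _ in range(order - 1):
        rows.append(rows[-1] @ J)
    return ObsMatrix(np.vstack(rows), block_count=order,
                     source="local-nonlinear")


def empirical_gramian(system: NonlinearSystem, config: EmpiricalGramianConfig,
                      x0: np.ndarray) -> Gramian:
    """Empirical observability Gramian from +/- eps perturbations.

    For each state direction e_i, two trajectories start at
    x0 +/- eps e_i; with output differences
    d_i(t) = y(+i, t) - y(-i, t) the Gramian is

        Go_ij = 1/(4 eps^2) * sum_t d_i(t)' d_j(t) * dt

    (left-endpoint quadrature).  Symmetric PSD by construction.
    """
    x0 = np.asarray(x0, dtype=float).ravel()
    if x0.size != system.n:
        raise ValueError("x0 length does not match system dimension")
    n, eps = system.n, config.eps
    starts = np.vstack([x0 + eps * np.eye(n), x0 - eps * np.eye(n)])
    f = _batched_field(system)
    traj = _rk4_batch(f, starts, config.horizon, config.dt)
    # outputs: (time, 2n, p)
    Y = traj @ system.readout.T
    D = Y[:, :n, :] - Y[:, n:, :]          # (time, n, p) differences
    # sum over time of D(t) D(t)' in the sensor-contracted sense
    Go = np.einsum("tip,tjp->ij", D[:-1], D[:-1]) * config.dt
    Go /= 4.0 * eps * eps
    return Gramian(Go, "empirical", horizon=(0.0, config.horizon * config.dt))


def output_energy_gramian(system: NonlinearSystem, x0: np.ndarray,
                          horizon: int, dt: float) -> Gramian:
    """Data-driven output Gramian of a single simulation:

        Go = sum_t y(t) y(t)' dt,   y(t) = C x(t),

    a p-by-p matrix whose trace is the measured signal energy of the
    trajectory launched at x0.  Unlike the perturbation-based
    ``empirical_gramian`` (which measures sensitivity to the initial
    state), this construction quantifies how much signal the chosen
    sensors actually collect from a given initial condition -- the
    natural graded measure when comparing dynamical regimes.
    """
    x0 = np.asarray(x0, dtype=float).ravel()
    if x0.size != system.n:
        raise ValueError("x0 length does not match system dimension")
    f = _batched_field(system)
    traj = _rk4_batch(f, x0[None, :], horizon, dt)
    Y = traj[:, 0, :] @ system.readout.T      # (time, p)
    Go = Y[:-1].T @ Y[:-1] * dt
    return Gramian(Go, "empirical-output",
                   horizon=(0.0, horizon * dt))


def hopf_observability_sweep(alphas, bounds=(1.0, 2.0, 4.0),
                             ic_count: int = 8, horizon: int = 40000,
                             dt: float = 0.05, seed: int = 0) -> list[dict]:
    """Observability of the Andronov-Hopf oscillator across its
    bifurcation, measuring y = x1.

    For each alpha, initial conditions are drawn uniformly from the
    boxes +/-b for each bound b, and the visibility M3 = trace of the
    output-energy Gramian is recorded per initial condition.  The
    horizon (default 2000 time units, hundreds of cycle periods) lets
    the steady-state behavior dominate the transient.  Returns one row
    per alpha with the per-IC M3 samples and their summary statistics.
    """
    rows = []
    for j, alpha in enumerate(alphas):
        system = andronov_hopf(alpha)
        f = _batched_field(system)
        samples = []
        for b in bounds:
            rng = np.random.default_rng(seed + 1000 * j)
            X0 = rng.uniform(-b, b, size=(ic_count, system.n))
            traj = _rk4_batch(f, X0, horizon, dt)
            Y = traj @ system.readout.T                      # (t, ic, p)
            samples.append(np.sum(Y[:-1] ** 2, axis=(0, 2)) * dt)
        m3 = np.concatenate(samples)
        rows.append({
            "alpha": float(alpha),
            "m3": m3,
            "m3_mean": float(np.mean(m3)),
            "m3_var": float(np.var(m3, ddof=1)),
            "m3_log10_var": float(np.var(np.log10(m3), ddof=1)),
            "m3_cv": float(np.std(m3, ddof=1) / np.mean(m3)),
        })
    return rows


#: Default initial condition for cell-cycle simulations: low kinase and
#: complex levels, Wee1 on, unit mass.
NOVAK_TYSON_X0 = np.array([0.05, 0.05, 0.05, 0.05, 0.05, 0.05, 0.2,
                           0.1, 0.1, 0.1, 0.9, 0.1, 1.0])


def novak_tyson_trajectory(system: NonlinearSystem, x0: np.ndarray,
                           t_end: float, dt: float = 0.005,
                           division_threshold: float = 0.2,
                           mitosis_threshold: float = 0.4) -> SnapshotSeries:
    """Cell-cycle trajectory with division: when the mitotic kinase G2K
    falls back below ``division_threshold`` after having exceeded
    ``mitosis_threshold`` (mitotic exit), cell mass is halved.  Keeps
    trajectories on a bounded periodic attractor instead of growing
    without bound."""
    f = lambda x: np.asarray(system.vector_field(x), dtype=float)
    steps = int(round(t_end / dt))
    out = np.empty((steps + 1, system.n))
    x = np.asarray(x0, dtype=float).copy()
    out[0] = x
    in_mitosis = False
    g2k, mass = 0, system.n - 1
    for k in range(steps):
        k1 = f(x)
        k2 = f(x + 0.5 * dt * k1)
        k3 = f(x + 0.5 * dt * k2)
        k4 = f(x + dt * k3)
        x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(x)):
            raise IntegrationBlowupError((k + 1) * dt)
        if x[g2k] > mitosis_threshold:
            in_mitosis = True
        elif in_mitosis and x[g2k] < division_threshold:
            x[mass] *= 0.5
            in_mitosis = False
        out[k + 1] = x
    return SnapshotSeries(out.T, system.state_names,
                          np.arange(steps + 1) * dt)


def novak_tyson_state_sample(count: int, seed: int,
                             system: NonlinearSystem | None = None,
                             t_end: float = 1200.0, dt: float = 0.005,
                             burn_in_fraction: float = 0.25) -> np.ndarray:
    """Random simulated cell-cycle states: one long dividing trajectory
    from the standard initial condition, burn-in discarded, ``count``
    time points drawn uniformly (seeded).  Rows are states."""
    if system is None:
        system = novak_tyson()
    traj = novak_tyson_trajectory(system, NOVAK_TYSON_X0, t_end, dt)
    v = traj.values
    rng = np.random.default_rng(seed)
    lo = int(burn_in_fraction * v.shape[1])
    idx = rng.choice(np.arange(lo, v.shape[1]), size=count, replace=False)
    return v[:, np.sort(idx)].T


def sample_states(box: Sequence[tuple[float, float]], count: int,
                  seed: int) -> np.ndarray:
    """Uniform random states from a per-coordinate box; rows are states."""
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])
    return rng.uniform(lo, hi, size=(count, len(box)))
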