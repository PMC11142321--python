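"""Observability matrices, Gramians, and the graded metrics M1/M2/M3.

For a linear system x(t+1) = A x(t), y(t) = C x(t) the observability
matrix is O = [C; CA; ...; CA^(b-1)] and the Kalman condition says the
system is observable iff rank(O) = n.  Because biological models are
poorly conditioned, rank is graded through three measures:

    M1 = effective rank of O          (observable directions)
    M2 = x0' Go x0                    (output energy of an initial state)
    M3 = trace(Go)                    (average visibility of directions)

where Go is an observability Gramian obtained from a Lyapunov equation
(stable LTI), a finite-horizon sum (LTV), or simulation (empirical).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg

from .models import LinearModel, state_transition

__all__ = [
    "ObsMatrix",
    "Gramian",
    "SensorSchedule",
    "observability_matrix",
    "ltv_observability_matrix",
    "metric_rank",
    "gramian_lyapunov",
    "gramian_ltv",
    "metric_energy",
    "metric_visibility",
    "kalman_pbh_tests",
    "UnstableSystemError",
]


class UnstableSystemError(ValueError):
    """Raised when an infinite-horizon Gramian is requested for an
    unstable system."""


@dataclass
class ObsMatrix:
    """A stacked observability matrix with its singular values."""

    O: np.ndarray
    block_count: int = 1
    source: str = "lti"  # lti | ltv | local-nonlinear
    singular_values: np.ndarray = field(default=None)  # type: ignore

    def __post_init__(self) -> None:
        self.O = np.atleast_2d(np.asarray(self.O, dtype=float))
        if self.singular_values is None:
            self.singular_values = np.linalg.svd(self.O, compute_uv=False)
        self.singular_values = np.asarray(self.singular_values, dtype=float)

    @property
    def n_states(self) -> int:
        return self.O.shape[1]


@dataclass
class Gramian:
    """Symmetric PSD observability Gramian with a provenance tag."""

    Go: np.ndarray
    method: str  # lyapunov-continuous | lyapunov-discrete | finite-horizon | ltv | empirical
    horizon: tuple | None = None

    def __post_init__(self) -> None:
        self.Go = np.asarray(self.Go, dtype=float)
        if self.Go.ndim != 2 or self.Go.shape[0] != self.Go.shape[1]:
            raise ValueError("Gramian must be square")
        asym = np.max(np.abs(self.Go - self.Go.T)) if self.Go.size else 0.0
        scale = max(1.0, np.max(np.abs(self.Go))) if self.Go.size else 1.0
        if asym > 1e-8 * scale:
            raise ValueError("Gramian is not symmetric")
        self.Go = 0.5 * (self.Go + self.Go.T)

    @property
    def n_states(self) -> int:
        return self.Go.shape[0]


class SensorSchedule:
    """Per-time measurement matrices C(t), or a relaxed indicator matrix.

    Construct from explicit matrices (``matrices=[C0, C1, ...]``), from a
    T-by-n indicator ``delta`` with entries in [0, 1], or from per-time
    lists of sensor indices/names (``sensors=[[...], ...]``).
    """

    def __init__(self, matrices: Sequence[np.ndarray] | None = None,
                 delta: np.ndarray | None = None,
                 sensors: Sequence[Sequence[int]] | None = None,
                 n_states: int | None = None,
                 state_names: Sequence[str] | None = None):
        if sum(x is not None for x in (matrices, delta, sensors)) != 1:
            raise ValueError("provide exactly one of matrices/delta/sensors")
        self.state_names = list(state_names) if state_names else None
        if matrices is not None:
            self.matrices = [np.atleast_2d(np.asarray(C, dtype=float))
                             for C in matrices]
            ncols = {C.shape[1] for C in self.matrices}
            if len(ncols) != 1:
                raise ValueError("all C(t) must share a column count")
            self._n = ncols.pop()
        elif delta is not None:
            delta = np.asarray(delta, dtype=float)
            if delta.ndim != 2:
                raise ValueError("delta must be a T-by-n matrix")
            if np.any(delta < -1e-12) or np.any(delta > 1 + 1e-12):
                raise ValueError("delta entries must lie in [0, 1]")
            self._n = delta.shape[1]
            self.matrices = []
            for row in delta:
                idx = np.flatnonzero(row > 0.5)
                C = np.zeros((len(idx), self._n))
                C[np.arange(len(idx)), idx] = 1.0
                self.matrices.append(C)
            self.delta = delta
        else:
            if n_states is None and state_names is None:
                raise ValueError("sensors form needs n_states or state_names")
            self._n = n_states if n_states is not None else len(state_names)
            self.matrices = []
            rows = []
            for per_t in sensors:
                idx = [self._sensor_index(s) for s in per_t]
                if len(set(idx)) != len(idx):
                    raise ValueError("duplicate sensor within a time step")
                C = np.zeros((len(idx), self._n))
                C[np.arange(len(idx)), idx] = 1.0
                self.matrices.append(C)
                r = np.zeros(self._n)
                r[idx] = 1.0
                rows.append(r)
            self.delta = np.array(rows) if rows else np.zeros((0, self._n))
        if not hasattr(self, "delta"):
            self.delta = None

    def _sensor_index(self, s) -> int:
        if isinstance(s, (int, np.integer)):
            return int(s)
        if self.state_names is None:
            raise ValueError("state_names required to resolve sensor names")
        return self.state_names.index(s)

    @property
    def n_states(self) -> int:
        return self._n

    def __len__(self) -> int:
        return len(self.matrices)

    def matrix_at(self, t: int) -> np.ndarray:
        if not 0 <= t < len(self.matrices):
            raise ValueError(f"schedule has no measurement matrix at t={t}")
        return self.matrices[t]

    def sensor_sets(self) -> list[list[str]]:
        """Per-time sensor identifiers (names when known, else indices)."""
        out = []
        for C in self.matrices:
            idx = [int(np.argmax(np.abs(row))) for row in C]
            if self.state_names:
                out.append([self.state_names[i] for i in idx])
            else:
                out.append(idx)
        return out

    @classmethod
    def constant(cls, C: np.ndarray, horizon: int,
                 state_names: Sequence[str] | None = None) -> "SensorSchedule":
        C = np.atleast_2d(np.asarray(C, dtype=float))
        return cls(matrices=[C] * horizon, state_names=state_names)


# ---------------------------------------------------------------------------
# observability matrices


def observability_matrix(A: np.ndarray, C: np.ndarray,
                         blocks: int | None = None) -> ObsMatrix:
    """O = [C; CA; ...; CA^(blocks-1)]; blocks defaults to n
    (Cayley-Hamilton bound)."""
    A = np.asarray(A, dtype=float)
    C = np.atleast_2d(np.asarray(C, dtype=float))
    n = A.shape[0]
    if A.shape != (n, n) or C.shape[1] != n:
        raise ValueError("incompatible A/C dimensions")
    if blocks is None:
        blocks = n
    if blocks < 1:
        raise ValueError("blocks must be positive")
    rows = [C]
    for _ in range(blocks - 1):
        rows.append(rows[-1] @ A)
    return ObsMatrix(np.vstack(rows), block_count=blocks, source="lti")


def ltv_observability_matrix(model: LinearModel, schedule: SensorSchedule,
                             t0: int, t: int) -> ObsMatrix:
    """Stacked blocks C(k) Phi(t0, k) for k = t0..t."""
    if t < t0:
        raise ValueError("t must be >= t0")
    if len(schedule) <= t - t0:
        raise ValueError("schedule shorter than requested horizon")
    if schedule.n_states != model.n_states:
        raise ValueError("schedule/model dimension mismatch")
    blocks = []
    Phi = np.eye(model.n_states)
    for k in range(t0, t + 1):
        blocks.append(schedule.matrix_at(k - t0) @ Phi)
        if k < t:
            Phi = model.matrix_at(k) @ Phi
    return ObsMatrix(np.vstack(blocks), block_count=t - t0 + 1, source="ltv")


def metric_rank(O: ObsMatrix, rel_tol: float = 1e-6) -> int:
    """M1: number of singular values with sigma_k / sigma_1 > rel_tol."""
    if not 0 < rel_tol < 1:
        raise ValueError("rel_tol must lie in (0, 1)")
    s = O.singular_values
    if s.size == 0 or s[0] == 0:
        return 0
    return int(np.sum(s / s[0] > rel_tol))


# ---------------------------------------------------------------------------
# Gramians


def gramian_lyapunov(A: np.ndarray, C: np.ndarray,
                     time_kind: str = "discrete") -> Gramian:
    """Infinite-horizon Gramian from the Lyapunov equation.

    continuous:  A' Go + Go A = -C'C   (requires Re(eig A) < 0)
    discrete:    A' Go A - Go = -C'C   (requires spectral radius < 1)
    """
    A = np.asarray(A, dtype=float)
    C = np.atleast_2d(np.asarray(C, dtype=float))
    eig = np.linalg.eigvals(A)
    if time_kind == "continuous":
        bad = eig[np.real(eig) >= 0]
        if bad.size:
            raise UnstableSystemError(
                f"eigenvalue {bad[0]:.6g} has non-negative real part; "
                "the continuous Lyapunov Gramian does not exist"
            )
        Go = scipy.linalg.solve_continuous_lyapunov(A.T, -C.T @ C)
        return Gramian(Go, "lyapunov-continuous")
    if time_kind == "discrete":
        bad = eig[np.abs(eig) >= 1]
        if bad.size:
            raise UnstableSystemError(
                f"eigenvalue {bad[0]:.6g} has modulus >= 1; the discrete "
                "Lyapunov Gramian does not exist"
            )
        Go = scipy.linalg.solve_discrete_lyapunov(A.T, C.T @ C)
        return Gramian(Go, "lyapunov-discrete")
    raise ValueError("time_kind must be 'continuous' or 'discrete'")


def gramian_ltv(model: LinearModel, schedule: SensorSchedule,
                t0: int, t: int) -> Gramian:
    """Finite-horizon Gramian
    Go(t0,t) = sum_{k=t0}^{t} Phi(t0,k)' C(k)' C(k) Phi(t0,k).

    Identical to O'O for the matching ``ltv_observability_matrix``.
    """
    O = ltv_observability_matrix(model, schedule, t0, t)
    return Gramian(O.O.T @ O.O, "ltv", horizon=(t0, t))


def gramian_finite_horizon(A: np.ndarray, C: np.ndarray,
                           horizon: int) -> Gramian:
    """Finite-horizon LTI Gramian sum_{k=0}^{horizon} (A^k)' C'C A^k."""
    A = np.asarray(A, dtype=float)
    C = np.atleast_2d(np.asarray(C, dtype=float))
    Go = np.zeros((A.shape[0], A.shape[0]))
    M = C.copy()
    for _ in range(horizon + 1):
        Go += M.T @ M
        M = M @ A
    return Gramian(Go, "finite-horizon", horizon=(0, horizon))


def metric_energy(Go: Gramian | np.ndarray, x0: np.ndarray) -> float:
    """M2 = x0' Go x0: output energy released by initial state x0."""
    G = Go.Go if isinstance(Go, Gramian) else np.asarray(Go, dtype=float)
    x0 = np.asarray(x0, dtype=float).ravel()
    if x0.size != G.shape[0]:
        raise ValueError("x0 length does not match the Gramian dimension")
    return float(x0 @ G @ x0)


def metric_visibility(Go: Gramian | np.ndarray) -> float:
    """M3 = trace(Go): aggregate visibility of all state directions."""
    G = Go.Go if isinstance(Go, Gramian) else np.asarray(Go, dtype=float)
    return float(np.trace(G))


# ---------------------------------------------------------------------------
# binary observability tests


@dataclass
class ObservabilityReport:
    rank: int
    n_states: int
    kalman_observable: bool
    pbh_observable: bool
    pbh_per_eigenvalue: list  # (eigenvalue, rank, passes)


def kalman_pbh_tests(A: np.ndarray, C: np.ndarray) -> ObservabilityReport:
    """Kalman rank test on the full observability matrix and the
    Popov-Belevitch-Hautus test rank [A - lambda I; C] = n for every
    eigenvalue lambda of A."""
    A = np.asarray(A, dtype=float)
    C = np.atleast_2d(np.asarray(C, dtype=float))
    n = A.shape[0]
    O = observability_matrix(A, C, blocks=n)
    kalman_rank = int(np.linalg.matrix_rank(O.O))
    per_eig = []
    for lam in np.linalg.eigvals(A):
        stacked = np.vstack([A - lam * np.eye(n), C.astype(complex)])
        r = int(np.linalg.matrix_rank(stacked))
        per_eig.append((complex(lam), r, r == n))
    return ObservabilityReport(
        rank=kalman_rank,
        n_states=n,
        kalman_observable=kalman_rank == n,
        pbh_observable=all(ok for _, _, ok in per_eig),
        pbh_per_eigenvalue=per_eig,
    )
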