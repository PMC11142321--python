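"""Data-driven linear models of gene-expression dynamics.

Snapshot time series (genes x time) are fit with discrete-time linear
propagators in the style of dynamic mode decomposition: a single
time-invariant matrix ``A`` (LTI) or one matrix per transition,
``x(t+1) = A(t) x(t)`` (LTV).  The state-transition matrix

    Phi(t0, t) = A(t-1) ... A(t0+1) A(t0),        Phi(t0, t0) = I

propagates states between two times and is the backbone of every
finite-horizon observability computation downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SnapshotSeries",
    "LinearModel",
    "fit_lti",
    "fit_ltv",
    "state_transition",
    "simulate",
    "read_expression",
    "write_expression",
    "model_to_json",
    "model_from_json",
]


@dataclass
class SnapshotSeries:
    """A genes-by-time matrix of system states.

    ``values`` has one row per state (gene) and one column per time point,
    so a series with T transitions holds T+1 columns.
    """

    values: np.ndarray
    state_names: Sequence[str]
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D states-by-time matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("snapshot values contain non-finite entries")
        self.state_names = list(self.state_names)
        if len(self.state_names) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.state_names)} state names for "
                f"{self.values.shape[0]} rows"
            )
        if self.times is None:
            self.times = np.arange(self.values.shape[1], dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (self.values.shape[1],):
            raise ValueError("times length must equal the number of columns")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_states(self) -> int:
        return self.values.shape[0]

    @property
    def n_transitions(self) -> int:
        """Number of snapshot-to-snapshot transitions, T."""
        return self.values.shape[1] - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.state_names, columns=list(self.times)
        )


@dataclass
class LinearModel:
    """Discrete-time linear propagator, time-invariant or time-varying.

    ``matrices`` is an (n, n) array for an LTI model or a (T, n, n) stack
    ``A(0..T-1)`` for an LTV model.
    """

    kind: str
    matrices: np.ndarray
    state_names: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("lti", "ltv"):
            raise ValueError("kind must be 'lti' or 'ltv'")
        self.matrices = np.asarray(self.matrices, dtype=float)
        expected_ndim = 2 if self.kind == "lti" else 3
        if self.matrices.ndim != expected_ndim:
            raise ValueError(
                f"{self.kind} model needs a {expected_ndim}-D matrix array"
            )
        if self.matrices.shape[-1] != self.matrices.shape[-2]:
            raise ValueError("transition matrices must be square")
        if not np.all(np.isfinite(self.matrices)):
            raise ValueError("transition matrices contain non-finite entries")
        if not self.state_names:
            self.state_names = [f"x{i}" for i in range(self.n_states)]
        self.state_names = list(self.state_names)
        if len(self.state_names) != self.n_states:
            raise ValueError("state_names length must equal model dimension")

    @property
    def n_states(self) -> int:
        return self.matrices.shape[-1]

    @property
    def horizon(self) -> int | None:
        """Number of available transitions (None = unlimited, LTI)."""
        return None if self.kind == "lti" else self.matrices.shape[0]

    def matrix_at(self, t: int) -> np.ndarray:
        """Transition matrix applied between times t and t+1."""
        if self.kind == "lti":
            return self.matrices
        if not 0 <= t < self.matrices.shape[0]:
            raise ValueError(f"time index {t} outside model horizon")
        return self.matrices[t]


def _regularized_lstsq(Xp: np.ndarray, X: np.ndarray, ridge: float,
                       rank: int | None = None) -> np.ndarray:
    """Minimum-norm solution A of A X = Xp, optionally ridge-regularized
    and/or projected onto the leading `rank` left singular vectors of X."""
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    if rank is not None:
        U, s, Vt = U[:, :rank], s[:rank], Vt[:rank]
    if ridge == 0:
        tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
        inv = np.where(s > tol, s / (s**2 + 1e-300), 0.0)
    else:
        inv = s / (s**2 + ridge)
    return Xp @ Vt.T @ np.diag(inv) @ U.T


def fit_lti(data: SnapshotSeries, ridge: float = 0.0,
            rank: int | None = None) -> LinearModel:
    """Fit a single propagator A minimizing ||X' - A X|| over all snapshot
    pairs (exact DMD on the raw states).

    Parameters
    ----------
    ridge : Tikhonov regularization on the pseudoinverse of X (0 = plain
        minimum-norm least squares).
    rank : optional SVD truncation of X before inversion (projected DMD);
        default keeps all modes.
    """
    if data.n_transitions < 1:
        raise ValueError("need at least 2 time points to fit a model")
    X = data.values[:, :-1]
    Xp = data.values[:, 1:]
    A = _regularized_lstsq(Xp, X, ridge, rank)
    return LinearModel("lti", A, data.state_names)


def fit_ltv(data: SnapshotSeries, window: int = 1, ridge: float = 0.0,
            rank: int | None = None) -> LinearModel:
    """Fit one propagator per transition from a sliding snapshot window.

    ``A(t)`` is the minimum-norm least-squares map from the window of
    snapshots ending at column t to the same window shifted forward one
    step.  ``window=1`` gives the classic rank-one per-step fit;
    ``window=T`` reproduces the LTI fit at every step.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    T = data.n_transitions
    if T < 1:
        raise ValueError("need at least 2 time points to fit a model")
    if window > T:
        raise ValueError(f"window {window} exceeds {T} available transitions")
    mats = []
    for t in range(T):
        # window of `window` transitions ending at t, shifted right when
        # t is too early to have a full history
        lo = min(max(0, t - window + 1), T - window)
        X = data.values[:, lo:lo + window]
        Xp = data.values[:, lo + 1:lo + window + 1]
        mats.append(_regularized_lstsq(Xp, X, ridge, rank))
    return LinearModel("ltv", np.stack(mats), data.state_names)


def state_transition(model: LinearModel, t0: int, t: int) -> np.ndarray:
    """State-transition matrix Phi(t0, t) = A(t-1)...A(t0), with
    Phi(t0, t0) = I (empty product)."""
    if t < t0:
        raise ValueError(f"t={t} precedes t0={t0}")
    n = model.n_states
    if model.kind == "lti":
        return np.linalg.matrix_power(model.matrices, t - t0)
    if t - t0 > 0 and t - 1 >= model.matrices.shape[0]:
        raise ValueError(f"t={t} outside model horizon {model.horizon}")
    Phi = np.eye(n)
    for k in range(t0, t):
        Phi = model.matrices[k] @ Phi
    return Phi


def simulate(model: LinearModel, x0: np.ndarray, steps: int,
             t0: int = 0) -> SnapshotSeries:
    """Iterate the model forward: column t holds Phi(t0, t0+t) x0."""
    x0 = np.asarray(x0, dtype=float).ravel()
    if x0.size != model.n_states:
        raise ValueError(
            f"x0 has length {x0.size}, model dimension is {model.n_states}"
        )
    if steps < 1:
        raise ValueError("steps must be positive")
    cols = [x0]
    x = x0
    for t in range(t0, t0 + steps):
        x = model.matrix_at(t) @ x if model.kind == "ltv" else model.matrices @ x
        cols.append(x)
    values = np.column_stack(cols)
    return SnapshotSeries(values, model.state_names,
                          np.arange(t0, t0 + steps + 1, dtype=float))


# ---------------------------------------------------------------------------
# file formats


def read_expression(path: str | Path) -> SnapshotSeries:
    """Read a genes-by-time CSV/TSV: first column gene ids, header = times."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    try:
        times = np.asarray([float(c) for c in df.columns])
    except ValueError:
        times = np.arange(df.shape[1], dtype=float)
    return SnapshotSeries(df.to_numpy(dtype=float),
                          [str(g) for g in df.index], times)


def write_expression(series: SnapshotSeries, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    series.to_frame().to_csv(path, sep=sep, float_format="%.17g")


def model_to_json(model: LinearModel, path: str | Path | None = None) -> dict:
    """Serialize a model to a JSON-compatible dict (row-major matrices)."""
    payload = {
        "schema": "dss-linear-model/1",
        "kind": model.kind,
        "n": model.n_states,
        "state_names": list(model.state_names),
        "matrices": model.matrices.tolist(),
    }
    if path is not None:
        Path(path).write_text(json.dumps(payload))
    return payload


def model_from_json(source: str | Path | dict) -> LinearModel:
    if isinstance(source, dict):
        payload = source
    else:
        payload = json.loads(Path(source).read_text())
    if payload.get("schema") != "dss-linear-model/1":
        raise ValueError("unrecognized model schema")
    return LinearModel(payload["kind"], np.asarray(payload["matrices"]),
                       payload["state_names"])
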