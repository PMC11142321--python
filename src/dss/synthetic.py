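"""Seeded generators for every synthetic fixture the toolkit needs.

These stand in for the kinds of data the selection and estimation
workflows target -- time-series transcriptomics, regime-switching
dynamics, chromatin contact maps, and multichannel recordings -- with
ground truth always returned alongside the data so recovery tests need
no external input.  Every generator is bit-reproducible under
(spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constraints_hic import ContactMatrix
from .models import LinearModel, SnapshotSeries, simulate

__all__ = [
    "GeneratorSpec",
    "random_stable_lti",
    "regime_switch_ltv",
    "expression_like",
    "planted_contacts",
    "multichannel_recording",
]


@dataclass
class GeneratorSpec:
    """Shared knobs for the synthetic generators.

    kind : lti | ltv-switch | expression | contacts | multichannel
    n / horizon : dimension and number of transitions T
    noise : scale of the multiplicative log-normal noise (expression)
        or additive noise (multichannel)
    spectral_radius : target spectral radius for stable systems (in
        (0, 1] for stability)
    switch_times : regime boundaries for ltv-switch
    """

    kind: str = "lti"
    n: int = 5
    horizon: int = 10
    noise: float = 0.0
    spectral_radius: float = 0.9
    switch_times: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.spectral_radius <= 1 + 1e-12:
            raise ValueError("spectral-radius bound must lie in (0, 1]")


def random_stable_lti(spec: GeneratorSpec) -> LinearModel:
    """Random dense A rescaled to exactly the requested spectral radius."""
    if spec.n < 1:
        raise ValueError("dimension must be >= 1")
    rng = np.random.default_rng(spec.seed)
    A = rng.standard_normal((spec.n, spec.n))
    rho = np.max(np.abs(np.linalg.eigvals(A)))
    if rho == 0:  # nilpotent draw; shift to give a nonzero radius
        A = A + np.eye(spec.n)
        rho = np.max(np.abs(np.linalg.eigvals(A)))
    A *= spec.spectral_radius / rho
    return LinearModel("lti", A)


def _spike_leak_matrix(n: int, favored: int, rho_dom: float,
                       rho_sub: float) -> np.ndarray:
    """Contraction whose range concentrates on one state: a dominant
    rank-one spike along e_favored plus a small identity leak.  Rows of
    any product ending in this matrix are dominated by row `favored`,
    which pins the per-time visibility ordering."""
    v = np.full(n, 1.0 / np.sqrt(n))
    A = rho_sub * np.eye(n)
    A[favored, :] += rho_dom * v
    return A


def regime_switch_ltv(spec: GeneratorSpec,
                      favored_states: tuple[int, ...] = (0, 2),
                      rho_dom: float = 0.9, rho_sub: float = 0.05
                      ) -> tuple[LinearModel, np.ndarray]:
    """Piecewise-constant LTV system whose dominant observable state
    provably switches between regimes.

    ``switch_times`` split 0..T-1 into consecutive regimes; regime r
    uses a spike-plus-leak contraction oriented along
    ``favored_states[r]``, so the visibility coefficient w(t, j) is
    maximized by the favored state of the active regime.  Returns the
    model and the per-transition regime labels.
    """
    T = spec.horizon
    boundaries = [0, *sorted(spec.switch_times), T]
    if any(not 0 <= s <= T for s in spec.switch_times):
        raise ValueError("switch times must lie within the horizon")
    n_regimes = len(boundaries) - 1
    if len(favored_states) < n_regimes:
        raise ValueError("need one favored state per regime")
    mats = np.empty((T, spec.n, spec.n))
    labels = np.empty(T, dtype=int)
    for r in range(n_regimes):
        A = _spike_leak_matrix(spec.n, favored_states[r], rho_dom, rho_sub)
        for t in range(boundaries[r], boundaries[r + 1]):
            mats[t] = A
            labels[t] = r
    return LinearModel("ltv", mats), labels


def expression_like(spec: GeneratorSpec, model: LinearModel,
                    x0: np.ndarray | None = None
                    ) -> tuple[SnapshotSeries, SnapshotSeries]:
    """Non-negative expression-like trajectories with multiplicative
    log-normal noise.

    The model is simulated from a positive initial state, each entry is
    multiplied by exp(N(0, noise^2)), and the result is clipped at 0.
    Returns (noisy series, noise-free truth).
    """
    if model.horizon is not None and model.horizon < spec.horizon:
        raise ValueError("model horizon shorter than requested series")
    rng = np.random.default_rng(spec.seed)
    if x0 is None:
        x0 = rng.uniform(0.5, 2.0, size=model.n_states)
    clean = simulate(model, x0, spec.horizon)
    if spec.noise > 0:
        factors = np.exp(rng.normal(0.0, spec.noise, size=clean.values.shape))
        noisy_values = np.clip(clean.values * factors, 0.0, None)
    else:
        noisy_values = clean.values.copy()
    noisy = SnapshotSeries(noisy_values, clean.state_names, clean.times)
    return noisy, clean


def planted_contacts(block_sizes: tuple[int, ...], within: float = 10.0,
                     between: float = 0.0, noise_frac: float = 0.0,
                     jitter: float = 0.1, seed: int = 0
                     ) -> tuple[ContactMatrix, np.ndarray]:
    """Block-structured contact matrix with known cluster labels.

    Within-block contacts average ``within``, between-block ``between``
    (with +/-``jitter`` relative spread).  ``noise_frac`` adds a
    random-ligation background: every pair receives an extra
    exponential contact with mean ``noise_frac * within``, emulating
    the spurious inter-locus reads of real Hi-C maps.  Returns the
    matrix and the planted labels.
    """
    rng = np.random.default_rng(seed)
    n = int(np.sum(block_sizes))
    labels = np.concatenate([np.full(sz, b) for b, sz in
                             enumerate(block_sizes)])
    same = labels[:, None] == labels[None, :]
    means = np.where(same, within, between).astype(float)
    scale = 1.0 + jitter * rng.uniform(-1.0, 1.0, size=(n, n))
    C = np.clip(means * scale, 0.0, None)
    if noise_frac > 0:
        C = C + rng.exponential(noise_frac * within, size=(n, n))
    C = np.triu(C, 1)
    C = C + C.T
    genes = [f"g{i}" for i in range(n)]
    return ContactMatrix(C, genes), labels


def multichannel_recording(spec: GeneratorSpec, model: LinearModel,
                           x0: np.ndarray | None = None
                           ) -> tuple[SnapshotSeries, SnapshotSeries]:
    """Zero-mean multichannel traces (neuron/EEG-like) with additive
    Gaussian noise; returns (noisy, truth)."""
    if model.horizon is not None and model.horizon < spec.horizon:
        raise ValueError("model horizon shorter than requested series")
    rng = np.random.default_rng(spec.seed)
    if x0 is None:
        x0 = rng.standard_normal(model.n_states)
    clean = simulate(model, x0, spec.horizon)
    noisy_values = clean.values + rng.normal(
        0.0, spec.noise, size=clean.values.shape)
    return SnapshotSeries(noisy_values, clean.state_names,
                          clean.times), clean
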