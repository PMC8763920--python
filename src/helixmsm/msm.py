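"""Markov state model estimation and validation.

From discrete state trajectories: sliding-window transition counts at lag
tau, ergodic trimming to the strongly connected set with the most counts,
maximum-likelihood transition-matrix estimation (row normalization of the
counts; optionally of the symmetrized counts for a reversible model),
implied timescales t_i = -tau / ln(lam_i), stationary distributions,
lag-time scans, GMRQ cross-validation for the number of states, and
trajectory bootstrap for uncertainty estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .cluster import assign, kcenters_fit

__all__ = [
    "CountMatrix",
    "MSMModel",
    "GMRQResult",
    "BootstrapEnsemble",
    "count_transitions",
    "largest_connected_set",
    "estimate_T",
    "implied_timescales",
    "lag_scan",
    "gmrq_cross_validate",
    "bootstrap_models",
    "fit_msm",
]


@dataclass
class CountMatrix:
    counts: np.ndarray  # (k, k) non-negative integers
    lag_frames: int
    lag_time: float
    mode: str = "sliding"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")


@dataclass
class MSMModel:
    T: np.ndarray             # (k, k) row-stochastic
    lag_frames: int
    lag_time: float
    eigenvalues: np.ndarray   # descending by modulus, lam_1 = 1
    pi: np.ndarray            # stationary distribution
    active: np.ndarray        # original state index of each model state
    reversible: bool
    counts: Optional[np.ndarray] = None

    @property
    def n_states(self) -> int:
        return self.T.shape[0]


@dataclass
class GMRQResult:
    k_candidates: List[int]
    train_scores: np.ndarray  # (n_candidates, n_folds)
    test_scores: np.ndarray   # (n_candidates, n_folds)
    selected_k: int


@dataclass
class BootstrapEnsemble:
    """Per-replicate downstream quantities with their mean and SEM."""

    n_boot: int
    seed: int
    replicates: List[dict]
    mean: dict = field(default_factory=dict)
    sem: dict = field(default_factory=dict)

    def summarize(self) -> None:
        keys = self.replicates[0].keys()
        n = len(self.replicates)
        for key in keys:
            vals = np.array([r[key] for r in self.replicates], dtype=float)
            self.mean[key] = vals.mean(axis=0)
            self.sem[key] = (vals.std(axis=0, ddof=1) / np.sqrt(n)
                             if n > 1 else np.zeros_like(vals.mean(axis=0)))


def count_transitions(
    label_sequences: Sequence[np.ndarray],
    lag_frames: int,
    n_states: Optional[int] = None,
    frame_dt: float = 1.0,
) -> CountMatrix:
    """Sliding-window transition counts: one count per (t, t + tau) pair
    within each trajectory, never across trajectory boundaries."""
    if lag_frames < 1:
        raise ValueError("lag must be >= 1 frame")
    seqs = [np.asarray(s, dtype=np.intp) for s in label_sequences]
    usable = [s for s in seqs if s.shape[0] > lag_frames]
    if not usable:
        raise ValueError(
            f"no trajectory longer than lag {lag_frames} frames"
        )
    if n_states is None:
        n_states = 1 + max(int(s.max()) for s in seqs)
    counts = np.zeros((n_states, n_states), dtype=np.int64)
    for s in usable:
        np.add.at(counts, (s[:-lag_frames], s[lag_frames:]), 1)
    return CountMatrix(counts=counts, lag_frames=lag_frames,
                       lag_time=lag_frames * frame_dt)


def largest_connected_set(cm: CountMatrix):
    """Strongly connected component carrying the most transition counts.

    Returns (active, trimmed) where ``active`` maps model states to original
    state indices and ``trimmed`` is the restricted count matrix.
    """
    counts = cm.counts
    if counts.sum() == 0:
        raise ValueError("count matrix has no transitions")
    graph = sp.csr_matrix((counts > 0).astype(np.int8))
    n_comp, labels = connected_components(graph, directed=True,
                                          connection="strong")
    best, best_weight = 0, -1
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        weight = counts[np.ix_(members, members)].sum()
        if weight > best_weight:
            best, best_weight = comp, weight
    active = np.flatnonzero(labels == best)
    if best_weight == 0:
        raise ValueError("largest strongly connected set has no transitions")
    trimmed = counts[np.ix_(active, active)]
    return active, CountMatrix(counts=trimmed, lag_frames=cm.lag_frames,
                               lag_time=cm.lag_time, mode=cm.mode)


def _eig_sorted(T: np.ndarray):
    lam, vec = np.linalg.eig(T)
    order = np.argsort(-np.abs(lam))
    return lam[order], vec[:, order]


def estimate_T(
    cm: CountMatrix,
    reversible: bool = False,
    active: Optional[np.ndarray] = None,
) -> MSMModel:
    """Maximum-likelihood transition matrix from trimmed, connected counts.

    Non-reversible (default): T_ij = c_ij / sum_j c_ij, the ML estimator of
    an unconstrained Markov chain.  Reversible: row normalization of the
    symmetrized counts (C + C^T)/2, which enforces detailed balance.
    """
    counts = np.asarray(cm.counts, dtype=np.float64)
    if reversible:
        counts = (counts + counts.T) / 2.0
    rows = counts.sum(axis=1)
    if (rows == 0).any():
        raise ValueError(
            "zero-count row in trimmed counts; run largest_connected_set "
            "first"
        )
    T = counts / rows[:, None]
    lam, _ = _eig_sorted(T)
    # stationary distribution: leading left eigenvector
    lam_l, vec_l = np.linalg.eig(T.T)
    i1 = np.argmin(np.abs(lam_l - 1.0))
    pi = np.real(vec_l[:, i1])
    pi = np.abs(pi)
    pi /= pi.sum()
    if active is None:
        active = np.arange(T.shape[0])
    return MSMModel(T=T, lag_frames=cm.lag_frames, lag_time=cm.lag_time,
                    eigenvalues=lam, pi=pi, active=np.asarray(active),
                    reversible=reversible, counts=cm.counts)


def implied_timescales(model: MSMModel, n_timescales: Optional[int] = None
                       ) -> np.ndarray:
    """Relaxation timescales t_i = -tau / ln(lam_i) for the non-stationary
    eigenvalues with 0 < lam_i < 1 (in the time units of the model's lag).

    Eigenvalues <= 0 or complex have no defined relaxation time at this lag
    and are excluded.  The unit eigenvalue is skipped.
    """
    lam = model.eigenvalues[1:]  # skip lam_1 = 1
    real = lam[np.abs(lam.imag) < 1e-10].real
    ok = real[(real > 0) & (real < 1.0 - 1e-12)]
    ts = -model.lag_time / np.log(ok)
    ts = np.sort(ts)[::-1]
    if n_timescales is not None:
        out = np.full(n_timescales, np.nan)
        out[:min(n_timescales, ts.size)] = ts[:n_timescales]
        return out
    return ts


def fit_msm(
    label_sequences: Sequence[np.ndarray],
    lag_frames: int,
    n_states: Optional[int] = None,
    frame_dt: float = 1.0,
    reversible: bool = False,
) -> MSMModel:
    """count -> trim -> estimate in one step."""
    cm = count_transitions(label_sequences, lag_frames, n_states=n_states,
                           frame_dt=frame_dt)
    active, trimmed = largest_connected_set(cm)
    return estimate_T(trimmed, reversible=reversible, active=active)


def lag_scan(
    label_sequences: Sequence[np.ndarray],
    lags_frames: Sequence[int],
    frame_dt: float = 1.0,
    n_timescales: int = 3,
    reversible: bool = False,
) -> pd.DataFrame:
    """Implied-timescale-versus-lag table for plateau inspection.

    One row per lag with columns lag_frames, lag_time and t_1..t_n (slowest
    first, in time units)."""
    lags = sorted(set(int(l) for l in lags_frames))
    if not lags or lags[0] < 1:
        raise ValueError("lags must be positive integers")
    rows = []
    for lag in lags:
        model = fit_msm(label_sequences, lag, frame_dt=frame_dt,
                        reversible=reversible)
        ts = implied_timescales(model, n_timescales)
        row = {"lag_frames": lag, "lag_time": lag * frame_dt}
        for i in range(n_timescales):
            row[f"t_{i + 1}"] = ts[i]
        rows.append(row)
    return pd.DataFrame(rows)


def _gmrq_score(V: np.ndarray, c0: np.ndarray, ct: np.ndarray) -> float:
    """Sum of generalized Rayleigh quotients of the columns of V under the
    test correlation pair: trace[(V' C0 V)^-1 (V' Ct V)]."""
    a = V.T @ c0 @ V
    b = V.T @ ct @ V
    return float(np.trace(np.linalg.solve(a, b)))


def _correlation_matrices(seqs, lag_frames, n_states):
    """State-indicator correlation matrices C0 (symmetrized one-step
    occupancies) and Ct (symmetrized transition frequencies)."""
    counts = np.zeros((n_states, n_states))
    for s in seqs:
        if s.shape[0] > lag_frames:
            np.add.at(counts, (s[:-lag_frames], s[lag_frames:]), 1)
    total = counts.sum()
    if total == 0:
        raise ValueError("no transition pairs at this lag")
    ct = (counts + counts.T) / (2.0 * total)
    c0 = np.diag((counts.sum(axis=0) + counts.sum(axis=1)) / (2.0 * total))
    return c0, ct


def gmrq_cross_validate(
    projected_trajs: Sequence[np.ndarray],
    k_candidates: Sequence[int],
    lag_frames: int,
    n_folds: int = 5,
    n_timescales: int = 3,
    seed: int = 0,
    reversible: bool = False,
) -> GMRQResult:
    """Select the number of k-centers states by cross-validated GMRQ.

    Trajectories are split into folds; per fold and candidate k, k-centers
    and an MSM are fit on the training trajectories and the summed
    generalized Rayleigh quotient of the leading ``n_timescales + 1`` train
    eigenvectors is evaluated with the held-out correlation matrices.  The
    selected k maximizes the mean test score.
    """
    trajs = [np.asarray(x, dtype=np.float64) for x in projected_trajs]
    if len(trajs) < 2:
        raise ValueError("need at least 2 trajectories for cross-validation")
    n_folds = min(n_folds, len(trajs))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(trajs))
    folds = [order[f::n_folds] for f in range(n_folds)]

    k_candidates = list(k_candidates)
    train_scores = np.full((len(k_candidates), n_folds), np.nan)
    test_scores = np.full((len(k_candidates), n_folds), np.nan)

    for f, test_idx in enumerate(folds):
        test_set = set(int(i) for i in test_idx)
        train = [t for i, t in enumerate(trajs) if i not in test_set]
        test = [t for i, t in enumerate(trajs) if i in test_set]
        all_train = np.concatenate(train, axis=0)
        for ki, k in enumerate(k_candidates):
            try:
                cmod = kcenters_fit(all_train, k, seed=seed)
                train_labels = [assign(t, cmod) for t in train]
                test_labels = [assign(t, cmod) for t in test]
                model = fit_msm(train_labels, lag_frames, n_states=k)
                # right eigenvectors of the train model on its active set
                lam, vec = _eig_sorted(model.T)
                m = min(n_timescales + 1, model.n_states)
                V_active = np.real(vec[:, :m])
                V = np.zeros((k, m))
                V[model.active] = V_active
                c0_tr, ct_tr = _correlation_matrices(train_labels,
                                                     lag_frames, k)
                c0_te, ct_te = _correlation_matrices(test_labels,
                                                     lag_frames, k)
                # score on the shared support to keep V'C0V invertible
                sup = np.flatnonzero(np.diag(c0_te)[model.active] > 0)
                shared = model.active[sup]
                if shared.size < m:
                    raise ValueError("test fold covers too few train states")
                train_scores[ki, f] = _gmrq_score(V, c0_tr, ct_tr)
                test_scores[ki, f] = _gmrq_score(
                    V[shared],
                    c0_te[np.ix_(shared, shared)],
                    ct_te[np.ix_(shared, shared)],
                )
            except (ValueError, np.linalg.LinAlgError) as exc:
                warnings.warn(
                    f"GMRQ fold {f}, k={k} skipped: {exc}", RuntimeWarning
                )
    mean_test = np.nanmean(test_scores, axis=1)
    selected_k = k_candidates[int(np.nanargmax(mean_test))]
    return GMRQResult(k_candidates=k_candidates, train_scores=train_scores,
                      test_scores=test_scores, selected_k=selected_k)


def bootstrap_models(
    label_sequences: Sequence[np.ndarray],
    lag_frames: int,
    n_boot: int = 5,
    seed: int = 0,
    frame_dt: float = 1.0,
    reversible: bool = False,
    n_timescales: int = 3,
    quantity_fn: Optional[Callable[[MSMModel, List[int]], dict]] = None,
    max_retries: int = 10,
) -> BootstrapEnsemble:
    """Trajectory bootstrap: each replicate draws ``len(label_sequences)``
    trajectories with replacement, refits the MSM and records downstream
    quantities (implied timescales, stationary entropy, and anything the
    caller's ``quantity_fn(model, chosen_indices)`` adds).

    Replicates whose resample is not connected are redrawn (at most
    ``max_retries`` times each).  Bit-reproducible for a fixed seed.
    """
    if len(label_sequences) < 2:
        raise ValueError("need at least 2 trajectories to bootstrap")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    n = len(label_sequences)
    replicates = []
    for _ in range(n_boot):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, size=n).tolist()
            try:
                model = fit_msm([label_sequences[i] for i in idx],
                                lag_frames, frame_dt=frame_dt,
                                reversible=reversible)
                break
            except ValueError as exc:
                if attempt == max_retries:
                    raise RuntimeError(
                        f"bootstrap replicate failed {max_retries} redraws: "
                        f"{exc}"
                    )
                warnings.warn(f"bootstrap resample redrawn: {exc}",
                              RuntimeWarning)
        quantities = {
            "timescales": implied_timescales(model, n_timescales),
            "pi_entropy": float(-(model.pi * np.log(model.pi + 1e-300)).sum()),
        }
        if quantity_fn is not None:
            quantities.update(quantity_fn(model, idx))
        replicates.append(quantities)
    ens = BootstrapEnsemble(n_boot=n_boot, seed=seed, replicates=replicates)
    ens.summarize()
    return ens
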