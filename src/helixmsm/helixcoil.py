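"""Kinetic Zimm-Bragg helix-coil model with an optional side-chain staple.

Each residue of a peptide is either helical (1) or coil (0).  A configuration
``x`` has statistical weight

    w(x) = sigma^(number of helical runs) * s^(number of helical residues)
           * J^(1 if both stapled residues are helical else 0)

i.e. the classic Zimm-Bragg measure (nucleation weight ``sigma``, propagation
weight ``s``) augmented with a multiplicative bonus ``J >= 1`` rewarding
configurations in which both residues of an i,i+4 (or i,i+7) staple are
helical.  Dynamics are single-residue Glauber flips satisfying detailed
balance with respect to ``w``, so the long-run distribution is exactly the
Zimm-Bragg equilibrium and the relaxation kinetics are nucleation-limited for
small ``sigma`` (two-basin helix/coil interconversion).

The module also provides exact oracles for this model: per-residue
equilibrium helix probabilities (transfer matrix / exhaustive enumeration)
and the exact relaxation time of the flip kernel (sparse eigensolve of the
2^n-state single-flip chain).  These are the ground truths the downstream
MSM pipeline is validated against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "HelixCoilParams",
    "StateTrajectory",
    "simulate_helix_coil",
    "equilibrium_helicity_exact",
    "relaxation_time_exact",
    "log_weight",
]

#: largest chain length for which exhaustive 2^n enumeration is attempted
ENUMERATION_LIMIT = 20

#: largest chain length for which the exact 2^n-state relaxation eigensolve
#: is attempted (sparse, ~n*2^n nonzeros)
RELAXATION_LIMIT = 18


@dataclass(frozen=True)
class HelixCoilParams:
    """Parameters of the kinetic Zimm-Bragg model.

    Parameters
    ----------
    n_res : int
        Number of residues (>= 1).
    sigma : float
        Nucleation weight (> 0).  Small values make helix nucleation rare and
        the kinetics two-basin / nucleation-limited.
    s : float
        Propagation weight (> 0).  s > 1 favours helix.
    staple : (int, int), optional
        0-based residue pair (i, j), i < j, crosslinked by the staple.
    staple_bonus : float
        Multiplicative weight J >= 1 applied when both stapled residues are
        helical.  J = 1 means no staple effect.
    flip_attempts_per_frame : int
        Glauber flip attempts between saved frames; controls the effective
        saving interval of the sampler.
    frame_dt : float
        Time per saved frame in nominal nanoseconds.
    seed : int
        Default RNG seed for :func:`simulate_helix_coil`.
    """

    n_res: int
    sigma: float
    s: float
    staple: Optional[Tuple[int, int]] = None
    staple_bonus: float = 1.0
    flip_attempts_per_frame: int = 15
    frame_dt: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_res < 1:
            raise ValueError(f"n_res must be >= 1, got {self.n_res}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not self.s > 0:
            raise ValueError(f"s must be > 0, got {self.s}")
        if self.staple_bonus < 1.0:
            raise ValueError(
                f"staple_bonus must be >= 1, got {self.staple_bonus}"
            )
        if self.flip_attempts_per_frame < 1:
            raise ValueError("flip_attempts_per_frame must be >= 1")
        if self.frame_dt <= 0:
            raise ValueError("frame_dt must be > 0")
        if self.staple is not None:
            i, j = self.staple
            if not (0 <= i < j < self.n_res):
                raise ValueError(
                    f"staple {self.staple} must satisfy 0 <= i < j < n_res"
                )


@dataclass
class StateTrajectory:
    """Binary helix/coil trajectory: ``states[f, r]`` is 1 if residue ``r``
    is helical in frame ``f``."""

    states: np.ndarray  # (frames, n_res) uint8
    frame_dt: float
    params: HelixCoilParams
    seed: int

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.uint8)
        if self.states.ndim != 2 or self.states.shape[0] < 1:
            raise ValueError("states must be a non-empty (frames, n_res) matrix")
        if not np.isin(self.states, (0, 1)).all():
            raise ValueError("states entries must be 0 or 1")

    @property
    def n_frames(self) -> int:
        return self.states.shape[0]

    @property
    def n_res(self) -> int:
        return self.states.shape[1]

    def helicity_per_frame(self) -> np.ndarray:
        """Fraction of helical residues in each frame."""
        return self.states.mean(axis=1)


def log_weight(x: np.ndarray, params: HelixCoilParams) -> float:
    """Log Zimm-Bragg weight of a single configuration ``x`` (0/1 vector)."""
    x = np.asarray(x, dtype=np.int8)
    if x.shape != (params.n_res,):
        raise ValueError("configuration length does not match n_res")
    n_h = int(x.sum())
    # a run starts wherever a helical residue has a coil (or chain-start)
    # left neighbour
    runs = int(x[0]) + int(((x[1:] == 1) & (x[:-1] == 0)).sum())
    lw = runs * math.log(params.sigma) + n_h * math.log(params.s)
    if params.staple is not None and params.staple_bonus > 1.0:
        i, j = params.staple
        if x[i] and x[j]:
            lw += math.log(params.staple_bonus)
    return lw


def _delta_log_weight(x, i, params, log_sigma, log_s, log_j):
    """Log-weight change for flipping site i, as fast scalar arithmetic.

    For a coil->helix flip the run count changes by 1 - (number of helical
    neighbours); helix->coil is the exact negative with the same neighbour
    count, so detailed balance holds by construction.
    """
    n = params.n_res
    left = x[i - 1] if i > 0 else 0
    right = x[i + 1] if i < n - 1 else 0
    d = (1 - left - right) * log_sigma + log_s
    if log_j != 0.0 and params.staple is not None:
        a, b = params.staple
        if i == a and x[b]:
            d += log_j
        elif i == b and x[a]:
            d += log_j
    return d if x[i] == 0 else -d


def simulate_helix_coil(
    params: HelixCoilParams,
    n_frames: int,
    seed: Optional[int] = None,
) -> StateTrajectory:
    """Sample a helix-coil trajectory by Glauber single-flip Monte Carlo.

    Between saved frames, ``params.flip_attempts_per_frame`` flips are
    attempted at uniformly chosen residues; an attempted flip of residue i is
    accepted with the heat-bath probability w'/(w + w') = 1/(1 + e^{-dlogw}),
    which satisfies detailed balance with respect to the Zimm-Bragg measure.
    The initial configuration is drawn with each residue independently
    helical with probability 1/2 (callers discard an equilibration segment).

    Parameters
    ----------
    params : HelixCoilParams
    n_frames : int
        Number of saved frames (>= 1).
    seed : int, optional
        Overrides ``params.seed``.
    """
    if n_frames < 1:
        raise ValueError(f"n_frames must be >= 1, got {n_frames}")
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    n = params.n_res
    m = params.flip_attempts_per_frame

    log_sigma = math.log(params.sigma)
    log_s = math.log(params.s)
    log_j = math.log(params.staple_bonus) if params.staple is not None else 0.0

    x = rng.integers(0, 2, size=n).astype(np.int8).tolist()
    states = np.empty((n_frames, n), dtype=np.uint8)

    # pre-draw randomness in bulk; the inner loop is plain-Python scalar work
    total = n_frames * m
    sites = rng.integers(0, n, size=total)
    unifs = rng.random(total)
    exp = math.exp
    idx = 0
    for f in range(n_frames):
        for _ in range(m):
            i = int(sites[idx])
            u = unifs[idx]
            idx += 1
            d = _delta_log_weight(x, i, params, log_sigma, log_s, log_j)
            # Glauber acceptance 1/(1+e^{-d}); guard the exp overflow
            if d >= 0:
                acc = 1.0 / (1.0 + exp(-d)) if d < 40 else 1.0
            else:
                acc = exp(d) / (1.0 + exp(d)) if d > -40 else 0.0
            if u < acc:
                x[i] = 1 - x[i]
        states[f] = x
    return StateTrajectory(states=states, frame_dt=params.frame_dt,
                           params=params, seed=seed)


def _enumerate_configs(n: int) -> np.ndarray:
    """All 2^n configurations as an (2^n, n) 0/1 int8 matrix (bit order:
    column r is residue r)."""
    idx = np.arange(2 ** n, dtype=np.uint32)
    return ((idx[:, None] >> np.arange(n, dtype=np.uint32)) & 1).astype(np.int8)


def _log_weights_all(bits: np.ndarray, params: HelixCoilParams) -> np.ndarray:
    """Vectorized log weights of every configuration in ``bits``."""
    n_h = bits.sum(axis=1)
    runs = bits[:, 0].astype(np.int64) + (
        (bits[:, 1:] == 1) & (bits[:, :-1] == 0)
    ).sum(axis=1)
    lw = runs * math.log(params.sigma) + n_h * math.log(params.s)
    if params.staple is not None and params.staple_bonus > 1.0:
        i, j = params.staple
        both = (bits[:, i] == 1) & (bits[:, j] == 1)
        lw = lw + both * math.log(params.staple_bonus)
    return lw


class ExactMethodUnsupportedError(ValueError):
    """Raised when an exact oracle is requested beyond its size limit."""


def equilibrium_helicity_exact(params: HelixCoilParams) -> np.ndarray:
    """Exact per-residue equilibrium helix probability.

    Uses exhaustive 2^n enumeration for ``n_res <= ENUMERATION_LIMIT``; for
    longer unstapled chains a transfer-matrix forward/backward pass is used.
    A stapled chain (J > 1) beyond the enumeration limit is unsupported: the
    staple couples non-adjacent residues and breaks the nearest-neighbour
    transfer structure.

    Returns
    -------
    ndarray of shape (n_res,) with P(residue r helical).
    """
    n = params.n_res
    stapled = params.staple is not None and params.staple_bonus > 1.0
    if n <= ENUMERATION_LIMIT:
        bits = _enumerate_configs(n)
        lw = _log_weights_all(bits, params)
        lw -= lw.max()
        w = np.exp(lw)
        z = w.sum()
        return (w[:, None] * bits).sum(axis=0) / z
    if stapled:
        raise ExactMethodUnsupportedError(
            f"exact stapled-chain helicity requires n_res <= "
            f"{ENUMERATION_LIMIT}, got {n}"
        )
    return _transfer_matrix_helicity(params)


def _transfer_matrix_helicity(params: HelixCoilParams) -> np.ndarray:
    """Per-residue helix probability of the unstapled Zimm-Bragg chain via
    forward/backward transfer vectors.

    Pairwise factor u(prev, cur): u(., 0) = 1, u(0, 1) = sigma*s (run start),
    u(1, 1) = s; the virtual residue before the chain is coil.
    """
    n = params.n_res
    sig, s = params.sigma, params.s
    u = np.array([[1.0, sig * s], [1.0, s]])
    fwd = np.empty((n, 2))
    fwd[0] = u[0]  # chain start: previous state is coil
    for r in range(1, n):
        fwd[r] = fwd[r - 1] @ u
        fwd[r] /= fwd[r].sum()  # running normalization for stability
    bwd = np.empty((n, 2))
    bwd[n - 1] = 1.0
    for r in range(n - 2, -1, -1):
        bwd[r] = u @ bwd[r + 1]
        bwd[r] /= bwd[r].sum()
    prob = fwd * bwd
    return prob[:, 1] / prob.sum(axis=1)


def _attempt_kernel(params: HelixCoilParams):
    """Sparse transition matrix of one Glauber flip attempt over all 2^n
    configurations, plus the stationary log-weights."""
    n = params.n_res
    n_states = 2 ** n
    bits = _enumerate_configs(n)
    lw = _log_weights_all(bits, params)

    log_sigma = math.log(params.sigma)
    log_s = math.log(params.s)
    log_j = math.log(params.staple_bonus) if params.staple is not None else 0.0

    rows, cols, vals = [], [], []
    diag = np.ones(n_states)
    states_idx = np.arange(n_states, dtype=np.int64)
    for i in range(n):
        xi = bits[:, i].astype(np.float64)
        left = bits[:, i - 1] if i > 0 else np.zeros(n_states, dtype=np.int8)
        right = bits[:, i + 1] if i < n - 1 else np.zeros(n_states, dtype=np.int8)
        d = (1.0 - left - right) * log_sigma + log_s
        if log_j != 0.0 and params.staple is not None:
            a, b = params.staple
            if i == a:
                d = d + log_j * bits[:, b]
            elif i == b:
                d = d + log_j * bits[:, a]
        d = (1.0 - 2.0 * xi) * d  # sign for helix->coil flips
        acc = 1.0 / (1.0 + np.exp(-np.clip(d, -40, 40)))
        p = acc / n  # site chosen uniformly
        partner = states_idx ^ (1 << i)
        rows.append(states_idx)
        cols.append(partner)
        vals.append(p)
        diag -= p
    rows.append(states_idx)
    cols.append(states_idx)
    vals.append(diag)
    P = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_states, n_states),
    ).tocsr()
    return P, lw


def relaxation_time_exact(params: HelixCoilParams) -> float:
    """Exact slowest relaxation time of the saved-frame chain, in the time
    units of ``frame_dt``.

    Builds the full 2^n-state single-flip Glauber kernel, symmetrizes it with
    the known stationary distribution, and computes its second-largest
    eigenvalue ``lam2``.  One saved frame composes ``m`` attempts, so the
    relaxation time is t = -frame_dt / (m * ln lam2).
    """
    n = params.n_res
    if n > RELAXATION_LIMIT:
        raise ExactMethodUnsupportedError(
            f"exact relaxation time requires n_res <= {RELAXATION_LIMIT}, "
            f"got {n}"
        )
    P, lw = _attempt_kernel(params)
    lw = lw - lw.max()
    pi = np.exp(lw)
    pi /= pi.sum()
    sq = np.sqrt(pi)
    # similarity transform D^(1/2) P D^(-1/2) is symmetric for a reversible P
    S = sp.diags(sq) @ P @ sp.diags(1.0 / sq)
    S = (S + S.T) / 2.0  # clean up round-off asymmetry
    if S.shape[0] <= 512:
        lams = np.linalg.eigvalsh(S.toarray())
        lam2 = lams[-2]
    else:
        lams = spla.eigsh(S, k=2, which="LA", return_eigenvectors=False)
        lam2 = np.sort(lams)[0]
    if not (0 < lam2 < 1):
        raise RuntimeError(f"unexpected second eigenvalue {lam2}")
    m = params.flip_attempts_per_frame
    return -params.frame_dt / (m * math.log(lam2))


def stationary_distribution_exact(params: HelixCoilParams):
    """Exact stationary distribution over all 2^n configurations, with the
    configuration bit matrix.  Enumeration-limited like the other oracles."""
    n = params.n_res
    if n > ENUMERATION_LIMIT:
        raise ExactMethodUnsupportedError(
            f"exact enumeration requires n_res <= {ENUMERATION_LIMIT}"
        )
    bits = _enumerate_configs(n)
    lw = _log_weights_all(bits, params)
    lw -= lw.max()
    w = np.exp(lw)
    return w / w.sum(), bits
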