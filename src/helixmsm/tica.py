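"""Time-lagged independent component analysis (tICA).

Given mean-free features f(t), tICA maximizes the time-lagged
autocorrelation <a|C(dt)|a> subject to the unit-variance constraint
<a|C(0)|a> = 1, where C(dt)_ij = <f_i(t) f_j(t + dt)> is the (symmetrized)
time-lagged correlation matrix.  The solutions are the leading eigenvectors
of the generalized symmetric eigenproblem

    C(dt) a = lam (C(0) + eps I) a,

with a small ridge eps making the whitening well-posed when features are
collinear.  Correlations are pooled over all (t, t + dt) pairs within each
trajectory, never across trajectory boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import scipy.linalg

from .featurize import FeatureMatrix

__all__ = ["TICAModel", "estimate_correlations", "solve_tica", "project",
           "fit_tica"]


@dataclass
class TICAModel:
    lag_frames: int
    lag_time: float
    mean: np.ndarray          # (n_features,)
    c0: np.ndarray            # (n_features, n_features) instantaneous cov
    ct: np.ndarray            # symmetrized time-lagged correlation
    eigenvalues: np.ndarray   # (n_components,) descending
    components: np.ndarray    # (n_components, n_features)
    n_components: int
    eps: float

    @property
    def timescales(self) -> np.ndarray:
        """Relaxation timescales -lag/ln(lam) for eigenvalues in (0, 1)."""
        lam = self.eigenvalues
        out = np.full(lam.shape, np.nan)
        ok = (lam > 0) & (lam < 1)
        out[ok] = -self.lag_time / np.log(lam[ok])
        return out


def estimate_correlations(
    feature_matrices: Sequence[FeatureMatrix],
    lag_frames: int,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled mean-free covariance C(0) and symmetrized time-lagged
    correlation C(dt) over a list of trajectories.

    The mean is the pooled average over every frame of every trajectory;
    C(0) averages outer products over all frames, C(dt) over all valid
    (t, t + dt) pairs within each trajectory, then symmetrized (C + C^T)/2.
    """
    if lag_frames < 1:
        raise ValueError("lag must be >= 1 frame")
    mats = [np.asarray(fm.values, dtype=np.float64) for fm in feature_matrices]
    if not mats:
        raise ValueError("no feature matrices given")
    for i, x in enumerate(mats):
        if x.shape[0] <= lag_frames:
            raise ValueError(
                f"trajectory {i} has {x.shape[0]} frames, need more than "
                f"lag {lag_frames}"
            )
    n_features = mats[0].shape[1]
    total = sum(x.shape[0] for x in mats)
    mean = sum(x.sum(axis=0) for x in mats) / total

    c0 = np.zeros((n_features, n_features))
    ct = np.zeros((n_features, n_features))
    n_pairs = 0
    for x in mats:
        xc = x - mean
        c0 += xc.T @ xc
        a, b = xc[:-lag_frames], xc[lag_frames:]
        ct += a.T @ b
        n_pairs += a.shape[0]
    c0 /= total
    ct /= n_pairs
    ct = (ct + ct.T) / 2.0
    return mean, c0, ct


def solve_tica(
    c0: np.ndarray,
    ct: np.ndarray,
    n_components: int,
    eps: Optional[float] = None,
    lag_frames: int = 1,
    lag_time: float = 1.0,
    mean: Optional[np.ndarray] = None,
) -> TICAModel:
    """Solve the regularized generalized eigenproblem and keep the top
    ``n_components`` eigenpairs.

    Components are normalized to unit variance <a|C0 + eps I|a> = 1 with a
    deterministic sign convention (the largest-magnitude loading of each
    component is positive).  ``eps`` defaults to 1e-6 * trace(C0)/n.
    """
    c0 = np.asarray(c0, dtype=np.float64)
    ct = np.asarray(ct, dtype=np.float64)
    if c0.shape != ct.shape or c0.shape[0] != c0.shape[1]:
        raise ValueError("C0 and C(dt) must be square and of equal shape")
    n = c0.shape[0]
    if not 1 <= n_components <= n:
        raise ValueError("n_components must be in [1, n_features]")
    if eps is None:
        eps = 1e-6 * np.trace(c0) / n
    c0r = c0 + eps * np.eye(n)
    try:
        scipy.linalg.cholesky(c0r)
    except scipy.linalg.LinAlgError:
        raise ValueError(
            "C0 + eps*I is not positive definite; increase eps"
        )
    lam, vec = scipy.linalg.eigh(ct, c0r)  # ascending, B-orthonormal
    order = np.argsort(lam)[::-1][:n_components]
    lam = lam[order]
    comp = vec[:, order].T
    # sign convention: largest |loading| positive
    for i in range(comp.shape[0]):
        j = np.argmax(np.abs(comp[i]))
        if comp[i, j] < 0:
            comp[i] = -comp[i]
    if mean is None:
        mean = np.zeros(n)
    return TICAModel(lag_frames=lag_frames, lag_time=lag_time,
                     mean=np.asarray(mean, dtype=np.float64), c0=c0, ct=ct,
                     eigenvalues=lam, components=comp,
                     n_components=n_components, eps=eps)


def fit_tica(
    feature_matrices: Sequence[FeatureMatrix],
    lag_frames: int,
    n_components: int = 4,
    eps: Optional[float] = None,
) -> TICAModel:
    """Estimate correlations and solve in one step."""
    mean, c0, ct = estimate_correlations(feature_matrices, lag_frames)
    dt = feature_matrices[0].frame_dt
    return solve_tica(c0, ct, n_components, eps=eps, lag_frames=lag_frames,
                      lag_time=lag_frames * dt, mean=mean)


def project(fm: FeatureMatrix, model: TICAModel) -> np.ndarray:
    """Project a feature matrix onto the kept components:
    y = (f - mean) @ a_i, one column per component."""
    x = np.asarray(fm.values, dtype=np.float64)
    if x.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"feature dimension {x.shape[1]} does not match model "
            f"dimension {model.mean.shape[0]}"
        )
    return (x - model.mean) @ model.components.T
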