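"""k-centers clustering (greedy farthest-point traversal).

The greedy traversal is the classic 2-approximation to the minimax
(coverage-radius) clustering objective: the first center is the point at
index ``seed mod n``; each subsequent center is the point farthest from the
current center set, ties broken by lowest index.  Assignment is to the
nearest center in Euclidean metric, ties to the lowest center index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ClusterModel", "kcenters_fit", "assign"]


@dataclass
class ClusterModel:
    centers: np.ndarray       # (k, dim)
    k: int
    coverage_radius: float    # max distance of any training point to its center
    seed: int
    center_indices: np.ndarray  # indices of the chosen points in training data


def kcenters_fit(points: np.ndarray, k: int, seed: int = 0) -> ClusterModel:
    """Fit k centers by greedy farthest-point traversal (deterministic)."""
    points = np.asarray(points, dtype=np.float64)
    if points.ndim == 1:
        points = points[:, None]
    n = points.shape[0]
    if n < 1:
        raise ValueError("need at least one point")
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must be in [1, n={n}]")
    first = seed % n
    center_idx = np.empty(k, dtype=np.intp)
    center_idx[0] = first
    # distance of every point to its nearest chosen center
    d = np.linalg.norm(points - points[first], axis=1)
    for c in range(1, k):
        nxt = int(np.argmax(d))  # argmax takes the lowest index on ties
        center_idx[c] = nxt
        d = np.minimum(d, np.linalg.norm(points - points[nxt], axis=1))
    return ClusterModel(centers=points[center_idx].copy(), k=k,
                        coverage_radius=float(d.max()), seed=seed,
                        center_indices=center_idx)


def assign(points: np.ndarray, model: ClusterModel,
           chunk: int = 65536) -> np.ndarray:
    """Nearest-center labels for each point (ties -> lowest center index)."""
    points = np.asarray(points, dtype=np.float64)
    if points.ndim == 1:
        points = points[:, None]
    if points.shape[1] != model.centers.shape[1]:
        raise ValueError(
            f"point dimension {points.shape[1]} does not match centers "
            f"dimension {model.centers.shape[1]}"
        )
    labels = np.empty(points.shape[0], dtype=np.intp)
    for start in range(0, points.shape[0], chunk):
        block = points[start:start + chunk]
        d2 = ((block[:, None, :] - model.centers[None, :, :]) ** 2).sum(-1)
        labels[start:start + chunk] = np.argmin(d2, axis=1)
    return labels
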