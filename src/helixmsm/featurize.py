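"""Distance featurization of coordinate trajectories.

The feature vector of a frame is the list of all pairwise Euclidean
distances between the selected CA and CB atoms, in lexicographic pair order
(a, b), a < b, so feature indices are stable across runs.  A 15-residue
peptide with CA and CB on every residue selects 30 atoms and yields
30*29/2 = 435 distance features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .geometry import CoordinateTrajectory

__all__ = [
    "FeatureMatrix",
    "select_feature_atoms",
    "compute_pair_features",
    "discard_equilibration",
]


@dataclass
class FeatureMatrix:
    """Frames-by-features matrix of pair distances (Angstrom) with the atom
    index pair behind each column."""

    values: np.ndarray  # (frames, n_features)
    descriptors: List[Tuple[int, int]]
    frame_dt: float
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (frames, features)")
        if self.values.shape[1] != len(self.descriptors):
            raise ValueError("descriptor count does not match feature count")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def select_feature_atoms(topology) -> List[int]:
    """Indices of all CA and CB atoms, ordered by residue with CA before CB
    within each residue.  Residues lacking a CB (glycine-like) contribute
    only their CA."""
    records = [(rec.res_index, 0 if rec.role == "CA" else 1, a)
               for a, rec in enumerate(topology)
               if rec.role in ("CA", "CB")]
    if not any(order == 0 for _, order, _ in records):
        raise ValueError("topology contains no CA atoms")
    return [a for _, _, a in sorted(records)]


def compute_pair_features(
    ct: CoordinateTrajectory,
    atoms: Sequence[int],
    chunk: int = 4096,
    dtype=np.float32,
) -> FeatureMatrix:
    """All pairwise distances between the selected atoms, one column per
    unordered pair in lexicographic (a, b) order."""
    atoms = list(atoms)
    if len(atoms) < 2:
        raise ValueError("need at least 2 atoms for pair distances")
    if max(atoms) >= ct.n_atoms or min(atoms) < 0:
        raise ValueError("atom index out of range for trajectory")
    k = len(atoms)
    iu = np.triu_indices(k, 1)
    descriptors = [(atoms[i], atoms[j]) for i, j in zip(*iu)]
    sel = ct.coords[:, atoms, :]
    n_frames = sel.shape[0]
    out = np.empty((n_frames, len(descriptors)), dtype=dtype)
    for start in range(0, n_frames, chunk):
        block = sel[start:start + chunk]
        diff = block[:, :, None, :] - block[:, None, :, :]
        dmat = np.sqrt((diff * diff).sum(-1))
        out[start:start + chunk] = dmat[:, iu[0], iu[1]]
    return FeatureMatrix(values=out, descriptors=descriptors,
                         frame_dt=ct.frame_dt)


def discard_equilibration(traj, t_eq: float):
    """Drop all frames with time < ``t_eq`` (time of frame f is
    f * frame_dt), returning the same trajectory type.

    Works on any of the frame-indexed containers (state trajectories,
    coordinate trajectories, feature matrices).
    """
    if t_eq < 0:
        raise ValueError("t_eq must be >= 0")
    from .helixcoil import StateTrajectory

    dt = traj.frame_dt
    n_skip = int(np.ceil(t_eq / dt - 1e-12))
    n_frames = traj.n_frames
    if n_skip >= n_frames:
        raise ValueError(
            f"t_eq={t_eq} discards all {n_frames} frames "
            f"(frame_dt={dt})"
        )
    if n_skip == 0:
        return traj
    if isinstance(traj, StateTrajectory):
        return StateTrajectory(states=traj.states[n_skip:], frame_dt=dt,
                               params=traj.params, seed=traj.seed)
    if isinstance(traj, CoordinateTrajectory):
        return CoordinateTrajectory(coords=traj.coords[n_skip:],
                                    topology=traj.topology, frame_dt=dt)
    if isinstance(traj, FeatureMatrix):
        return FeatureMatrix(values=traj.values[n_skip:],
                             descriptors=traj.descriptors, frame_dt=dt,
                             source=traj.source)
    raise TypeError(f"unsupported trajectory type {type(traj)!r}")
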