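"""Secondary-structure assignment and MSM-weighted helicity.

``assign_helix`` applies the classic backbone hydrogen-bond criterion: an
i -> i+4 bond exists when the electrostatic energy

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

between the C=O of residue i and the N-H of residue i+4 is below -0.5
kcal/mol, and a residue is alpha-helical ('H') when it lies in a stretch
supported by two consecutive i -> i+4 bonds.  Only the alpha-helix class is
assigned (3-10/pi helices, sheets and turns are not distinguished from coil);
the energy cutoff and the two-bond rule are configurable.

Ensemble helicity is the stationary-weighted state average
<h> = sum_i pi_i h_i where h_i is the mean helicity of the frames assigned
to Markov state i.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .geometry import CoordinateTrajectory
from .msm import MSMModel

__all__ = [
    "SecondaryStructureTrajectory",
    "HelicityProfile",
    "assign_helix",
    "state_helicity",
    "ensemble_helicity",
]

_Q1Q2_F = 0.084 * 332.0  # DSSP electrostatic prefactor, kcal/mol * A


@dataclass
class SecondaryStructureTrajectory:
    """Boolean helix labels: ``helix[f, r]`` is True when residue r of frame
    f is assigned 'H'."""

    helix: np.ndarray  # (frames, n_res) bool
    rule: str = "hbond-i4"

    def __post_init__(self) -> None:
        self.helix = np.asarray(self.helix, dtype=bool)
        if self.helix.ndim != 2:
            raise ValueError("labels must be (frames, n_res)")

    @property
    def n_frames(self) -> int:
        return self.helix.shape[0]

    def helicity_per_frame(self) -> np.ndarray:
        return self.helix.mean(axis=1)


@dataclass
class HelicityProfile:
    """Per-residue and overall MSM-weighted helicity with bootstrap SEM."""

    per_residue: np.ndarray
    per_residue_sem: np.ndarray
    overall: float
    overall_sem: float
    state_helicity: np.ndarray  # h_i per Markov state

    def __post_init__(self) -> None:
        if ((self.per_residue < -1e-12) | (self.per_residue > 1 + 1e-12)).any():
            raise ValueError("per-residue helicity must lie in [0, 1]")


def assign_helix(
    ct: CoordinateTrajectory,
    energy_cutoff: float = -0.5,
    min_consecutive_bonds: int = 2,
) -> SecondaryStructureTrajectory:
    """Alpha-helix assignment from backbone i -> i+4 hydrogen bonds."""
    required = {"N", "CA", "C", "O", "H"}
    roles = {rec.role for rec in ct.topology}
    missing = required - roles
    if missing:
        raise ValueError(f"topology lacks required atom roles: {missing}")
    N = ct.coords[:, ct.atom_indices("N")]
    C = ct.coords[:, ct.atom_indices("C")]
    O = ct.coords[:, ct.atom_indices("O")]
    H = ct.coords[:, ct.atom_indices("H")]
    n_frames, n_res = N.shape[0], N.shape[1]
    helix = np.zeros((n_frames, n_res), dtype=bool)
    if n_res < 5:
        return SecondaryStructureTrajectory(helix=helix)

    def dist(a, b):
        return np.linalg.norm(a - b, axis=-1)

    # bond[f, i]: C=O of residue i to N-H of residue i+4
    acc_C, acc_O = C[:, :-4], O[:, :-4]
    don_N, don_H = N[:, 4:], H[:, 4:]
    energy = _Q1Q2_F * (
        1.0 / dist(acc_O, don_N)
        + 1.0 / dist(acc_C, don_H)
        - 1.0 / dist(acc_O, don_H)
        - 1.0 / dist(acc_C, don_N)
    )
    bond = energy < energy_cutoff  # (frames, n_res - 4)

    # two consecutive bonds i, i+1 support residues i+1 .. i+4
    w = min_consecutive_bonds
    if bond.shape[1] < w:
        return SecondaryStructureTrajectory(helix=helix)
    run = np.ones(bond.shape[:1] + (bond.shape[1] - w + 1,), dtype=bool)
    for off in range(w):
        run &= bond[:, off:bond.shape[1] - w + 1 + off]
    # run[f, i] True -> residues i+1 .. i+w+2 are helical
    for i in range(run.shape[1]):
        helix[:, i + 1:i + w + 3] |= run[:, [i]]
    return SecondaryStructureTrajectory(helix=helix)


def state_helicity(
    ss: SecondaryStructureTrajectory | np.ndarray,
    labels: np.ndarray,
    model: MSMModel,
):
    """Mean helicity of the frames assigned to each model state.

    Returns (h_states, h_states_per_residue): ``h_states[i]`` is the mean
    fraction of helical residues over frames in active state i, and the
    per-residue variant averages each residue's indicator separately.
    """
    helix = ss.helix if isinstance(ss, SecondaryStructureTrajectory) \
        else np.asarray(ss, dtype=bool)
    labels = np.asarray(labels)
    if helix.shape[0] != labels.shape[0]:
        raise ValueError("frame counts of labels and structure disagree")
    n_states = model.n_states
    n_res = helix.shape[1]
    h = np.empty(n_states)
    h_res = np.empty((n_states, n_res))
    for i, orig in enumerate(model.active):
        mask = labels == orig
        if not mask.any():
            raise ValueError(
                f"active state {orig} has no frames in the supplied labels"
            )
        h_res[i] = helix[mask].mean(axis=0)
        h[i] = h_res[i].mean()
    return h, h_res


def ensemble_helicity(
    h: np.ndarray,
    pi: np.ndarray,
    h_res: Optional[np.ndarray] = None,
):
    """Stationary-weighted average helicity <h> = sum_i pi_i h_i.

    Returns the overall scalar, or (overall, per_residue) when the
    per-state per-residue matrix is supplied.
    """
    h = np.asarray(h, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if h.shape[0] != pi.shape[0]:
        raise ValueError("state helicity and pi lengths disagree")
    if not np.isclose(pi.sum(), 1.0, atol=1e-8):
        raise ValueError("pi must sum to 1")
    if ((h < -1e-12) | (h > 1 + 1e-12)).any():
        raise ValueError("state helicities must lie in [0, 1]")
    overall = float(pi @ h)
    if h_res is None:
        return overall
    h_res = np.asarray(h_res, dtype=float)
    if h_res.shape[0] != pi.shape[0]:
        raise ValueError("h_res and pi lengths disagree")
    return overall, pi @ h_res


def msm_helicity_profile(
    ss_list: Sequence[np.ndarray],
    label_list: Sequence[np.ndarray],
    model: MSMModel,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Convenience: pool per-trajectory structure labels and state labels,
    compute state helicities under ``model`` and return
    (overall, per_residue, h_states)."""
    helix = np.concatenate([np.asarray(s, dtype=bool) for s in ss_list])
    labels = np.concatenate([np.asarray(l) for l in label_list])
    h, h_res = state_helicity(helix, labels, model)
    overall, per_res = ensemble_helicity(h, model.pi, h_res)
    return overall, per_res, h
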