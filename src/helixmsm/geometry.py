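"""Backbone coordinate construction from helix/coil state trajectories.

Frames are built residue-by-residue with internal coordinates (the NeRF
torsion-driven placement): helical residues get ideal alpha-helix torsions
(phi, psi) = (-57, -47) degrees, coil residues draw torsions uniformly from a
beta/PPII-like basin, and every residue receives N, CA, C, O, CB and an amide
H.  The H is placed 1.0 A from N along the negative bisector of its two
heavy-atom neighbours (standard practice when amide hydrogens are absent from
a structure).  Optional isotropic Gaussian jitter emulates thermal noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

__all__ = [
    "BackboneGeometry",
    "AtomRecord",
    "CoordinateTrajectory",
    "build_coordinates",
]

ATOM_ROLES = ("N", "CA", "C", "O", "CB", "H")


@dataclass(frozen=True)
class BackboneGeometry:
    """Ideal bond lengths (A), bond angles (deg) and torsion conventions used
    by the chain builder."""

    phi_helix: float = -57.0
    psi_helix: float = -47.0
    coil_phi_range: Tuple[float, float] = (-180.0, -60.0)
    coil_psi_range: Tuple[float, float] = (60.0, 180.0)
    # bond lengths
    len_n_ca: float = 1.458
    len_ca_c: float = 1.525
    len_c_n: float = 1.329
    len_c_o: float = 1.231
    len_ca_cb: float = 1.521
    len_n_h: float = 1.0
    # bond angles
    ang_c_n_ca: float = 121.7
    ang_n_ca_c: float = 111.2
    ang_ca_c_n: float = 116.2
    ang_ca_c_o: float = 120.8
    ang_n_ca_cb: float = 110.5
    omega: float = 180.0
    dih_c_n_ca_cb: float = -122.6  # improper fixing CB chirality
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("len_n_ca", "len_ca_c", "len_c_n", "len_c_o",
                     "len_ca_cb", "len_n_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("ang_c_n_ca", "ang_n_ca_c", "ang_ca_c_n",
                     "ang_ca_c_o", "ang_n_ca_cb"):
            a = getattr(self, name)
            if not (0.0 < a < 180.0):
                raise ValueError(f"{name} must lie in (0, 180) degrees")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


@dataclass(frozen=True)
class AtomRecord:
    res_index: int
    res_name: str
    role: str  # one of ATOM_ROLES


@dataclass
class CoordinateTrajectory:
    """Cartesian trajectory: ``coords[f, a]`` is the (x, y, z) of atom ``a``
    in frame ``f``, with a typed topology listing residue index and role."""

    coords: np.ndarray  # (frames, atoms, 3) float
    topology: List[AtomRecord]
    frame_dt: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[1] != len(self.topology):
            raise ValueError("topology length does not match atom count")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")
        residues = {rec.res_index for rec in self.topology}
        ca_residues = {rec.res_index for rec in self.topology
                       if rec.role == "CA"}
        if residues != ca_residues:
            raise ValueError("every residue must have a CA atom")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def n_res(self) -> int:
        return 1 + max(rec.res_index for rec in self.topology)

    def atom_indices(self, role: str) -> np.ndarray:
        """Indices of atoms with the given role, in residue order."""
        idx = [(rec.res_index, a) for a, rec in enumerate(self.topology)
               if rec.role == role]
        return np.array([a for _, a in sorted(idx)], dtype=np.intp)


def _normalize(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _place(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF placement of atom D bonded to c, with angle b-c-D and dihedral
    a-b-c-D.  All of a, b, c are (F, 3); bond/angle scalars; torsion scalar
    or (F,)."""
    theta = math.radians(angle_deg)
    tors = np.deg2rad(np.asarray(torsion_deg, dtype=np.float64))
    bc = _normalize(c - b)
    n = _normalize(np.cross(b - a, bc))
    m = np.cross(n, bc)
    ct, st = np.cos(tors), np.sin(tors)
    if np.ndim(ct) == 0:
        ct = np.full(c.shape[0], float(ct))
        st = np.full(c.shape[0], float(st))
    d_local = (
        -math.cos(theta) * bc
        + (math.sin(theta) * ct)[:, None] * m
        + (math.sin(theta) * st)[:, None] * n
    )
    return c + bond * d_local


def dihedral(a, b, c, d) -> np.ndarray:
    """Signed dihedral angle a-b-c-d in degrees (vectorized over leading
    axes)."""
    b0, b1, b2 = a - b, c - b, d - c
    b1n = _normalize(b1)
    v = b0 - (b0 * b1n).sum(-1, keepdims=True) * b1n
    w = b2 - (b2 * b1n).sum(-1, keepdims=True) * b1n
    x = (v * w).sum(-1)
    y = (np.cross(b1n, v) * w).sum(-1)
    return np.degrees(np.arctan2(y, x))


def build_topology(n_res: int, res_name: str = "ALA") -> List[AtomRecord]:
    """Topology with N, CA, C, O, CB, H for every residue, in residue order."""
    top = []
    for r in range(n_res):
        for role in ATOM_ROLES:
            top.append(AtomRecord(res_index=r, res_name=res_name, role=role))
    return top


def build_coordinates(
    st,
    geom: Optional[BackboneGeometry] = None,
    seed: int = 0,
) -> CoordinateTrajectory:
    """Build Cartesian backbone coordinates for every frame of a
    :class:`~helixmsm.helixcoil.StateTrajectory`.

    Helical residues (state 1) use (phi_helix, psi_helix); coil residues draw
    torsions uniformly from the configured coil ranges, independently per
    frame and residue.  Gaussian jitter of sd ``geom.jitter_sd`` is added to
    all coordinates at the end.  Deterministic given ``seed``.
    """
    if geom is None:
        geom = BackboneGeometry()
    states = np.asarray(st.states, dtype=np.int8)
    if states.shape[0] < 1:
        raise ValueError("state trajectory is empty")
    rng = np.random.default_rng(seed)
    n_frames, n_res = states.shape
    helix = states == 1

    phi = np.where(
        helix,
        geom.phi_helix,
        rng.uniform(*geom.coil_phi_range, size=states.shape),
    )
    psi = np.where(
        helix,
        geom.psi_helix,
        rng.uniform(*geom.coil_psi_range, size=states.shape),
    )

    F = n_frames
    N = np.empty((n_res, F, 3))
    CA = np.empty((n_res, F, 3))
    C = np.empty((n_res, F, 3))
    O = np.empty((n_res, F, 3))
    CB = np.empty((n_res, F, 3))
    H = np.empty((n_res, F, 3))

    # first residue seeds the frame: N at origin, CA on +x, C in the xy plane
    N[0] = 0.0
    CA[0] = np.array([geom.len_n_ca, 0.0, 0.0])
    ang = math.radians(geom.ang_n_ca_c)
    C[0] = CA[0] + geom.len_ca_c * np.array(
        [-math.cos(ang), math.sin(ang), 0.0]
    )

    for r in range(n_res):
        if r > 0:
            N[r] = _place(N[r - 1], CA[r - 1], C[r - 1],
                          geom.len_c_n, geom.ang_ca_c_n, psi[:, r - 1])
            CA[r] = _place(CA[r - 1], C[r - 1], N[r],
                           geom.len_n_ca, geom.ang_c_n_ca, geom.omega)
            C[r] = _place(C[r - 1], N[r], CA[r],
                          geom.len_ca_c, geom.ang_n_ca_c, phi[:, r])
        O[r] = _place(N[r], CA[r], C[r],
                      geom.len_c_o, geom.ang_ca_c_o, psi[:, r] + 180.0)
        CB[r] = _place(C[r], N[r], CA[r],
                       geom.len_ca_cb, geom.ang_n_ca_cb, geom.dih_c_n_ca_cb)
        if r > 0:
            hdir = -(_normalize(C[r - 1] - N[r]) + _normalize(CA[r] - N[r]))
        else:
            hdir = -(CA[r] - N[r])
        H[r] = N[r] + geom.len_n_h * _normalize(hdir)

    per_res = np.stack([N, CA, C, O, CB, H], axis=1)  # (res, role, F, 3)
    coords = per_res.transpose(2, 0, 1, 3).reshape(F, n_res * len(ATOM_ROLES), 3)
    if geom.jitter_sd > 0:
        coords = coords + rng.normal(0.0, geom.jitter_sd, size=coords.shape)
    return CoordinateTrajectory(
        coords=coords,
        topology=build_topology(n_res),
        frame_dt=st.frame_dt,
    )
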