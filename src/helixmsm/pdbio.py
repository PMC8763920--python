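"""Multi-model PDB reading and writing for coordinate trajectories.

One MODEL/ENDMDL block per frame, fixed-column ATOM records.  Coordinates
survive a round trip to 3 decimal places (the PDB fixed-point columns);
topology (residue index, residue name, atom role) round-trips exactly.
"""

from __future__ import annotations

import os
from typing import List

import numpy as np

from .geometry import AtomRecord, CoordinateTrajectory

__all__ = ["write_pdb_multimodel", "read_pdb_multimodel", "PDBParseError"]

# PDB atom names for our roles are identical to the role strings
_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "H": "H"}


class PDBParseError(ValueError):
    """Malformed PDB record; the message names the offending line number."""


def write_pdb_multimodel(ct: CoordinateTrajectory, path: str) -> None:
    """Write a trajectory as a multi-model PDB file."""
    if ct.n_frames < 1:
        raise ValueError("cannot write an empty trajectory")
    with open(path, "w") as fh:
        fh.write("REMARK   1 frame_dt %.6f\n" % ct.frame_dt)
        for f in range(ct.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for a, rec in enumerate(ct.topology):
                x, y, z = ct.coords[f, a]
                name = rec.role if len(rec.role) == 4 else f" {rec.role:<3s}"
                fh.write(
                    "ATOM  %5d %4s %3s A%4d    %8.3f%8.3f%8.3f%6.2f%6.2f"
                    "          %2s\n"
                    % (a + 1, name, rec.res_name, rec.res_index + 1,
                       x, y, z, 1.0, 0.0, _ELEMENT.get(rec.role, ""))
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_pdb_multimodel(path: str) -> CoordinateTrajectory:
    """Read a multi-model PDB file written by :func:`write_pdb_multimodel`
    (or any single-chain PDB whose atom names match the backbone roles)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    frames: List[List[np.ndarray]] = []
    topology: List[AtomRecord] = []
    frame_dt = 1.0
    current: List[np.ndarray] = []
    first_model_topology = True
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tag = line[:6]
            if tag == "REMARK" and "frame_dt" in line:
                try:
                    frame_dt = float(line.split()[-1])
                except ValueError:
                    raise PDBParseError(
                        f"line {lineno}: malformed frame_dt remark"
                    )
            elif tag == "MODEL ":
                in_model = True
                current = []
            elif tag == "ENDMDL":
                if not in_model:
                    raise PDBParseError(f"line {lineno}: ENDMDL without MODEL")
                frames.append(current)
                first_model_topology = False
                in_model = False
            elif tag in ("ATOM  ", "HETATM"):
                try:
                    name = line[12:16].strip()
                    res_name = line[17:20].strip()
                    res_seq = int(line[22:26])
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except (ValueError, IndexError):
                    raise PDBParseError(
                        f"line {lineno}: malformed ATOM record"
                    )
                if first_model_topology:
                    topology.append(
                        AtomRecord(res_index=res_seq - 1, res_name=res_name,
                                   role=name)
                    )
                current.append(np.array([x, y, z]))
    if in_model:
        raise PDBParseError("file ended inside an open MODEL block")
    if not frames:
        # single-model files without MODEL records
        if current:
            frames.append(current)
        else:
            raise PDBParseError("no ATOM records found")
    n_atoms = len(topology)
    for f, fr in enumerate(frames):
        if len(fr) != n_atoms:
            raise PDBParseError(
                f"model {f + 1} has {len(fr)} atoms, expected {n_atoms}"
            )
    coords = np.array(frames)
    return CoordinateTrajectory(coords=coords, topology=topology,
                                frame_dt=frame_dt)
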