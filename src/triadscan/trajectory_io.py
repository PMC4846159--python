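"""Conformational-ensemble I/O and atom selection.

A trajectory is an ordered stack of coordinate frames sharing one topology
(the chains/residues/atom names of a :class:`~triadscan.peptide_models.
StructureModel`), with a frame time spacing in picoseconds.  Ensembles are
exchanged as multi-model PDB files (one MODEL per frame, wwPDB fixed-width
columns, written and parsed through biotite) or optionally as plain
XYZ-per-frame CSV tables.  Time metadata is not encoded in the PDB; it is
supplied by configuration (default 20 ps per frame, matching a typical MD
snapshot interval).

Binary MD formats and altloc/insertion-code PDBs are out of scope; the latter
are rejected loudly rather than silently mis-read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .peptide_models import (
    Atom,
    Chain,
    Residue,
    StructureModel,
    THREE_TO_ONE,
)

__all__ = [
    "Trajectory",
    "AtomSelection",
    "TrajectoryFormatError",
    "read_multimodel_pdb",
    "write_pdb",
    "select_atoms",
    "write_xyz_csv",
    "read_xyz_csv",
    "model_to_atom_array",
]

DEFAULT_FRAME_SPACING_PS = 20.0


class TrajectoryFormatError(ValueError):
    """Malformed or unsupported ensemble file."""


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed topology.

    ``topology`` carries atom identities (its own coordinates are those of
    frame 0 unless stated otherwise); ``frames`` has shape
    (n_frames, n_atoms, 3) in Angstrom.
    """

    topology: StructureModel
    frames: np.ndarray
    frame_spacing_ps: float = DEFAULT_FRAME_SPACING_PS
    origin_time_ps: float = 0.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frames carry {self.frames.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )
        if self.frame_spacing_ps <= 0:
            raise ValueError("frame_spacing_ps must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @property
    def times_ps(self) -> np.ndarray:
        return self.origin_time_ps + self.frame_spacing_ps * np.arange(self.n_frames)

    @property
    def extent_ps(self) -> tuple:
        """Half-open time interval [origin, origin + n_frames * spacing)."""
        return (self.origin_time_ps,
                self.origin_time_ps + self.n_frames * self.frame_spacing_ps)


@dataclass(frozen=True)
class AtomSelection:
    """Resolved atom indices (strictly increasing) with human-readable labels."""

    indices: tuple
    labels: tuple = ()

    def __post_init__(self):
        idx = tuple(int(i) for i in self.indices)
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("selection indices must be strictly increasing")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)


def atom_records(model: StructureModel):
    """Flatten a model into (index, chain_id, res_id, res_name, atom_name)."""
    out = []
    for i, (ch, res, atom) in enumerate(model.iter_atoms()):
        out.append((i, ch.chain_id, res.seq_id, res.name, atom.name))
    return out


def select_atoms(trajectory_or_model, predicate: Callable) -> AtomSelection:
    """Resolve a predicate over (chain_id, res_id, res_name, atom_name) into a
    deterministic atom index list (topology order).  An empty selection is a
    valid result, not an error."""
    model = getattr(trajectory_or_model, "topology", trajectory_or_model)
    indices, labels = [], []
    for i, chain_id, res_id, res_name, atom_name in atom_records(model):
        if predicate(chain_id, res_id, res_name, atom_name):
            indices.append(i)
            labels.append(f"{chain_id}/{res_name}{res_id}/{atom_name}")
    return AtomSelection(tuple(indices), tuple(labels))


# ---------------------------------------------------------------------------
# PDB I/O (biotite behind the interface)
# ---------------------------------------------------------------------------


def _element_of(atom_name: str) -> str:
    return atom_name.lstrip("0123456789")[0]


def model_to_atom_array(model: StructureModel) -> struc.AtomArray:
    records = atom_records(model)
    arr = struc.AtomArray(len(records))
    arr.chain_id = np.array([r[1] for r in records], dtype="U4")
    arr.res_id = np.array([r[2] for r in records], dtype=int)
    arr.res_name = np.array([r[3] for r in records], dtype="U5")
    arr.atom_name = np.array([r[4] for r in records], dtype="U6")
    arr.element = np.array([_element_of(r[4]) for r in records], dtype="U2")
    arr.hetero = np.zeros(len(records), dtype=bool)
    arr.coord = model.coords().astype(np.float32)
    return arr


def write_pdb(path, model_or_trajectory) -> None:
    """Write a model (single MODEL) or trajectory (one MODEL per frame)."""
    obj = model_or_trajectory
    if isinstance(obj, Trajectory):
        template = model_to_atom_array(obj.topology)
        stack = struc.stack([template] * obj.n_frames)
        stack.coord = obj.frames.astype(np.float32)
        structure = stack
    elif isinstance(obj, StructureModel):
        structure = model_to_atom_array(obj)
    else:
        raise TypeError("expected StructureModel or Trajectory")
    pdb_file = PDBFile()
    pdb_file.set_structure(structure)
    pdb_file.write(str(path))


def _prescan_pdb_text(lines: Sequence[str]) -> None:
    """Enforce the supported PDB dialect before handing the file to biotite:
    congruent atom counts across MODELs (error names the model), no altloc,
    no insertion codes."""
    counts: dict = {}
    model_no = 1
    seen_model_record = False
    for line in lines:
        rec = line[:6]
        if rec.startswith("MODEL"):
            seen_model_record = True
            try:
                model_no = int(line.split()[1])
            except (IndexError, ValueError):
                model_no = len(counts) + 1
            counts.setdefault(model_no, 0)
        elif rec in ("ATOM  ", "HETATM"):
            if len(line) > 16 and line[16] not in (" ", ""):
                raise TrajectoryFormatError(
                    f"altloc identifiers are not supported (line: {line.rstrip()!r})"
                )
            if len(line) > 26 and line[26] not in (" ", ""):
                raise TrajectoryFormatError(
                    f"insertion codes are not supported (line: {line.rstrip()!r})"
                )
            if len(line.rstrip("\n")) < 54:
                raise TrajectoryFormatError(
                    f"missing coordinates (line: {line.rstrip()!r})"
                )
            counts[model_no] = counts.get(model_no, 0) + 1
    if not counts or all(c == 0 for c in counts.values()):
        raise TrajectoryFormatError("no ATOM records found")
    ref_model = min(counts)
    ref = counts[ref_model]
    for m in sorted(counts):
        if counts[m] != ref:
            raise TrajectoryFormatError(
                f"MODEL {m} has {counts[m]} atoms, expected {ref} "
                f"(from MODEL {ref_model})"
            )
    del seen_model_record  # single unwrapped model is fine


def _stack_to_trajectory(stack: struc.AtomArrayStack,
                         frame_spacing_ps: float,
                         origin_time_ps: float) -> Trajectory:
    first = stack[0]
    chains: list = []
    current_chain = None
    current_res = None
    for i in range(first.array_length()):
        cid = str(first.chain_id[i])
        rid = int(first.res_id[i])
        rname = str(first.res_name[i])
        if current_chain is None or current_chain.chain_id != cid:
            current_chain = Chain(cid, [])
            chains.append(current_chain)
            current_res = None
        if current_res is None or current_res.seq_id != rid:
            if rname not in THREE_TO_ONE:
                raise TrajectoryFormatError(f"non-canonical residue {rname!r}")
            current_res = Residue(rname, rid, {})
            current_chain.residues.append(current_res)
        name = str(first.atom_name[i])
        current_res.atoms[name] = Atom(name, np.asarray(first.coord[i], dtype=float))
    topology = StructureModel(chains)
    return Trajectory(topology, np.asarray(stack.coord, dtype=float),
                      frame_spacing_ps=frame_spacing_ps,
                      origin_time_ps=origin_time_ps)


def read_multimodel_pdb(path, frame_spacing_ps: float = DEFAULT_FRAME_SPACING_PS,
                        origin_time_ps: float = 0.0) -> Trajectory:
    """Read a multi-model (or single, unwrapped) PDB into a trajectory.

    The topology is taken from MODEL 1; all MODELs must be congruent.  Frame
    timing comes from the arguments, not from PDB remarks.
    """
    with open(path) as fh:
        lines = fh.readlines()
    _prescan_pdb_text(lines)
    pdb_file = PDBFile.read(str(path))
    stack = pdb_file.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    return _stack_to_trajectory(stack, frame_spacing_ps, origin_time_ps)


# ---------------------------------------------------------------------------
# Plain-text XYZ-per-frame table (synthetic-ensemble convenience)
# ---------------------------------------------------------------------------


def write_xyz_csv(path, trajectory: Trajectory) -> None:
    """Write frames as a CSV of (frame, atom, chain, res_id, res_name,
    atom_name, x, y, z)."""
    records = atom_records(trajectory.topology)
    with open(path, "w") as fh:
        fh.write("frame,atom,chain,res_id,res_name,atom_name,x,y,z\n")
        for f in range(trajectory.n_frames):
            for (i, cid, rid, rname, aname) in records:
                x, y, z = trajectory.frames[f, i]
                fh.write(f"{f},{i},{cid},{rid},{rname},{aname},"
                         f"{x:.6f},{y:.6f},{z:.6f}\n")


def read_xyz_csv(path, topology: StructureModel,
                 frame_spacing_ps: float = DEFAULT_FRAME_SPACING_PS,
                 origin_time_ps: float = 0.0) -> Trajectory:
    """Read frames written by :func:`write_xyz_csv` against a known topology."""
    import pandas as pd

    table = pd.read_csv(path)
    n_atoms = topology.n_atoms
    n_frames = int(table["frame"].max()) + 1
    if len(table) != n_frames * n_atoms:
        raise TrajectoryFormatError(
            f"table has {len(table)} rows, expected {n_frames} x {n_atoms}"
        )
    order = table.sort_values(["frame", "atom"], kind="stable")
    frames = order[["x", "y", "z"]].to_numpy(dtype=float).reshape(n_frames, n_atoms, 3)
    return Trajectory(topology, frames, frame_spacing_ps=frame_spacing_ps,
                      origin_time_ps=origin_time_ps)
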