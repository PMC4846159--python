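"""Idealized all-atom peptide model construction.

Builds extended chains, three-strand antiparallel amyloid beta-sheets and
N-terminal fusion constructs from sequence plus backbone internal coordinates
(bond lengths, bond angles, phi/psi/omega torsions), using the natural
extension reference frame (NeRF) to convert internal to Cartesian coordinates.

The models are deliberately idealized: no force field, no energy minimization.
Only the backbone plus the side-chain functional atoms needed by the catalytic
triad detector (hydroxyl oxygens, imidazole nitrogens, carboxylate oxygens,
and CB) are placed, with geometry taken from chemical-component-dictionary
averages.  Coordinates are in Angstrom; the strand axis is Z, the sheet
stacking axis is X; residues are numbered 1-based from the N-terminus.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterator, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Construct",
    "BackboneGeometry",
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "SheetSpec",
    "UnknownResidueError",
    "DihedralUndefinedError",
    "build_chain",
    "measure_dihedral",
    "dihedral",
    "place_atom",
    "assemble_sheet",
    "align_to_z",
    "fuse_nterm",
    "apply_mutation",
    "amidate_cterm",
    "load_registry",
    "get_construct",
    "build_construct_model",
    "iter_bonds",
    "CP4_SEQUENCE",
    "ABETA_SEQUENCE",
    "CP4_ABETA_SEQUENCE",
]

# ---------------------------------------------------------------------------
# Sequences and residue naming
# ---------------------------------------------------------------------------

CP4_SEQUENCE = "SMESLSKTHHYR"
ABETA_SEQUENCE = "FFKLVFF"
CP4_ABETA_SEQUENCE = CP4_SEQUENCE + ABETA_SEQUENCE

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}


class UnknownResidueError(ValueError):
    """Sequence contains a character outside the 20 canonical one-letter codes."""


class DihedralUndefinedError(ValueError):
    """A requested backbone dihedral lacks one of its four defining atoms."""


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("sequence must be non-empty")
    for i, code in enumerate(sequence, start=1):
        if code not in ONE_TO_THREE:
            raise UnknownResidueError(
                f"unknown residue code {code!r} at position {i}"
            )


# ---------------------------------------------------------------------------
# Geometry tables
# ---------------------------------------------------------------------------

#: Backbone bond lengths (Angstrom).
BOND_LENGTHS: Mapping[str, float] = {
    "N-CA": 1.458,
    "CA-C": 1.525,
    "C-N": 1.329,   # peptide bond
    "C-O": 1.231,
    "C-OXT": 1.249,
    "CA-CB": 1.529,
}

#: Backbone bond angles (degrees).
BOND_ANGLES: Mapping[str, float] = {
    "N-CA-C": 111.0,
    "CA-C-N": 116.2,
    "C-N-CA": 121.7,
    "CA-C-O": 120.5,
    "CA-C-OXT": 117.0,
    "N-CA-CB": 109.5,
}

#: Improper torsion C-N-CA-CB fixing L-amino-acid chirality (degrees).
CB_IMPROPER = -120.0

#: Side-chain internal coordinates: resname -> list of
#: (atom, (ref_a, ref_b, ref_c), bond to ref_c, angle at ref_c, torsion).
#: Only functional atoms relevant to triad detection are placed; torsion
#: defaults encode one idealized rotamer (no rotamer sampling in scope).
SIDECHAIN_ICS: Mapping[str, Sequence[tuple]] = {
    "SER": [("OG", ("N", "CA", "CB"), 1.428, 109.5, 180.0)],
    "THR": [("OG1", ("N", "CA", "CB"), 1.428, 109.5, 180.0)],
    "HIS": [
        ("CG", ("N", "CA", "CB"), 1.510, 113.0, 180.0),
        ("ND1", ("CA", "CB", "CG"), 1.351, 120.3, 90.0),
        ("CE1", ("CB", "CG", "ND1"), 1.337, 107.9, 180.0),
        ("NE2", ("CG", "ND1", "CE1"), 1.337, 107.6, 0.0),
        ("CD2", ("ND1", "CE1", "NE2"), 1.374, 109.4, 0.0),
    ],
    "GLU": [
        ("CG", ("N", "CA", "CB"), 1.530, 109.4, 180.0),
        ("CD", ("CA", "CB", "CG"), 1.508, 109.4, 180.0),
        ("OE1", ("CB", "CG", "CD"), 1.249, 120.0, 0.0),
        ("OE2", ("CB", "CG", "CD"), 1.249, 120.0, 180.0),
    ],
    "ASP": [
        ("CG", ("N", "CA", "CB"), 1.508, 109.5, 180.0),
        ("OD1", ("CA", "CB", "CG"), 1.249, 120.0, 0.0),
        ("OD2", ("CA", "CB", "CG"), 1.249, 120.0, 180.0),
    ],
}


def wrap_angle(angle: float) -> float:
    """Map an angle in degrees into the interval (-180, 180]."""
    wrapped = float(np.mod(angle, 360.0))
    if wrapped > 180.0:
        wrapped -= 360.0
    if wrapped == -180.0:
        wrapped = 180.0
    return wrapped


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Construct:
    """A named peptide with termini chemistry and mutation annotations."""

    name: str
    sequence: str
    c_terminus: str = "free"  # "free" | "amidated"
    mutations: tuple = ()     # tuple of (1-based position, from, to)
    panel_id: int | None = None
    assembled: bool = False
    note: str = ""

    def __post_init__(self):
        _validate_sequence(self.sequence)
        if self.c_terminus not in ("free", "amidated"):
            raise ValueError(f"invalid c_terminus {self.c_terminus!r}")


@dataclass(frozen=True)
class BackboneGeometry:
    """Per-residue (phi, psi, omega) in degrees plus bond geometry tables.

    ``omega[i]`` is the torsion about the peptide bond following residue
    ``i+1`` (CA_i, C_i, N_{i+1}, CA_{i+1}); the last entry is unused.
    """

    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray
    bond_lengths: Mapping[str, float] = field(default_factory=lambda: dict(BOND_LENGTHS))
    bond_angles: Mapping[str, float] = field(default_factory=lambda: dict(BOND_ANGLES))

    def __post_init__(self):
        for label in ("phi", "psi", "omega"):
            arr = np.asarray(getattr(self, label), dtype=float)
            object.__setattr__(self, label, arr)
            if np.any(arr <= -180.0) or np.any(arr > 180.0):
                raise ValueError(f"{label} angles must lie in (-180, 180]")
        if len({len(self.phi), len(self.psi), len(self.omega)}) != 1:
            raise ValueError("phi, psi, omega must have equal length")
        for table in (self.bond_lengths, self.bond_angles):
            if any(v <= 0 for v in table.values()):
                raise ValueError("geometry-table values must be strictly positive")

    def __len__(self) -> int:
        return len(self.phi)

    @classmethod
    def uniform(cls, n: int, phi: float, psi: float, omega: float = 180.0) -> "BackboneGeometry":
        return cls(np.full(n, float(phi)), np.full(n, float(psi)), np.full(n, float(omega)))

    @classmethod
    def extended(cls, n: int) -> "BackboneGeometry":
        """Fully extended chain, phi = psi = 180 degrees."""
        return cls.uniform(n, 180.0, 180.0)

    @classmethod
    def amyloid(cls, n: int) -> "BackboneGeometry":
        """Amyloid beta-strand conformation, (phi, psi) = (-135, 135)."""
        return cls.uniform(n, -135.0, 135.0)


@dataclass
class Atom:
    name: str
    coord: np.ndarray

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)


@dataclass
class Residue:
    name: str      # three-letter code
    seq_id: int    # 1-based
    atoms: dict    # name -> Atom, insertion-ordered

    def add(self, name: str, coord: np.ndarray) -> None:
        if name in self.atoms:
            raise ValueError(f"duplicate atom {name!r} in residue {self.name}{self.seq_id}")
        self.atoms[name] = Atom(name, coord)

    def __contains__(self, name: str) -> bool:
        return name in self.atoms

    def __getitem__(self, name: str) -> Atom:
        return self.atoms[name]

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE[self.name]


@dataclass
class Chain:
    chain_id: str
    residues: list

    def residue(self, seq_id: int) -> Residue:
        for res in self.residues:
            if res.seq_id == seq_id:
                return res
        raise KeyError(f"no residue {seq_id} in chain {self.chain_id}")


@dataclass
class StructureModel:
    """Chains of residues of named atoms with Cartesian coordinates (Angstrom)."""

    chains: list

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(f"no chain {chain_id!r}")

    def iter_atoms(self) -> Iterator[tuple]:
        """Yield (chain, residue, atom) in deterministic topology order."""
        for ch in self.chains:
            for res in ch.residues:
                for atom in res.atoms.values():
                    yield ch, res, atom

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def coords(self) -> np.ndarray:
        return np.array([a.coord for _, _, a in self.iter_atoms()], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        atoms = [a for _, _, a in self.iter_atoms()]
        if coords.shape != (len(atoms), 3):
            raise ValueError("coordinate array shape does not match topology")
        for atom, xyz in zip(atoms, coords):
            atom.coord = xyz.copy()

    def transform(self, rotation: np.ndarray | None = None,
                  translation: np.ndarray | None = None) -> "StructureModel":
        """Return a rigidly transformed copy (rotation applied first)."""
        out = self.copy()
        coords = out.coords()
        if rotation is not None:
            coords = coords @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            coords = coords + np.asarray(translation, dtype=float)
        out.set_coords(coords)
        return out

    def copy(self) -> "StructureModel":
        return _copy.deepcopy(self)


@dataclass(frozen=True)
class SheetSpec:
    """Geometry of an idealized amyloid sheet stack.

    Strands run along Z; successive strands are offset along X by
    ``strand_spacing``.  Flipped strands are rotated 180 degrees about the
    X-axis, reversing their N->C direction to give antiparallel pairing.
    The default flip pattern alternates so that every adjacent pair is
    antiparallel; ``SheetSpec.literal_two_of_three()`` reproduces the
    alternative in which strands 2 and 3 of a 3-strand sheet are flipped.
    """

    n_strands: int = 3
    strand_spacing: float = 5.0
    flip_pattern: tuple | None = None
    core_phi: float = -135.0
    core_psi: float = 135.0

    def __post_init__(self):
        if self.n_strands < 1:
            raise ValueError("n_strands must be >= 1")
        if self.strand_spacing <= 0:
            raise ValueError("strand_spacing must be > 0")
        if self.flip_pattern is not None:
            pattern = tuple(bool(f) for f in self.flip_pattern)
            if len(pattern) != self.n_strands:
                raise ValueError("flip_pattern length must equal n_strands")
            object.__setattr__(self, "flip_pattern", pattern)

    @property
    def flips(self) -> tuple:
        if self.flip_pattern is not None:
            return self.flip_pattern
        return tuple(i % 2 == 1 for i in range(self.n_strands))

    @classmethod
    def literal_two_of_three(cls) -> "SheetSpec":
        return cls(n_strands=3, flip_pattern=(False, True, True))


# ---------------------------------------------------------------------------
# Internal-to-Cartesian placement (NeRF) and torsion measurement
# ---------------------------------------------------------------------------


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d bonded to c with |cd| = bond, angle(b,c,d) = angle and
    torsion(a,b,c,d) = torsion (degrees), via the natural extension
    reference frame."""
    theta = np.radians(angle)
    chi = np.radians(torsion)
    d_local = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(chi),
        bond * np.sin(theta) * np.sin(chi),
    ])
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-10:
        raise ValueError("reference atoms a, b, c are collinear; torsion frame undefined")
    n = n / norm
    m = np.cross(n, bc)
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion angle (degrees) of four points, IUPAC sign convention,
    in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return wrap_angle(float(np.degrees(np.arctan2(y, x))))


def _place_sidechain(res: Residue) -> None:
    ics = SIDECHAIN_ICS.get(res.name, ())
    for name, (ra, rb, rc), bond, angle, torsion in ics:
        res.add(name, place_atom(res[ra].coord, res[rb].coord, res[rc].coord,
                                 bond, angle, torsion))


def _finish_residue(res: Residue, psi: float, *, terminal_free: bool = False,
                    lengths: Mapping[str, float] = BOND_LENGTHS,
                    angles: Mapping[str, float] = BOND_ANGLES) -> None:
    """Place carbonyl O (and OXT on a free C-terminus), CB and functional
    side-chain atoms of a residue whose backbone N, CA, C already exist."""
    n, ca, c = res["N"].coord, res["CA"].coord, res["C"].coord
    res.add("O", place_atom(n, ca, c, lengths["C-O"], angles["CA-C-O"],
                            wrap_angle(psi + 180.0)))
    if terminal_free:
        res.add("OXT", place_atom(n, ca, c, lengths["C-OXT"], angles["CA-C-OXT"],
                                  wrap_angle(psi)))
    if res.name != "GLY":
        res.add("CB", place_atom(c, n, ca, lengths["CA-CB"], angles["N-CA-CB"],
                                 CB_IMPROPER))
        _place_sidechain(res)


def build_chain(sequence: str, geometry: BackboneGeometry,
                chain_id: str = "A", c_terminus: str = "free") -> StructureModel:
    """Build a single peptide chain from sequence and backbone torsions.

    Backbone atoms are placed sequentially by NeRF, so re-measuring any
    interior phi/psi from the output reproduces the input torsions.  The
    first residue seeds the frame (phi of residue 1 is undefined); the psi
    of the last residue orients its carbonyl/carboxylate.
    """
    _validate_sequence(sequence)
    if len(geometry) != len(sequence):
        raise ValueError(
            f"geometry supplies {len(geometry)} residues for a {len(sequence)}-mer"
        )
    if c_terminus not in ("free", "amidated"):
        raise ValueError(f"invalid c_terminus {c_terminus!r}")
    lengths, angles = geometry.bond_lengths, geometry.bond_angles

    residues = []
    # seed frame: N at origin, CA on +X, C in the XY plane
    n0 = np.zeros(3)
    ca0 = np.array([lengths["N-CA"], 0.0, 0.0])
    theta = np.radians(180.0 - angles["N-CA-C"])
    c0 = ca0 + lengths["CA-C"] * np.array([np.cos(theta), np.sin(theta), 0.0])
    prev = {"N": n0, "CA": ca0, "C": c0}
    for i, code in enumerate(sequence):
        res = Residue(ONE_TO_THREE[code], i + 1, {})
        if i == 0:
            res.add("N", prev["N"])
            res.add("CA", prev["CA"])
            res.add("C", prev["C"])
        else:
            n_i = place_atom(prev["N"], prev["CA"], prev["C"],
                             lengths["C-N"], angles["CA-C-N"], geometry.psi[i - 1])
            ca_i = place_atom(prev["CA"], prev["C"], n_i,
                              lengths["N-CA"], angles["C-N-CA"], geometry.omega[i - 1])
            c_i = place_atom(prev["C"], n_i, ca_i,
                             lengths["CA-C"], angles["N-CA-C"], geometry.phi[i])
            res.add("N", n_i)
            res.add("CA", ca_i)
            res.add("C", c_i)
        prev = {"N": res["N"].coord, "CA": res["CA"].coord, "C": res["C"].coord}
        residues.append(res)
    for i, res in enumerate(residues):
        last = i == len(residues) - 1
        _finish_residue(res, float(geometry.psi[i]),
                        terminal_free=last and c_terminus == "free",
                        lengths=lengths, angles=angles)
    return StructureModel([Chain(chain_id, residues)])


_DIHEDRAL_ATOMS = {
    "phi": (("prev", "C"), ("self", "N"), ("self", "CA"), ("self", "C")),
    "psi": (("self", "N"), ("self", "CA"), ("self", "C"), ("next", "N")),
    "omega": (("self", "CA"), ("self", "C"), ("next", "N"), ("next", "CA")),
}


def measure_dihedral(model: StructureModel, chain_id: str, seq_id: int,
                     which: str) -> float:
    """Measure a backbone dihedral (degrees) from model coordinates."""
    if which not in _DIHEDRAL_ATOMS:
        raise ValueError(f"which must be phi, psi or omega, got {which!r}")
    chain = model.chain(chain_id)
    index = {res.seq_id: i for i, res in enumerate(chain.residues)}
    if seq_id not in index:
        raise KeyError(f"no residue {seq_id} in chain {chain_id}")
    i = index[seq_id]
    points = []
    for where, atom_name in _DIHEDRAL_ATOMS[which]:
        j = i + {"prev": -1, "self": 0, "next": 1}[where]
        if j < 0 or j >= len(chain.residues):
            raise DihedralUndefinedError(
                f"undefined dihedral: {which} of terminal residue "
                f"{chain_id}/{seq_id} lacks a flanking residue"
            )
        res = chain.residues[j]
        if atom_name not in res:
            raise DihedralUndefinedError(
                f"undefined dihedral: atom {atom_name} missing in "
                f"{chain_id}/{res.seq_id}"
            )
        points.append(res[atom_name].coord)
    return dihedral(*points)


# ---------------------------------------------------------------------------
# Sheet assembly and N-terminal fusion
# ---------------------------------------------------------------------------


def _rotation_onto(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector u onto unit vector v (Rodrigues)."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    c = float(np.dot(u, v))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # u antiparallel to v: rotate pi about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, perp)
        axis /= np.linalg.norm(axis)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        return np.eye(3) + 2.0 * K @ K
    axis = axis / s
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def align_to_z(chain_model: StructureModel) -> StructureModel:
    """Center a single-chain model and rotate its CA principal axis onto +Z,
    with N->C pointing in the +Z direction."""
    if len(chain_model.chains) != 1:
        raise ValueError("align_to_z expects a single-chain model")
    ca = np.array([res["CA"].coord for res in chain_model.chains[0].residues])
    centroid = ca.mean(axis=0)
    centered = ca - centroid
    # dominant right singular vector = CA principal axis
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    rot = _rotation_onto(axis, np.array([0.0, 0.0, 1.0]))
    return chain_model.transform(rotation=rot, translation=None).transform(
        translation=-rot @ centroid
    )


#: 180-degree rotation about the X-axis (the strand flip).
FLIP_X = np.diag([1.0, -1.0, -1.0])

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def assemble_sheet(chain_model: StructureModel, spec: SheetSpec,
                   align: bool = True) -> StructureModel:
    """Stack rigid copies of a chain into an idealized beta-sheet.

    Strand ``i`` is the input chain, optionally flipped 180 degrees about X,
    then translated by ``i * strand_spacing`` along X.  Rigid motions only:
    every strand's internal geometry is identical to the input chain.
    """
    if len(chain_model.chains) != 1:
        raise ValueError("assemble_sheet expects a single-chain model")
    base = align_to_z(chain_model) if align else chain_model.copy()
    chains = []
    for i, flip in enumerate(spec.flips):
        strand = base.copy()
        coords = strand.coords()
        if flip:
            coords = coords @ FLIP_X.T
        coords = coords + np.array([i * spec.strand_spacing, 0.0, 0.0])
        strand.set_coords(coords)
        ch = strand.chains[0]
        ch.chain_id = _CHAIN_IDS[i % len(_CHAIN_IDS)]
        chains.append(ch)
    return StructureModel(chains)


def fuse_nterm(prefix, scaffold: StructureModel,
               prefix_geometry: BackboneGeometry,
               junction_phi: float = -135.0) -> StructureModel:
    """Fuse a peptide prefix onto the N-terminus of every scaffold chain.

    The prefix backbone is grown N-terminally from each chain's first
    residue by reverse NeRF, using the prefix phi/psi/omega plus
    ``junction_phi`` for the (previously undefined) phi of the scaffold's
    first residue.  Scaffold coordinates are untouched; residues are
    renumbered so the fused chain starts at 1.
    """
    sequence = prefix.sequence if isinstance(prefix, Construct) else str(prefix)
    if not sequence:
        raise ValueError("prefix must be non-empty")
    _validate_sequence(sequence)
    if len(prefix_geometry) != len(sequence):
        raise ValueError("prefix geometry length does not match prefix sequence")
    firsts = {ch.residues[0].seq_id for ch in scaffold.chains}
    if len(firsts) != 1:
        raise ValueError("scaffold chains do not share the same first residue position")

    lengths, angles = prefix_geometry.bond_lengths, prefix_geometry.bond_angles
    npfx = len(sequence)
    out_chains = []
    for ch in scaffold.chains:
        next_res = ch.residues[0]
        n_next = next_res["N"].coord
        ca_next = next_res["CA"].coord
        c_next = next_res["C"].coord
        phi_next = junction_phi
        new_residues: list = []
        for k in range(npfx - 1, -1, -1):  # prefix index, 0-based, N-terminal last
            res = Residue(ONE_TO_THREE[sequence[k]], k + 1, {})
            c_k = place_atom(c_next, ca_next, n_next,
                             lengths["C-N"], angles["C-N-CA"], phi_next)
            ca_k = place_atom(ca_next, n_next, c_k,
                              lengths["CA-C"], angles["CA-C-N"],
                              float(prefix_geometry.omega[k]))
            n_k = place_atom(n_next, c_k, ca_k,
                             lengths["N-CA"], angles["N-CA-C"],
                             float(prefix_geometry.psi[k]))
            res.add("N", n_k)
            res.add("CA", ca_k)
            res.add("C", c_k)
            new_residues.insert(0, res)
            n_next, ca_next, c_next = n_k, ca_k, c_k
            phi_next = float(prefix_geometry.phi[k])
        for k, res in enumerate(new_residues):
            _finish_residue(res, float(prefix_geometry.psi[k]),
                            terminal_free=False, lengths=lengths, angles=angles)
        old = _copy.deepcopy(ch.residues)
        for j, res in enumerate(old):
            res.seq_id = npfx + j + 1
        out_chains.append(Chain(ch.chain_id, new_residues + old))
    return StructureModel(out_chains)


# ---------------------------------------------------------------------------
# Construct bookkeeping
# ---------------------------------------------------------------------------


def apply_mutation(parent: Construct, position: int, to_residue: str) -> Construct:
    """Point substitution; records (position, from, to) and updates the sequence."""
    if to_residue not in ONE_TO_THREE:
        raise UnknownResidueError(f"unknown residue code {to_residue!r}")
    if not 1 <= position <= len(parent.sequence):
        raise ValueError(
            f"position {position} outside sequence of length {len(parent.sequence)}"
        )
    frm = parent.sequence[position - 1]
    if frm == to_residue:
        raise ValueError(f"no-op mutation {frm}{position}{to_residue}")
    seq = parent.sequence[:position - 1] + to_residue + parent.sequence[position:]
    return replace(parent, sequence=seq,
                   mutations=parent.mutations + ((position, frm, to_residue),))


def amidate_cterm(parent: Construct) -> Construct:
    """Convert the C-terminal carboxylate to a carboxamide (no OXT downstream,
    no C-terminal acid candidate)."""
    if parent.c_terminus == "amidated":
        raise ValueError(f"{parent.name} is already amidated")
    return replace(parent, c_terminus="amidated")


def load_registry() -> dict:
    """Load the shipped construct registry (name -> Construct)."""
    text = resources.files("triadscan.data").joinpath("constructs.yaml").read_text()
    raw = yaml.safe_load(text)
    registry: dict = {}
    for entry in raw["constructs"]:
        con = Construct(
            name=entry["name"],
            sequence=entry["base_sequence"],
            c_terminus="free",
            panel_id=entry.get("panel_id"),
            assembled=bool(entry.get("assembled", False)),
            note=entry.get("note", ""),
        )
        for pos, frm, to in entry.get("mutations", []) or []:
            if con.sequence[pos - 1] != frm:
                raise ValueError(
                    f"registry entry {con.name}: from-residue {frm} does not match "
                    f"parent sequence at position {pos}"
                )
            con = apply_mutation(con, pos, to)
        if entry.get("c_terminus", "free") == "amidated":
            con = amidate_cterm(con)
        if con.name in registry:
            raise ValueError(f"duplicate construct name {con.name!r}")
        registry[con.name] = con
    panel_ids = [c.panel_id for c in registry.values() if c.panel_id is not None]
    if len(panel_ids) != len(set(panel_ids)):
        raise ValueError("panel_id values must be unique within the registry")
    return registry


def get_construct(name: str) -> Construct:
    registry = load_registry()
    try:
        return registry[name]
    except KeyError:
        raise KeyError(
            f"unknown construct {name!r}; registry has {sorted(registry)}"
        ) from None


def build_construct_model(construct: Construct,
                          sheet_spec: SheetSpec | None = None,
                          core_length: int = len(ABETA_SEQUENCE)) -> StructureModel:
    """Build the idealized model for a construct.

    Monomeric constructs become a single chain in the amyloid beta-strand
    conformation.  Assembled constructs (or an explicit ``sheet_spec``) are
    built the way the fusion was modelled: the C-terminal amyloid core
    (last ``core_length`` residues) is built as a strand, stacked into the
    sheet, and the remaining N-terminal segment is fused onto every chain
    in the same extended conformation.
    """
    seq = construct.sequence
    if sheet_spec is None and not construct.assembled:
        return build_chain(seq, BackboneGeometry.amyloid(len(seq)),
                           c_terminus=construct.c_terminus)
    spec = sheet_spec or SheetSpec()
    if len(seq) <= core_length:
        raise ValueError("assembled construct must be longer than its amyloid core")
    core, prefix = seq[-core_length:], seq[:-core_length]
    core_geom = BackboneGeometry.uniform(core_length, spec.core_phi, spec.core_psi)
    chain = build_chain(core, core_geom, c_terminus=construct.c_terminus)
    sheet = assemble_sheet(chain, spec)
    prefix_geom = BackboneGeometry.uniform(len(prefix), spec.core_phi, spec.core_psi)
    return fuse_nterm(prefix, sheet, prefix_geom, junction_phi=spec.core_phi)


# ---------------------------------------------------------------------------
# Geometry audit
# ---------------------------------------------------------------------------


def iter_bonds(model: StructureModel):
    """Yield (description, measured length, table length) for every bond the
    builder places, for geometry-conservation checks."""
    for ch in model.chains:
        for i, res in enumerate(ch.residues):
            tag = f"{ch.chain_id}/{res.name}{res.seq_id}"
            yield f"{tag} N-CA", float(np.linalg.norm(res["CA"].coord - res["N"].coord)), BOND_LENGTHS["N-CA"]
            yield f"{tag} CA-C", float(np.linalg.norm(res["C"].coord - res["CA"].coord)), BOND_LENGTHS["CA-C"]
            if "O" in res:
                yield f"{tag} C-O", float(np.linalg.norm(res["O"].coord - res["C"].coord)), BOND_LENGTHS["C-O"]
            if "OXT" in res:
                yield f"{tag} C-OXT", float(np.linalg.norm(res["OXT"].coord - res["C"].coord)), BOND_LENGTHS["C-OXT"]
            if "CB" in res:
                yield f"{tag} CA-CB", float(np.linalg.norm(res["CB"].coord - res["CA"].coord)), BOND_LENGTHS["CA-CB"]
            for name, (_, _, rc), bond, _, _ in SIDECHAIN_ICS.get(res.name, ()):
                if name in res and rc in res:
                    yield (f"{tag} {rc}-{name}",
                           float(np.linalg.norm(res[name].coord - res[rc].coord)), bond)
            if i + 1 < len(ch.residues):
                nxt = ch.residues[i + 1]
                yield (f"{tag} C-N(+1)",
                       float(np.linalg.norm(nxt["N"].coord - res["C"].coord)),
                       BOND_LENGTHS["C-N"])
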