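"""Hydrolysis-competent catalytic triad detection and occupancy statistics.

A hydrolysis-competent structure is a conformation in which a hydroxyl-group
oxygen (Ser OG / Thr OG1), a histidine imidazole nitrogen (ND1 or NE2) and a
carboxylate oxygen (Glu OE1/OE2, Asp OD1/OD2, or the free C-terminal O/OXT)
lie mutually within a distance cutoff, default 5 Angstrom.  The default
``pair_mode="all"`` requires all three pairwise distances under the cutoff
(the strictest reading of the criterion); ``pair_mode="bridge"`` requires
only hydroxyl-His and His-acid, treating the histidine as the mandatory
relay of the charge network.

Triads are identified at residue level: a triad identity (e.g.
``A/S1-A/H10-B/F19ct``) is competent in a frame if ANY atom-level
combination of its candidate atoms passes, which prevents double counting
the two carboxylate oxygens or the two imidazole nitrogens.  Occupancy is
the fraction of analysis-window frames in which an identity is competent;
the "any triad" series is the per-frame indicator that at least one
identity is competent.  The default analysis window is the second half of
the trajectory (equilibration discarded, production kept).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .peptide_models import StructureModel, THREE_TO_ONE
from .trajectory_io import Trajectory

__all__ = [
    "ResidueRef",
    "CandidateAtom",
    "CandidateSets",
    "Triad",
    "TriadOccupancy",
    "DEFAULT_CUTOFF",
    "enumerate_candidates",
    "detect_triads_frame",
    "occupancy",
    "rank_triads",
]

DEFAULT_CUTOFF = 5.0

HYDROXYL_ATOMS = {"SER": ("OG",), "THR": ("OG1",)}
HIS_ATOMS = {"HIS": ("ND1", "NE2")}
SIDECHAIN_ACID_ATOMS = {"GLU": ("OE1", "OE2"), "ASP": ("OD1", "OD2")}
CTERM_ACID_ATOMS = ("O", "OXT")


class ResidueRef(NamedTuple):
    """Residue-level identity of one triad member."""

    chain_id: str
    res_id: int
    res_name: str
    role: str  # "hydroxyl" | "his" | "acid" | "cterm"

    @property
    def label(self) -> str:
        one = THREE_TO_ONE.get(self.res_name, "X")
        suffix = "ct" if self.role == "cterm" else ""
        return f"{self.chain_id}/{one}{self.res_id}{suffix}"


class CandidateAtom(NamedTuple):
    index: int          # atom index in topology order
    residue: ResidueRef
    atom_name: str


@dataclass(frozen=True)
class CandidateSets:
    """The three candidate atom classes of the triad criterion.

    Amidated chains (no OXT on the last residue) contribute no C-terminal
    acid oxygens; their terminal carbonyl O is an amide oxygen, not a
    carboxylate.
    """

    hydroxyl_O: tuple
    his_N: tuple
    acid_O: tuple

    def __post_init__(self):
        all_idx = [a.index for group in (self.hydroxyl_O, self.his_N, self.acid_O)
                   for a in group]
        if len(all_idx) != len(set(all_idx)):
            raise ValueError("candidate sets must be pairwise disjoint")

    def counts(self) -> tuple:
        return (len(self.hydroxyl_O), len(self.his_N), len(self.acid_O))

    def per_chain_counts(self) -> Mapping[str, tuple]:
        chains: dict = {}
        for role_i, group in enumerate((self.hydroxyl_O, self.his_N, self.acid_O)):
            for atom in group:
                counts = chains.setdefault(atom.residue.chain_id, [0, 0, 0])
                counts[role_i] += 1
        return {cid: tuple(c) for cid, c in chains.items()}


@dataclass(frozen=True, order=True)
class Triad:
    """Residue-level triad identity (hydroxyl, histidine, acid)."""

    hydroxyl: ResidueRef
    his: ResidueRef
    acid: ResidueRef

    @property
    def label(self) -> str:
        return f"{self.hydroxyl.label}-{self.his.label}-{self.acid.label}"

    @property
    def is_cross_chain(self) -> bool:
        chains = {self.hydroxyl.chain_id, self.his.chain_id, self.acid.chain_id}
        return len(chains) > 1


@dataclass(frozen=True)
class TriadOccupancy:
    """Per-frame competent-triad sets and per-identity occupancy fractions."""

    cutoff: float
    per_frame: tuple                 # tuple of frozenset[Triad]
    fractions: Mapping[Triad, float]
    n_frames: int
    window_ps: tuple                 # (start, end), half-open
    any_fraction: float

    def any_series(self) -> np.ndarray:
        return np.array([1 if frame else 0 for frame in self.per_frame], dtype=int)


def _chain_is_free(chain) -> bool:
    return "OXT" in chain.residues[-1]


def enumerate_candidates(topology: StructureModel) -> CandidateSets:
    """Enumerate hydroxyl / imidazole / carboxylate candidate atoms.

    Deterministic topology order.  Empty sets are permitted (e.g.
    poly-alanine yields three empty sets).
    """
    hydroxyl, his, acid = [], [], []
    index = 0
    for ch in topology.chains:
        free = _chain_is_free(ch)
        last_id = ch.residues[-1].seq_id
        for res in ch.residues:
            for atom_name in res.atoms:
                if atom_name in HYDROXYL_ATOMS.get(res.name, ()):
                    hydroxyl.append(CandidateAtom(
                        index, ResidueRef(ch.chain_id, res.seq_id, res.name, "hydroxyl"),
                        atom_name))
                elif atom_name in HIS_ATOMS.get(res.name, ()):
                    his.append(CandidateAtom(
                        index, ResidueRef(ch.chain_id, res.seq_id, res.name, "his"),
                        atom_name))
                elif atom_name in SIDECHAIN_ACID_ATOMS.get(res.name, ()):
                    acid.append(CandidateAtom(
                        index, ResidueRef(ch.chain_id, res.seq_id, res.name, "acid"),
                        atom_name))
                elif (free and res.seq_id == last_id
                      and atom_name in CTERM_ACID_ATOMS):
                    acid.append(CandidateAtom(
                        index, ResidueRef(ch.chain_id, res.seq_id, res.name, "cterm"),
                        atom_name))
                index += 1
    return CandidateSets(tuple(hydroxyl), tuple(his), tuple(acid))


def _restrict(triad: Triad, chain_mode: str) -> bool:
    if chain_mode == "any":
        return True
    if chain_mode == "intra":
        return not triad.is_cross_chain
    if chain_mode == "cross":
        return triad.is_cross_chain
    raise ValueError(f"chain_mode must be any/intra/cross, got {chain_mode!r}")


def detect_triads_frame(coords: np.ndarray, candidates: CandidateSets,
                        cutoff: float = DEFAULT_CUTOFF,
                        pair_mode: str = "all",
                        chain_mode: str = "any") -> frozenset:
    """Detect competent triad identities in one coordinate frame.

    ``coords`` is the full-topology (n_atoms, 3) array the candidate indices
    refer to.  Neighbor search uses a k-d tree over the candidate atoms;
    triples are assembled from the within-cutoff pair lists.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if pair_mode not in ("all", "bridge"):
        raise ValueError(f"pair_mode must be 'all' or 'bridge', got {pair_mode!r}")
    coords = np.asarray(coords, dtype=float)
    atoms = list(candidates.hydroxyl_O) + list(candidates.his_N) + list(candidates.acid_O)
    if not atoms:
        return frozenset()
    max_index = max(a.index for a in atoms)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] <= max_index:
        raise ValueError(
            f"coordinate array of shape {coords.shape} does not cover candidate "
            f"atom index {max_index}"
        )
    n_h = len(candidates.hydroxyl_O)
    n_n = len(candidates.his_N)
    roles = np.array([0] * n_h + [1] * n_n + [2] * len(candidates.acid_O))
    pts = coords[[a.index for a in atoms]]
    tree = cKDTree(pts)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    # adjacency restricted to the role pairs the criterion needs
    his_of_h: dict = {}
    acid_of_n: dict = {}
    ha_ok: set = set()
    for a, b in pairs:
        ra, rb = roles[a], roles[b]
        if ra > rb:
            a, b, ra, rb = b, a, rb, ra
        if (ra, rb) == (0, 1):
            his_of_h.setdefault(a, []).append(b)
        elif (ra, rb) == (1, 2):
            acid_of_n.setdefault(a, []).append(b)
        elif (ra, rb) == (0, 2):
            ha_ok.add((a, b))
    found = set()
    for h, his_list in his_of_h.items():
        for n in his_list:
            for a in acid_of_n.get(n, ()):
                if pair_mode == "all" and (h, a) not in ha_ok:
                    continue
                triad = Triad(atoms[h].residue, atoms[n].residue, atoms[a].residue)
                if _restrict(triad, chain_mode):
                    found.add(triad)
    return frozenset(found)


def occupancy(trajectory: Trajectory,
              candidates: CandidateSets | None = None,
              cutoff: float = DEFAULT_CUTOFF,
              window_ps: tuple | None = None,
              pair_mode: str = "all",
              chain_mode: str = "any") -> TriadOccupancy:
    """Per-identity occupancy fractions over an analysis window.

    ``window_ps`` is a half-open interval [start, end) in trajectory time;
    the default keeps the second half of the trajectory (production window
    after discarding the first half as equilibration).
    """
    t0, t1 = trajectory.extent_ps
    if window_ps is None:
        window_ps = ((t0 + t1) / 2.0, t1)
    start, end = map(float, window_ps)
    if not (t0 <= start < end <= t1):
        raise ValueError(
            f"window [{start}, {end}) ps empty or outside trajectory extent "
            f"[{t0}, {t1}) ps"
        )
    if candidates is None:
        candidates = enumerate_candidates(trajectory.topology)
    times = trajectory.times_ps
    mask = (times >= start) & (times < end)
    frame_ids = np.nonzero(mask)[0]
    if frame_ids.size == 0:
        raise ValueError("analysis window contains no frames")
    per_frame = tuple(
        detect_triads_frame(trajectory.frames[i], candidates, cutoff,
                            pair_mode=pair_mode, chain_mode=chain_mode)
        for i in frame_ids
    )
    counts: dict = {}
    for frame in per_frame:
        for triad in frame:
            counts[triad] = counts.get(triad, 0) + 1
    n = len(per_frame)
    fractions = {triad: c / n for triad, c in counts.items()}
    any_fraction = sum(1 for frame in per_frame if frame) / n
    return TriadOccupancy(cutoff=cutoff, per_frame=per_frame,
                          fractions=fractions, n_frames=n,
                          window_ps=(start, end), any_fraction=any_fraction)


def rank_triads(occ: TriadOccupancy, top_k: int | None = None) -> list:
    """Triad identities sorted by occupancy (descending), ties broken by
    lexicographic identity label.  An ensemble with no competent triads
    yields an empty list (an explicit 'no competent triads' result)."""
    ranked = sorted(occ.fractions.items(), key=lambda kv: (-kv[1], kv[0].label))
    if top_k is not None:
        ranked = ranked[:max(0, int(top_k))]
    return ranked
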