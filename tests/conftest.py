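"""Shared fixtures: built models, candidate sets, and an exhaustive
triple-loop triad oracle kept independent of the package's k-d-tree path."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from triadscan import peptide_models as pm
from triadscan import triad_analysis as ta


@pytest.fixture(scope="session")
def cp4ab():
    return pm.get_construct("CP4-AB")


@pytest.fixture(scope="session")
def sheet_model(cp4ab):
    """Three-strand antiparallel CP4-Abeta assembly, free C-termini."""
    return pm.build_construct_model(cp4ab)


@pytest.fixture(scope="session")
def sheet_candidates(sheet_model):
    return ta.enumerate_candidates(sheet_model)


@pytest.fixture()
def she_model():
    """Minimal Ser-His-Glu chain: one atom class of each triad role plus a
    free C-terminus, small enough to hand-position."""
    return pm.build_chain("SHE", pm.BackboneGeometry.amyloid(3))


@pytest.fixture(scope="session")
def planted_triad():
    """The dominant cross-chain triad: S1 and H10 of chain A with the
    amyloid C-terminus of adjacent chain B."""
    return ta.Triad(
        hydroxyl=ta.ResidueRef("A", 1, "SER", "hydroxyl"),
        his=ta.ResidueRef("A", 10, "HIS", "his"),
        acid=ta.ResidueRef("B", 19, "PHE", "cterm"),
    )


def exhaustive_triads(coords, candidates, cutoff, pair_mode="all"):
    """O(n^3) reference detector: plain Python triple loop over atom-level
    combinations, collapsed to residue-level identities."""
    found = set()
    for h in candidates.hydroxyl_O:
        for n in candidates.his_N:
            for a in candidates.acid_O:
                d_hn = np.linalg.norm(coords[h.index] - coords[n.index])
                d_na = np.linalg.norm(coords[n.index] - coords[a.index])
                d_ha = np.linalg.norm(coords[h.index] - coords[a.index])
                ok = d_hn <= cutoff and d_na <= cutoff
                if pair_mode == "all":
                    ok = ok and d_ha <= cutoff
                if ok:
                    found.add(ta.Triad(h.residue, n.residue, a.residue))
    return frozenset(found)


def random_candidates(n_res_per_role=10, atoms_per_res=2):
    """Synthetic candidate sets: several residues per role, two atoms each,
    to exercise the identity-level (any-atom-combination) semantics."""
    roles = [("hydroxyl", ("OG", "OG1")),
             ("his", ("ND1", "NE2")),
             ("acid", ("OE1", "OE2"))]
    groups = {"hydroxyl": [], "his": [], "acid": []}
    index = 0
    res_id = 1
    for role, atom_names in roles:
        for _ in range(n_res_per_role):
            ref = ta.ResidueRef("A", res_id, {"hydroxyl": "SER",
                                              "his": "HIS",
                                              "acid": "GLU"}[role], role)
            for name in atom_names[:atoms_per_res]:
                groups[role].append(ta.CandidateAtom(index, ref, name))
                index += 1
            res_id += 1
    return ta.CandidateSets(tuple(groups["hydroxyl"]), tuple(groups["his"]),
                            tuple(groups["acid"]))
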