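"""First coordination sphere detection and vacancy dummy placement.

A metal with an open coordination site can bind a protein residue directly.
To make that interaction directional in an AutoDock-style force field, a
zero-charge, zero-parameter dummy atom (type DD) is placed at the vacant
site; scoring then weights the metal-acceptor hydrogen-bond-like well by the
angle to the metal->dummy axis, exactly as donor hydrogens direct ordinary
hydrogen bonds.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mol_model import Atom, Ligand, MoleculeError
from .periodic import covalent_radius, is_metal
from .mol_model import DATIVE_BOND_FACTOR

__all__ = ["CoordinationSphere", "detect_sphere", "place_dummy", "add_vacancy_dummy",
           "DEFAULT_DUMMY_BOND_LENGTH", "BALANCED_SPHERE_THRESHOLD"]

DEFAULT_DUMMY_BOND_LENGTH = 2.0   # Å, typical first-sphere metal-donor distance
BALANCED_SPHERE_THRESHOLD = 0.2   # |sum of unit vectors| below this = balanced sphere


@dataclass
class CoordinationSphere:
    metal_index: int
    ligating_atom_indices: list[int]
    ligand_unit_vectors: np.ndarray  # (CN, 3) metal->ligator unit vectors

    @property
    def coordination_number(self) -> int:
        return len(self.ligating_atom_indices)


def detect_sphere(ligand: Ligand) -> CoordinationSphere:
    """Find the non-hydrogen atoms datively bonded to the metal.

    Uses the dative distance criterion (1.25 x covalent radius sum); ligators
    are sorted by distance. Coordination numbers outside 2-6 are rejected with
    the measured distances in the message.
    """
    if ligand.metal_index is None:
        raise MoleculeError("ligand has no metal atom")
    m = ligand.atoms[ligand.metal_index]
    rm = covalent_radius(m.element)
    entries = []
    for a in ligand.atoms:
        if a.index == m.index or a.is_dummy or a.element == "H":
            continue
        d = float(np.linalg.norm(a.coords - m.coords))
        if d < DATIVE_BOND_FACTOR * (rm + covalent_radius(a.element)):
            entries.append((d, a.index))
    entries.sort()
    cn = len(entries)
    if cn < 2 or cn > 6:
        dists = ", ".join(f"{i}:{d:.2f} Å" for d, i in entries) or "none"
        raise MoleculeError(
            f"coordination number {cn} outside the supported 2-6 range "
            f"(ligator distances: {dists})")
    idx = [i for _, i in entries]
    vecs = np.array([ligand.atoms[i].coords - m.coords for i in idx])
    vecs = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
    return CoordinationSphere(metal_index=m.index, ligating_atom_indices=idx,
                              ligand_unit_vectors=vecs)


def _balanced_sphere_direction(ligand: Ligand, sphere: CoordinationSphere) -> np.ndarray:
    """Vacancy direction for a geometrically balanced sphere (square planar,
    octahedral): the best-fit-plane normal of the ligator directions, pointing
    into the half-space holding fewer ligand atoms; on a tie the sign making
    the first non-zero component positive."""
    vecs = sphere.ligand_unit_vectors
    # plane through the origin (metal): normal = least-variance direction
    _, s, vt = np.linalg.svd(vecs, full_matrices=False)
    if s[-1] > 0.5 * s[0] and len(vecs) >= 6:
        raise MoleculeError(
            "coordination sphere is saturated and isotropic; no vacancy "
            "direction is defined — set vacant_site=false")
    normal = vt[-1]
    metal_pos = ligand.atoms[sphere.metal_index].coords
    above = below = 0
    for a in ligand.atoms:
        if a.index == sphere.metal_index or a.is_dummy:
            continue
        h = float((a.coords - metal_pos) @ normal)
        if h > 1e-9:
            above += 1
        elif h < -1e-9:
            below += 1
    if above > below:
        normal = -normal
    elif above == below:
        for comp in normal:
            if abs(comp) > 1e-12:
                if comp < 0:
                    normal = -normal
                break
    return normal / np.linalg.norm(normal)


def place_dummy(ligand: Ligand, sphere: CoordinationSphere | None = None,
                bond_length: float = DEFAULT_DUMMY_BOND_LENGTH) -> Ligand:
    """Append the vacancy dummy atom along the open coordination direction.

    The direction is the normalized negative sum of the metal->ligator unit
    vectors; when that sum nearly vanishes (balanced sphere) the best-fit
    plane normal is used instead. Idempotent: an existing dummy is left
    untouched.
    """
    if ligand.dummy_index is not None:
        return ligand
    if sphere is None:
        sphere = detect_sphere(ligand)
    if sphere.coordination_number > 6:
        raise MoleculeError("cannot place a vacancy dummy beyond 6-coordination")
    total = sphere.ligand_unit_vectors.sum(axis=0)
    norm = float(np.linalg.norm(total))
    if norm < BALANCED_SPHERE_THRESHOLD:
        if sphere.coordination_number >= 6:
            raise MoleculeError(
                "6-coordinate balanced sphere has no vacant site; "
                "set vacant_site=false")
        v = _balanced_sphere_direction(ligand, sphere)
    else:
        v = -total / norm
    metal = ligand.atoms[sphere.metal_index]
    dummy = Atom(index=len(ligand.atoms), element="DD",
                 coords=metal.coords + bond_length * v,
                 partial_charge=0.0, ad_type="DD")
    ligand.atoms.append(dummy)
    ligand.dummy_index = dummy.index
    ligand.bonds.append((metal.index, dummy.index, 1.0))
    return ligand


def add_vacancy_dummy(ligand: Ligand, vacant_site: bool = True,
                      bond_length: float = DEFAULT_DUMMY_BOND_LENGTH) -> Ligand:
    """Config-level entry point: with ``vacant_site`` false the ligand is
    returned unchanged (no dummy, isotropic metal interactions)."""
    if not vacant_site:
        return ligand
    return place_dummy(ligand, bond_length=bond_length)
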