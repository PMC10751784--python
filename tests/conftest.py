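"""Shared fixtures: small molecules built in memory and written to tmp files."""
from __future__ import annotations

import numpy as np
import pytest

from coordock.atom_typing import assign_types, build_torsion_tree
from coordock.mol_model import Atom, Ligand, perceive_bonds


def build_ligand(rows, bonds=None) -> Ligand:
    """rows: (element, x, y, z[, charge]) tuples."""
    atoms = []
    for i, row in enumerate(rows):
        el, x, y, z = row[:4]
        q = row[4] if len(row) > 4 else 0.0
        atoms.append(Atom(index=i, element=el, coords=np.array([x, y, z]),
                          partial_charge=q))
    lig = Ligand(atoms=atoms)
    lig.bonds = bonds if bonds is not None else perceive_bonds(atoms)
    return lig


@pytest.fixture
def water() -> Ligand:
    return build_ligand([
        ("O", 0.000, 0.000, 0.117, -0.834),
        ("H", 0.000, 0.757, -0.467, 0.417),
        ("H", 0.000, -0.757, -0.467, 0.417),
    ])


@pytest.fixture
def methane() -> Ligand:
    r = 1.089 / np.sqrt(3)
    return build_ligand([
        ("C", 0, 0, 0),
        ("H", r, r, r), ("H", r, -r, -r), ("H", -r, r, -r), ("H", -r, -r, r),
    ])


@pytest.fixture
def benzene() -> Ligand:
    rows = []
    for k in range(6):
        a = np.pi / 3 * k
        rows.append(("C", 1.397 * np.cos(a), 1.397 * np.sin(a), 0.0))
    for k in range(6):
        a = np.pi / 3 * k
        rows.append(("H", 2.481 * np.cos(a), 2.481 * np.sin(a), 0.0))
    return build_ligand(rows)


@pytest.fixture
def imidazole() -> Ligand:
    # ring: N1(-H), C2, N3 (pyridine-type), C4, C5; experimental-ish geometry
    return build_ligand([
        ("N", -1.113, 0.651, 0.0),   # N1, carries H
        ("C", -1.202, -0.718, 0.0),  # C2
        ("N", 0.024, -1.242, 0.0),   # N3, acceptor
        ("C", 0.917, -0.214, 0.0),   # C4
        ("C", 0.230, 0.967, 0.0),    # C5
        ("H", -1.863, 1.319, 0.0),   # on N1
        ("H", -2.123, -1.281, 0.0),
        ("H", 1.990, -0.332, 0.0),
        ("H", 0.545, 1.999, 0.0),
    ])


@pytest.fixture
def butane() -> Ligand:
    # heavy-atom n-butane, zigzag
    return build_ligand([
        ("C", 0.00, 0.00, 0.0),
        ("C", 1.52, 0.00, 0.0),
        ("C", 2.05, 1.42, 0.0),
        ("C", 3.57, 1.42, 0.0),
    ])


@pytest.fixture
def typed(request):
    def _typed(lig: Ligand) -> Ligand:
        assign_types(lig)
        lig.torsion_tree = build_torsion_tree(lig)
        return lig
    return _typed
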