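"""AutoDock-style atom typing and torsion-tree construction.

The type alphabet mirrors the seven protein types (C, A, HD, N, NA, OA, SA)
plus non-polar hydrogen H, the metal's own element symbol, and DD for the
vacancy dummy. Rules are deterministic functions of the element and the bond
graph:

* H bonded to N/O/S -> HD (hydrogen-bond donor), otherwise H
* C in a detected aromatic ring -> A, otherwise C
* N with no bound hydrogen and fewer than three heavy neighbours -> NA
  (lone pair available to accept), otherwise N
* O -> OA, S -> SA (always treated as acceptors)
* metal -> its element symbol; DD stays DD
"""
from __future__ import annotations

import numpy as np
import networkx as nx

from .mol_model import Atom, Ligand, MoleculeError, Receptor, TorsionTree
from .periodic import is_metal

__all__ = ["assign_types", "build_torsion_tree", "build_torsion_tree_from_bonds",
           "aromatic_atoms", "apply_torsions"]

PLANARITY_TOL = 0.15  # Å, max out-of-plane deviation for an aromatic ring


def _bond_graph(mol: Ligand | Receptor, bonds=None) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(a.index for a in mol.atoms)
    src = bonds if bonds is not None else getattr(mol, "bonds", [])
    g.add_edges_from((a, b) for a, b, *_ in src)
    return g


def aromatic_atoms(mol: Ligand | Receptor, bonds=None) -> set[int]:
    """Indices of atoms in aromatic rings.

    A ring (from the cycle basis) counts as aromatic when it has 5 or 6
    members, consists of C/N/O/S only, every member has at most three
    neighbours (sp2-compatible), and the ring is planar to ``PLANARITY_TOL``.
    """
    g = _bond_graph(mol, bonds)
    atom_of = {a.index: a for a in mol.atoms}
    out: set[int] = set()
    for ring in nx.cycle_basis(g):
        if len(ring) not in (5, 6):
            continue
        if any(atom_of[i].element not in ("C", "N", "O", "S") for i in ring):
            continue
        if any(g.degree(i) > 3 for i in ring):
            continue
        pts = np.array([atom_of[i].coords for i in ring])
        centered = pts - pts.mean(axis=0)
        # smallest singular direction = plane normal; residual = out-of-plane spread
        _, s, _ = np.linalg.svd(centered, full_matrices=False)
        if s[-1] / np.sqrt(len(ring)) < PLANARITY_TOL:
            out.update(ring)
    return out


def assign_types(mol: Ligand | Receptor) -> Ligand | Receptor:
    """Assign an AutoDock-style type to every atom, in place; returns ``mol``.

    Idempotent; raises for elements without a rule.
    """
    bonds = getattr(mol, "bonds", None)
    if bonds is None or (not bonds and len(mol.atoms) > 1):
        from .mol_model import perceive_bonds
        bonds = perceive_bonds(mol.atoms)
        if isinstance(mol, Ligand):
            mol.bonds = bonds
    g = _bond_graph(mol, bonds)
    atom_of = {a.index: a for a in mol.atoms}
    aromatic = aromatic_atoms(mol, bonds)
    for a in mol.atoms:
        el = a.element
        nbr_elements = [atom_of[j].element for j in g.neighbors(a.index)]
        if a.is_dummy:
            a.ad_type = "DD"
        elif is_metal(el):
            a.ad_type = el
        elif el == "H":
            a.ad_type = "HD" if any(e in ("N", "O", "S") for e in nbr_elements) else "H"
        elif el == "C":
            a.ad_type = "A" if a.index in aromatic else "C"
        elif el == "N":
            has_h = any(e == "H" for e in nbr_elements)
            heavy = sum(1 for e in nbr_elements if e not in ("H", "DD"))
            a.ad_type = "NA" if (not has_h and heavy < 3) else "N"
        elif el == "O":
            a.ad_type = "OA"
        elif el == "S":
            a.ad_type = "SA"
        elif el in ("P", "F", "Cl", "Br", "I", "B", "Si", "Se"):
            a.ad_type = el  # halogens/phosphorus keep their element symbol
        else:
            raise MoleculeError(f"no typing rule for element {el!r} (atom {a.index})")
    return mol


# ---------------------------------------------------------------------------
# torsion tree
# ---------------------------------------------------------------------------

def _first_sphere(lig: Ligand, g: nx.Graph) -> set[int]:
    if lig.metal_index is None:
        return set()
    sphere = {lig.metal_index}
    sphere.update(g.neighbors(lig.metal_index))
    return sphere


def _is_amide(lig: Ligand, g: nx.Graph, i: int, j: int) -> bool:
    atom_of = {a.index: a for a in lig.atoms}
    for c, n in ((i, j), (j, i)):
        if atom_of[c].element == "C" and atom_of[n].element == "N":
            for k in g.neighbors(c):
                if k != n and atom_of[k].element == "O" and g.degree(k) == 1:
                    return True
    return False


def rotatable_bonds(lig: Ligand) -> list[tuple[int, int]]:
    """Acyclic single bonds between non-terminal heavy atoms, excluding amide
    bonds and any bond touching the metal or its first coordination sphere."""
    g = _bond_graph(lig)
    atom_of = {a.index: a for a in lig.atoms}
    rigid_core = _first_sphere(lig, g)
    cyc = set()
    for ring in nx.cycle_basis(g):
        ring_edges = {frozenset(e) for e in zip(ring, ring[1:] + ring[:1])}
        cyc.update(ring_edges)
    out = []
    for a, b, order in lig.bonds:
        if order != 1.0 or frozenset((a, b)) in cyc:
            continue
        if a in rigid_core or b in rigid_core:
            continue
        if lig.metal_index in (a, b) or lig.dummy_index in (a, b):
            continue
        # non-terminal heavy atoms on both ends
        def heavy_degree(i: int) -> int:
            return sum(1 for k in g.neighbors(i)
                       if atom_of[k].element not in ("H", "DD"))
        if atom_of[a].element in ("H", "DD") or atom_of[b].element in ("H", "DD"):
            continue
        if heavy_degree(a) < 2 or heavy_degree(b) < 2:
            continue
        if _is_amide(lig, g, a, b):
            continue
        out.append((min(a, b), max(a, b)))
    return sorted(out)


def _distal_set(g: nx.Graph, anchor: int, pivot: int) -> set[int]:
    h = g.copy()
    h.remove_edge(anchor, pivot)
    comp = nx.node_connected_component(h, pivot)
    return set(comp)


def build_torsion_tree(lig: Ligand, root: int | None = None) -> TorsionTree:
    """Build the rotatable-bond tree used by the docking genome.

    The root is the atom minimizing the largest distal subtree over all
    rotatable bonds (removal-balanced), lowest index on ties. Errors out
    beyond 10 rotatable bonds — GA search degrades past that point.
    """
    rot = rotatable_bonds(lig)
    if len(rot) > 10:
        raise MoleculeError(f"{len(rot)} rotatable bonds exceed the supported maximum of 10")
    return build_torsion_tree_from_bonds(lig, rot, root=root)


def build_torsion_tree_from_bonds(lig: Ligand, rot: list[tuple[int, int]],
                                  root: int | None = None) -> TorsionTree:
    g = _bond_graph(lig)
    real = [a.index for a in lig.atoms if not a.is_dummy]
    if root is None:
        if not rot:
            root = lig.metal_index if lig.metal_index is not None else min(real)
        else:
            best = (float("inf"), None)
            for cand in real:
                worst = 0
                for a, b in rot:
                    distal = _distal_set(g, a, b) if cand not in _distal_set(g, a, b) \
                        else _distal_set(g, b, a)
                    worst = max(worst, len(distal))
                if (worst, cand) < best:
                    best = (worst, cand)
            root = best[1]
    tree = TorsionTree(root=root)
    # orient each rotatable bond away from the root and order root-outward
    oriented = []
    for a, b in rot:
        if root in _distal_set(g, a, b):
            a, b = b, a
        oriented.append((a, b, len(nx.shortest_path(g, root, a))))
    oriented.sort(key=lambda t: (t[2], t[0], t[1]))
    for a, b, _ in oriented:
        moving = sorted(_distal_set(g, a, b))
        # the dummy rides with the metal; keep it out of torsion moving sets
        if lig.dummy_index in moving:
            moving.remove(lig.dummy_index)
        tree.bonds.append((a, b))
        tree.moving_sets.append(np.array(moving, dtype=int))
    return tree


def apply_torsions(coords: np.ndarray, tree: TorsionTree,
                   angles: np.ndarray) -> np.ndarray:
    """Rotate each distal subtree about its bond axis by the given angle (rad).

    Applied root-outward so parent rotations carry child branches along.
    Returns new coordinates; the input is not modified.
    """
    out = coords.copy()
    for (anchor, pivot), moving, ang in zip(tree.bonds, tree.moving_sets, angles):
        if ang == 0.0 or len(moving) == 0:
            continue
        axis = out[pivot] - out[anchor]
        n = np.linalg.norm(axis)
        if n < 1e-12:
            continue
        axis = axis / n
        c, s = np.cos(ang), np.sin(ang)
        k = axis
        rel = out[moving] - out[pivot]
        # Rodrigues rotation, vectorized over the moving set
        out[moving] = (rel * c + np.cross(k, rel) * s
                       + np.outer(rel @ k, k) * (1 - c)) + out[pivot]
    return out
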