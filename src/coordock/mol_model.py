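"""Molecular data model and file IO for XYZ, PDB and PDBQT.

The in-memory containers are deliberately small: an :class:`Atom` carries the
element, Cartesian coordinates (Å), a partial charge (e) and an AutoDock-style
atom type; a :class:`Ligand` adds a bond graph, the metal/dummy bookkeeping and
the torsion tree; a :class:`Receptor` is a rigid typed atom set.

XYZ files may carry an extra numeric column holding per-atom partial charges
(quantum-derived charges are ingested, never computed here). PDB files are read
through gemmi; PDBQT (AutoDock dialect with ROOT/BRANCH torsion blocks) is
written and parsed directly since no installed library understands the torsion
tree records.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .periodic import COVALENT_RADII, covalent_radius, is_metal

logger = logging.getLogger(__name__)

__all__ = [
    "Atom", "Ligand", "Receptor", "TorsionTree",
    "MoleculeError", "ParseError",
    "read_xyz", "write_xyz", "read_pdb", "write_pdb",
    "read_pdbqt", "write_pdbqt", "perceive_bonds",
]

BOND_FACTOR = 1.15          # covalent bond: d < 1.15 (r_i + r_j)
DATIVE_BOND_FACTOR = 1.25   # metal-ligand dative bonds are longer

WATER_RESNAMES = {"HOH", "WAT", "H2O", "DOD", "TIP", "TIP3"}


class MoleculeError(ValueError):
    """Invalid molecular data."""


class ParseError(MoleculeError):
    """Malformed input file."""


@dataclass
class Atom:
    index: int
    element: str
    coords: np.ndarray
    partial_charge: float = 0.0
    ad_type: str | None = None
    residue_tag: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise MoleculeError(f"atom {self.index}: coordinates must be a finite 3-vector")
        if self.element != "DD" and self.element not in COVALENT_RADII:
            raise MoleculeError(f"atom {self.index}: unrecognized element {self.element!r}")
        if self.element == "DD" and self.partial_charge != 0.0:
            raise MoleculeError("dummy atoms carry exactly zero charge")

    @property
    def is_dummy(self) -> bool:
        return self.element == "DD"


@dataclass
class TorsionTree:
    """Rotatable-bond tree: ``bonds[k] = (anchor, pivot)`` with the atoms distal
    to the pivot listed in ``moving_sets[k]``; bonds are ordered root-outward so
    torsions can be applied sequentially."""

    root: int
    bonds: list[tuple[int, int]] = field(default_factory=list)
    moving_sets: list[np.ndarray] = field(default_factory=list)

    @property
    def n_torsions(self) -> int:
        return len(self.bonds)


@dataclass
class Ligand:
    atoms: list[Atom]
    bonds: list[tuple[int, int, float]] = field(default_factory=list)
    metal_index: int | None = None
    dummy_index: int | None = None
    torsion_tree: TorsionTree | None = None

    def __post_init__(self) -> None:
        if self.metal_index is None:
            metals = [a.index for a in self.atoms if is_metal(a.element)]
            if len(metals) == 1:
                self.metal_index = metals[0]
        dummies = [a.index for a in self.atoms if a.is_dummy]
        if len(dummies) > 1:
            raise MoleculeError("at most one vacancy dummy atom is allowed")
        if dummies:
            self.dummy_index = dummies[0]

    # -- convenience views -------------------------------------------------
    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        for atom, xyz in zip(self.atoms, coords):
            atom.coords = xyz

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms])

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def heavy_indices(self, include_metal: bool = True) -> list[int]:
        out = []
        for a in self.atoms:
            if a.is_dummy or a.element == "H":
                continue
            if not include_metal and is_metal(a.element):
                continue
            out.append(a.index)
        return out

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b, _ in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def validate(self) -> None:
        """Check the structural invariants (connectivity, dummy bookkeeping)."""
        import networkx as nx

        g = nx.Graph()
        real = [a.index for a in self.atoms if not a.is_dummy]
        g.add_nodes_from(real)
        g.add_edges_from((a, b) for a, b, _ in self.bonds
                         if self.dummy_index not in (a, b))
        if real and not nx.is_connected(g):
            raise MoleculeError("ligand bond graph is disconnected (ignoring the dummy)")
        if self.dummy_index is not None:
            partners = self.neighbors(self.dummy_index)
            if partners and partners != [self.metal_index]:
                raise MoleculeError("the dummy atom may bond only to the metal")
        if self.torsion_tree is not None and self.torsion_tree.n_torsions > 10:
            raise MoleculeError("more than 10 rotatable bonds is not supported")


@dataclass
class Receptor:
    atoms: list[Atom]
    source_resolution: float | None = None

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms])

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


# ---------------------------------------------------------------------------
# bond perception
# ---------------------------------------------------------------------------

def perceive_bonds(atoms: list[Atom]) -> list[tuple[int, int, float]]:
    """Distance-based bond perception.

    Two atoms are bonded iff ``d < 1.15 (r_i + r_j)`` with Cordero covalent
    radii; pairs involving a metal use a 1.25 factor to capture the longer
    dative coordination bonds. Dummy atoms never bond here (the dummy-metal
    link is added explicitly when the dummy is placed).
    """
    bonds: list[tuple[int, int, float]] = []
    n = len(atoms)
    if n < 2:
        return bonds
    xyz = np.array([a.coords for a in atoms])
    radii = np.array([covalent_radius(a.element) for a in atoms])
    metal_mask = np.array([is_metal(a.element) for a in atoms])
    dummy_mask = np.array([a.is_dummy for a in atoms])
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    rsum = radii[:, None] + radii[None, :]
    factor = np.where(metal_mask[:, None] | metal_mask[None, :],
                      DATIVE_BOND_FACTOR, BOND_FACTOR)
    bonded = d < factor * rsum
    for i in range(n):
        for j in range(i + 1, n):
            if bonded[i, j] and not (dummy_mask[i] or dummy_mask[j]):
                bonds.append((atoms[i].index, atoms[j].index, 1.0))
    return bonds


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def _normalize_element(sym: str) -> str:
    if sym.upper() == "DD":
        return "DD"
    return sym[:1].upper() + sym[1:].lower()


def read_xyz(path: str | Path, charge_column: bool = True) -> Ligand:
    """Read an XYZ file, optionally with a 5th numeric per-atom charge column.

    When the charge column is absent (or ``charge_column`` is false) charges
    are zero and a warning is recorded — docking without charges is legal but
    usually not what a user wants.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}: malformed XYZ header (expected atom count)") from None
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) < n:
        raise ParseError(f"{path}: header promises {n} atoms, found {len(body)} lines")
    atoms: list[Atom] = []
    any_charge = False
    for i, line in enumerate(body[:n]):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"{path}: line {i + 3}: expected 'El x y z [q]'")
        element = _normalize_element(parts[0])
        if element != "DD" and element not in COVALENT_RADII:
            raise ParseError(f"{path}: line {i + 3}: unknown element symbol {parts[0]!r}")
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise ParseError(f"{path}: line {i + 3}: non-numeric coordinates") from None
        q = 0.0
        if charge_column and len(parts) >= 5:
            try:
                q = float(parts[4])
                any_charge = True
            except ValueError:
                raise ParseError(f"{path}: line {i + 3}: non-numeric charge column") from None
        atoms.append(Atom(index=i, element=element, coords=np.array(xyz), partial_charge=q))
    if charge_column and not any_charge:
        warnings.warn(f"{path}: no charge column found; all partial charges set to 0",
                      stacklevel=2)
    lig = Ligand(atoms=atoms)
    lig.bonds = perceive_bonds(atoms)
    return lig


def write_xyz(ligand: Ligand, path: str | Path, with_charges: bool = True,
              comment: str = "") -> None:
    path = Path(path)
    lines = [str(ligand.n_atoms), comment]
    for a in ligand.atoms:
        q = f" {a.partial_charge:12.6f}" if with_charges else ""
        lines.append(f"{a.element:<2s} {a.coords[0]:14.6f} {a.coords[1]:14.6f} "
                     f"{a.coords[2]:14.6f}{q}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PDB (via gemmi)
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path, keep_nonresidues: bool = False) -> Receptor:
    """Read a single-model PDB into a rigid receptor.

    Waters and HETATM groups are dropped unless ``keep_nonresidues`` is set
    (cofactors that take part in binding must be kept). Alternate locations
    are resolved to the highest occupancy, first listed on a tie.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError on parse failure
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no models found")
    if len(st) > 1:
        raise MoleculeError(
            f"{path}: {len(st)} models present; supply a single-model file "
            "(select one model before docking)")
    st.setup_entities()
    model = st[0]
    atoms: list[Atom] = []
    idx = 0
    for chain in model:
        for residue in chain:
            resname = residue.name.strip()
            if resname in WATER_RESNAMES:
                continue
            is_het = residue.het_flag == "H"
            if is_het and not keep_nonresidues:
                continue
            # altloc resolution: per atom name, keep highest occupancy
            by_name: dict[str, gemmi.Atom] = {}
            for at in residue:
                prev = by_name.get(at.name)
                if prev is None or at.occ > prev.occ:
                    by_name[at.name] = at
            for at in by_name.values():
                el = _normalize_element(at.element.name)
                if el not in COVALENT_RADII:
                    raise ParseError(f"{path}: unknown element {at.element.name!r} "
                                     f"in residue {resname}")
                atoms.append(Atom(
                    index=idx, element=el,
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    partial_charge=at.charge,
                    residue_tag=f"{resname}:{residue.seqid.num}:{chain.name}",
                ))
                idx += 1
    if not atoms:
        raise MoleculeError(f"{path}: no receptor atoms remain after filtering")
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    return Receptor(atoms=atoms, source_resolution=resolution)


def write_pdb(receptor: Receptor, path: str | Path) -> None:
    """Write a minimal single-model PDB (ATOM records only)."""
    lines = []
    for i, a in enumerate(receptor.atoms, start=1):
        resname, seq, chain = "UNK", 1, "A"
        if a.residue_tag:
            parts = a.residue_tag.split(":")
            resname = parts[0][:3]
            if len(parts) > 1:
                seq = int(parts[1])
            if len(parts) > 2:
                chain = parts[2][:1]
        name = (a.element + str(i))[:4]
        lines.append(
            f"ATOM  {i:5d} {name:<4s} {resname:<3s} {chain}{seq:4d}    "
            f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PDBQT
# ---------------------------------------------------------------------------

def _pdbqt_atom_line(serial: int, atom: Atom) -> str:
    name = (atom.element + str(serial))[:4]
    resname, seq, chain = "LIG", 1, "A"
    if atom.residue_tag:
        parts = atom.residue_tag.split(":")
        resname = parts[0][:3]
        if len(parts) > 1:
            seq = int(parts[1])
        if len(parts) > 2:
            chain = parts[2][:1]
    return (f"ATOM  {serial:5d} {name:<4s} {resname:<3s} {chain}{seq:4d}    "
            f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}    {atom.partial_charge:6.3f} {atom.ad_type:<2s}")


def write_pdbqt(mol: Ligand | Receptor, path: str | Path) -> None:
    """Write an AutoDock4-style PDBQT.

    Ligands get a ROOT block plus nested BRANCH blocks following the torsion
    tree and a trailing TORSDOF record; receptors are flat ATOM lists. Every
    atom must already be typed.
    """
    untyped = [a.index for a in mol.atoms if a.ad_type is None]
    if untyped:
        raise MoleculeError(f"cannot write PDBQT: untyped atoms at indices {untyped}")
    lines: list[str] = []
    if isinstance(mol, Receptor):
        for i, a in enumerate(mol.atoms, start=1):
            lines.append(_pdbqt_atom_line(i, a))
    else:
        tree = mol.torsion_tree
        if tree is None:
            tree = TorsionTree(root=mol.atoms[0].index)
        # group atoms into rigid fragments: root fragment plus one per torsion;
        # the innermost (deepest) moving set containing an atom wins
        frag_of: dict[int, int] = {}
        for i in (a.index for a in mol.atoms):
            containing = [k for k, mv in enumerate(tree.moving_sets, start=1) if i in mv]
            frag_of[i] = max(containing) if containing else 0
        serial_of: dict[int, int] = {}
        counter = [0]

        def emit_fragment(frag: int) -> None:
            members = [a for a in mol.atoms if frag_of[a.index] == frag]
            for a in members:
                counter[0] += 1
                serial_of[a.index] = counter[0]
                lines.append(_pdbqt_atom_line(counter[0], a))
            for k, (anchor, pivot) in enumerate(tree.bonds, start=1):
                if frag_of[anchor] == frag and frag_of[pivot] == k:
                    lines.append(f"BRANCH {serial_of[anchor]:4d} {counter[0] + 1:4d}")
                    emit_fragment(k)
                    lines.append(f"ENDBRANCH {serial_of[anchor]:4d} {serial_of[pivot]:4d}")

        lines.append("ROOT")
        # atoms of fragment 0 first, then close ROOT before branching
        members = [a for a in mol.atoms if frag_of[a.index] == 0]
        for a in members:
            counter[0] += 1
            serial_of[a.index] = counter[0]
            lines.append(_pdbqt_atom_line(counter[0], a))
        lines.append("ENDROOT")
        for k, (anchor, pivot) in enumerate(tree.bonds, start=1):
            if frag_of[anchor] == 0 and frag_of[pivot] == k:
                lines.append(f"BRANCH {serial_of[anchor]:4d} {counter[0] + 1:4d}")
                emit_fragment(k)
                lines.append(f"ENDBRANCH {serial_of[anchor]:4d} {serial_of[pivot]:4d}")
        lines.append(f"TORSDOF {tree.n_torsions}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pdbqt(path: str | Path) -> Ligand | Receptor:
    """Parse a PDBQT file written by :func:`write_pdbqt` (or AutoDock tools).

    Returns a :class:`Ligand` when torsion-tree records are present, otherwise
    a :class:`Receptor`. Bonds are re-perceived from geometry (PDBQT carries
    no connectivity).
    """
    path = Path(path)
    atoms: list[Atom] = []
    branch_bonds: list[tuple[int, int]] = []  # serial pairs
    has_tree = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM"):
            try:
                x = float(line[30:38]); y = float(line[38:46]); z = float(line[46:54])
                q = float(line[66:76])
                ad = line[77:79].strip() or line[76:79].strip()
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: malformed ATOM record") from None
            element = "DD" if ad == "DD" else _normalize_element(ad if len(ad) <= 2 else ad[:2])
            if ad in ("A", "HD"):
                element = {"A": "C", "HD": "H"}[ad]
            elif ad in ("NA",):
                element = "N"
            elif ad in ("OA",):
                element = "O"
            elif ad in ("SA",):
                element = "S"
            resname = line[17:20].strip()
            seq = line[22:26].strip()
            chain = line[21].strip()
            tag = f"{resname}:{seq}:{chain}" if resname else None
            atoms.append(Atom(index=len(atoms), element=element,
                              coords=np.array([x, y, z]),
                              partial_charge=0.0 if ad == "DD" else q,
                              ad_type=ad, residue_tag=tag))
        elif rec == "BRANCH":
            has_tree = True
            parts = line.split()
            branch_bonds.append((int(parts[1]), int(parts[2])))
        elif rec in ("ROOT", "ENDROOT", "ENDBRANCH", "TORSDOF", "REMARK"):
            if rec in ("ROOT",):
                has_tree = True
    if not atoms:
        raise ParseError(f"{path}: no atoms")
    if not has_tree:
        return Receptor(atoms=atoms)
    lig = Ligand(atoms=atoms)
    lig.bonds = perceive_bonds(atoms)
    if lig.dummy_index is not None and lig.metal_index is not None:
        lig.bonds.append((lig.metal_index, lig.dummy_index, 1.0))
    if branch_bonds:
        from .atom_typing import build_torsion_tree_from_bonds
        rot = [(a - 1, b - 1) for a, b in branch_bonds]  # serial -> 0-based index
        lig.torsion_tree = build_torsion_tree_from_bonds(lig, rot)
    else:
        lig.torsion_tree = TorsionTree(root=atoms[0].index)
    return lig
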