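"""File IO and bond perception for XYZ, PDB and PDBQT."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coordock.atom_typing import assign_types, build_torsion_tree
from coordock.fixtures import make_toy_complex
from coordock.mol_model import (Atom, Ligand, MoleculeError, ParseError,
                                Receptor, perceive_bonds, read_pdb, read_pdbqt,
                                read_xyz, write_pdb, write_pdbqt, write_xyz)

WATER_XYZ = """3
water with charge column
O  0.000000  0.000000  0.117300 -0.834
H  0.000000  0.757200 -0.469200  0.417
H  0.000000 -0.757200 -0.469200  0.417
"""

PDB_WITH_WATERS = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.685   7.148  -4.927  1.00  0.00           C
ATOM      4  O   ALA A   1      13.405   7.504  -5.862  1.00  0.00           O
HETATM    5  FE  HEM A   2       8.000   8.000  -8.000  1.00  0.00          FE
HETATM    6  O   HOH A   3       2.000   2.000   2.000  1.00  0.00           O
HETATM    7  H1  HOH A   3       2.600   2.600   2.000  1.00  0.00           H
HETATM    8  H2  HOH A   3       1.400   2.600   2.000  1.00  0.00           H
HETATM    9  O   HOH A   4       4.000   4.000   4.000  1.00  0.00           O
HETATM   10  H1  HOH A   4       4.600   4.600   4.000  1.00  0.00           H
HETATM   11  H2  HOH A   4       3.400   4.600   4.000  1.00  0.00           H
END
"""

ALTLOC_PDB = """\
ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.40  0.00           N
ATOM      2  N  BALA A   1       1.000   0.000   0.000  0.60  0.00           N
ATOM      3  CA  ALA A   1       0.500   1.400   0.000  1.00  0.00           C
END
"""


class TestXYZ:
    def test_water_atoms_and_bonds(self, tmp_path):
        p = tmp_path / "water.xyz"
        p.write_text(WATER_XYZ)
        lig = read_xyz(p)
        assert lig.n_atoms == 3
        assert len(lig.bonds) == 2
        assert lig.elements == ["O", "H", "H"]

    def test_charge_column_passthrough(self, tmp_path):
        p = tmp_path / "water.xyz"
        p.write_text(WATER_XYZ)
        lig = read_xyz(p)
        np.testing.assert_allclose(lig.charges, [-0.834, 0.417, 0.417])

    def test_missing_charges_warns(self, tmp_path):
        p = tmp_path / "bare.xyz"
        p.write_text("1\n\nC 0.0 0.0 0.0\n")
        with pytest.warns(UserWarning, match="charge"):
            lig = read_xyz(p)
        assert lig.charges[0] == 0.0

    def test_malformed_header(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("not-a-count\n\nC 0 0 0\n")
        with pytest.raises(ParseError, match="header"):
            read_xyz(p)

    def test_unknown_element_names_line(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("1\n\nXq 0 0 0\n")
        with pytest.raises(ParseError, match="line 3"):
            read_xyz(p)

    def test_short_body_rejected(self, tmp_path):
        p = tmp_path / "short.xyz"
        p.write_text("5\n\nC 0 0 0\n")
        with pytest.raises(ParseError, match="5 atoms"):
            read_xyz(p)

    @settings(max_examples=25, deadline=None)
    @given(coords=st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50),
                                     st.floats(-50, 50)), min_size=1, max_size=8))
    def test_roundtrip_coordinates(self, coords, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("xyz")
        atoms = [Atom(index=i, element="C", coords=np.array(c), partial_charge=0.1 * i)
                 for i, c in enumerate(coords)]
        lig = Ligand(atoms=atoms)
        path = tmp / "roundtrip.xyz"
        write_xyz(lig, path)
        back = read_xyz(path)
        np.testing.assert_allclose(back.coords, lig.coords, atol=1e-6)
        np.testing.assert_allclose(back.charges, lig.charges, atol=1e-6)
        assert back.elements == lig.elements


class TestPDB:
    def test_waters_removed(self, tmp_path):
        p = tmp_path / "rec.pdb"
        p.write_text(PDB_WITH_WATERS)
        rec = read_pdb(p, keep_nonresidues=False)
        # 4 protein atoms; 6 water atoms and the HETATM cofactor dropped
        assert rec.n_atoms == 4

    def test_cofactor_kept_on_request(self, tmp_path):
        p = tmp_path / "rec.pdb"
        p.write_text(PDB_WITH_WATERS)
        rec = read_pdb(p, keep_nonresidues=True)
        assert any(a.element == "Fe" for a in rec.atoms)
        # waters go regardless
        assert not any("HOH" in (a.residue_tag or "") for a in rec.atoms)

    def test_empty_after_filtering_errors(self, tmp_path):
        p = tmp_path / "wat.pdb"
        p.write_text("\n".join(PDB_WITH_WATERS.splitlines()[5:]) + "\n")
        with pytest.raises(MoleculeError, match="no receptor atoms"):
            read_pdb(p)

    def test_multi_model_rejected(self, tmp_path):
        p = tmp_path / "nmr.pdb"
        body = "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
        p.write_text(f"MODEL        1\n{body}ENDMDL\nMODEL        2\n{body}ENDMDL\nEND\n")
        with pytest.raises(MoleculeError, match="model"):
            read_pdb(p)

    def test_altloc_highest_occupancy(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        rec = read_pdb(p)
        n_atoms = [a for a in rec.atoms if a.element == "N"]
        assert len(n_atoms) == 1
        assert n_atoms[0].coords[0] == pytest.approx(1.0)  # occ 0.60 wins

    def test_write_read_roundtrip(self, tmp_path):
        p = tmp_path / "rec.pdb"
        p.write_text(PDB_WITH_WATERS)
        rec = read_pdb(p)
        out = tmp_path / "out.pdb"
        write_pdb(rec, out)
        back = read_pdb(out)
        assert back.n_atoms == rec.n_atoms
        np.testing.assert_allclose(back.coords, rec.coords, atol=1e-3)


class TestPDBQT:
    def test_rigid_ligand_single_root(self, tmp_path, water):
        assign_types(water)
        water.torsion_tree = build_torsion_tree(water)
        path = tmp_path / "water.pdbqt"
        write_pdbqt(water, path)
        text = path.read_text()
        assert text.count("ROOT") == 2  # ROOT + ENDROOT
        assert "BRANCH" not in text
        assert "TORSDOF 0" in text

    def test_branch_count_matches_torsions(self, tmp_path):
        lig = make_toy_complex(n_torsions=3)
        path = tmp_path / "lig.pdbqt"
        write_pdbqt(lig, path)
        text = path.read_text()
        assert sum(1 for ln in text.splitlines() if ln.startswith("BRANCH")) == 3
        assert "TORSDOF 3" in text

    def test_roundtrip_charges_and_coords(self, tmp_path):
        lig = make_toy_complex(n_torsions=2)
        path = tmp_path / "lig.pdbqt"
        write_pdbqt(lig, path)
        back = read_pdbqt(path)
        assert isinstance(back, Ligand)
        assert back.n_atoms == lig.n_atoms
        assert [a.ad_type for a in back.atoms] == [a.ad_type for a in lig.atoms]
        np.testing.assert_allclose(back.coords, lig.coords, atol=1e-3)
        np.testing.assert_allclose(back.charges, lig.charges, atol=1e-3)
        assert back.torsion_tree.n_torsions == lig.torsion_tree.n_torsions

    def test_untyped_atom_rejected(self, tmp_path):
        lig = Ligand(atoms=[Atom(index=0, element="C", coords=np.zeros(3))])
        with pytest.raises(MoleculeError, match="untyped"):
            write_pdbqt(lig, tmp_path / "x.pdbqt")

    def test_receptor_roundtrip(self, tmp_path):
        atoms = [Atom(index=i, element=e, coords=np.array([float(i), 0, 0]),
                      partial_charge=0.1 * i, ad_type=t, residue_tag="ALA:1:A")
                 for i, (e, t) in enumerate([("C", "C"), ("O", "OA"), ("N", "NA")])]
        rec = Receptor(atoms=atoms)
        path = tmp_path / "rec.pdbqt"
        write_pdbqt(rec, path)
        back = read_pdbqt(path)
        assert isinstance(back, Receptor)
        np.testing.assert_allclose(back.charges, rec.charges, atol=1e-3)


class TestBondPerception:
    def test_symmetric_no_self_bonds(self, benzene):
        bonds = perceive_bonds(benzene.atoms)
        assert all(a != b for a, b, _ in bonds)
        pairs = {(a, b) for a, b, _ in bonds}
        assert all((b, a) not in pairs for a, b in pairs)

    def test_dative_bond_longer_cutoff(self):
        # Ru-N at 2.3 Å: beyond the 1.15 covalent cutoff, inside the dative one
        atoms = [Atom(index=0, element="Ru", coords=np.zeros(3)),
                 Atom(index=1, element="N", coords=np.array([2.3, 0, 0]))]
        assert len(perceive_bonds(atoms)) == 1
        atoms_cc = [Atom(index=0, element="C", coords=np.zeros(3)),
                    Atom(index=1, element="C", coords=np.array([2.3, 0, 0]))]
        assert len(perceive_bonds(atoms_cc)) == 0

    def test_dummy_never_bonds(self):
        atoms = [Atom(index=0, element="Ru", coords=np.zeros(3)),
                 Atom(index=1, element="DD", coords=np.array([0.5, 0, 0]))]
        assert perceive_bonds(atoms) == []


class TestInvariants:
    def test_dummy_charge_must_be_zero(self):
        with pytest.raises(MoleculeError):
            Atom(index=0, element="DD", coords=np.zeros(3), partial_charge=0.1)

    def test_at_most_one_dummy(self):
        atoms = [Atom(index=i, element="DD", coords=np.array([float(i), 0, 0]))
                 for i in range(2)]
        with pytest.raises(MoleculeError, match="one"):
            Ligand(atoms=atoms)

    def test_disconnected_graph_rejected(self):
        atoms = [Atom(index=0, element="C", coords=np.zeros(3)),
                 Atom(index=1, element="C", coords=np.array([10.0, 0, 0]))]
        lig = Ligand(atoms=atoms)
        lig.bonds = []
        with pytest.raises(MoleculeError, match="disconnected"):
            lig.validate()
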