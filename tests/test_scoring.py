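"""Lennard-Jones forms, parameter tables, electrostatics and pair-sum energy."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coordock.coordination import add_vacancy_dummy
from coordock.fixtures import make_toy_complex, pocket_problem, PocketSpec
from coordock.mol_model import Atom, MoleculeError, Receptor
from coordock.scoring import (EnergyModel, LJParamSet, default_params,
                              electrostatic_energy, hbond_weight,
                              intermolecular_energy, lj_energy, load_params,
                              mehler_solmajer_dielectric)


class TestLJ:
    @pytest.mark.parametrize("exps", [(12, 6), (12, 10)])
    def test_minimum_is_minus_epsilon_at_rmin(self, exps):
        eps, rmin = 0.7, 2.3
        assert lj_energy(rmin, eps, rmin, exps) == pytest.approx(-eps, abs=1e-12)
        r = np.linspace(0.7 * rmin, 4 * rmin, 20001)
        e = lj_energy(r, eps, rmin, exps)
        assert e.min() == pytest.approx(-eps, abs=1e-6)
        assert r[np.argmin(e)] == pytest.approx(rmin, rel=1e-3)

    def test_decay_at_long_range(self):
        eps, rmin = 2.0, 2.0
        # closed forms at r = 10 R_min (x = 0.1): the 12-10 well is below
        # 1e-6 eps; the 12-6 tail equals (1e-12 - 2e-6) eps exactly
        assert abs(lj_energy(10 * rmin, eps, rmin, (12, 10))) < 1e-6 * eps
        assert lj_energy(10 * rmin, eps, rmin, (12, 6)) == pytest.approx(
            eps * (1e-12 - 2e-6), rel=1e-12)

    def test_126_zero_crossing(self):
        eps, rmin = 1.3, 3.1
        r0 = rmin * 2 ** (-1 / 6)
        assert lj_energy(r0, eps, rmin, (12, 6)) == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_separation_rejected(self):
        with pytest.raises(ValueError):
            lj_energy(0.0, 1.0, 2.0)


class TestParams:
    def test_printed_metal_rmin_defaults(self):
        ps = default_params(metals=("Ru",))
        assert ps.get_pair("Ru", "HD")[1] == pytest.approx(1.00)
        assert ps.get_pair("Ru", "NA")[1] == pytest.approx(2.20)
        assert ps.get_pair("Ru", "OA")[1] == pytest.approx(2.25)
        assert ps.get_pair("Ru", "SA")[1] == pytest.approx(2.30)

    def test_metal_metal_epsilon_fixed(self):
        ps = default_params(metals=("Ru", "Pt"))
        assert ps.get_pair("Ru", "Ru")[0] == pytest.approx(0.010)
        assert ps.get_pair("Pt", "Pt")[0] == pytest.approx(0.010)

    def test_exponent_assignment(self):
        ps = default_params(metals=("Os",))
        assert ps.get_pair("Os", "HD")[2] == (12, 6)
        for t in ("NA", "OA", "SA"):
            assert ps.get_pair("Os", t)[2] == (12, 10)

    def test_lookup_symmetric(self):
        ps = default_params(metals=("Cu",))
        assert ps.get_pair("Cu", "OA") == ps.get_pair("OA", "Cu")

    def test_user_override_single_pair(self, tmp_path):
        p = tmp_path / "override.txt"
        p.write_text("# comment line\nRu OA 3.5 2.25 12,10\n")
        ps = load_params(p, metals=("Ru",))
        assert ps.get_pair("Ru", "OA")[0] == pytest.approx(3.5)
        assert ps.get_pair("Ru", "NA")[0] == pytest.approx(2.0)  # untouched

    def test_shipped_example_file_loads(self):
        from coordock.scoring import example_override_path
        ps = load_params(example_override_path(), metals=("Mo",))
        assert ps.get_pair("Mo", "HD")[0] == pytest.approx(5.62)
        assert ps.get_pair("Mo", "SA")[0] == pytest.approx(0.17)

    def test_negative_epsilon_names_line(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("Ru OA -1.0 2.25 12,10\n")
        with pytest.raises(ValueError, match=":1"):
            load_params(p, metals=("Ru",))

    def test_missing_pair_errors_with_types(self):
        ps = LJParamSet()
        with pytest.raises(MoleculeError, match="Qq"):
            ps.get_pair("Qq", "OA")


class TestHbondWeight:
    def test_collinear_full_weight(self):
        assert hbond_weight([0, 0, 0], [0, 0, 1], [0, 0, 3]) == pytest.approx(1.0)

    def test_perpendicular_zero(self):
        assert hbond_weight([0, 0, 0], [0, 0, 1], [3, 0, 0]) == pytest.approx(0.0)

    def test_45_degrees_half(self):
        assert hbond_weight([0, 0, 0], [0, 0, 1], [2, 0, 2]) == pytest.approx(0.5)

    def test_no_dummy_isotropic(self):
        assert hbond_weight([0, 0, 0], None, [3, 0, 0]) == 1.0

    def test_behind_plane_zero(self):
        assert hbond_weight([0, 0, 0], [0, 0, 1], [0, 0, -3]) == 0.0


class TestElectrostatics:
    def test_zero_charge_zero_energy(self):
        assert electrostatic_energy(0.0, 0.5, 3.0) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(qi=st.floats(-1, 1), qj=st.floats(-1, 1),
           r=st.floats(0.5, 15.0))
    def test_sign_matches_charge_product(self, qi, qj, r):
        e = electrostatic_energy(qi, qj, r)
        assert np.sign(e) == np.sign(qi * qj)

    def test_screened_monotone_decay(self):
        assert abs(electrostatic_energy(1, 1, 3.0)) > abs(electrostatic_energy(1, 1, 6.0))

    def test_dielectric_limits(self):
        # approaches the bulk-water value at long range, small at contact
        assert mehler_solmajer_dielectric(50.0) == pytest.approx(78.4, abs=0.5)
        assert mehler_solmajer_dielectric(1.0) < 10.0


def _single_pair_system(metal_eps=2.0):
    lig = make_toy_complex(coordination_number=5, n_torsions=0)
    add_vacancy_dummy(lig)
    for a in lig.atoms:
        a.partial_charge = 0.0
    params = default_params(metals=("Ru",))
    _, rmin, _ = params.get_pair("Ru", "OA")
    rec = Receptor(atoms=[Atom(index=0, element="O", ad_type="OA",
                               coords=np.array([0.0, 0.0, rmin]))])
    return lig, rec, params


class TestIntermolecularEnergy:
    def test_far_ligand_zero(self):
        lig, rec, params = _single_pair_system()
        far = lig.coords + np.array([100.0, 0, 0])
        bd = intermolecular_energy(lig, rec, params, ligand_coords=far)
        assert abs(bd.total) < 1e-6

    def test_single_pair_reduction(self):
        # metal at R_min from one OA, zero charges, dummy collinear -> -eps
        lig, rec, params = _single_pair_system()
        eps = params.get_pair("Ru", "OA")[0]
        bd = intermolecular_energy(lig, rec, params)
        assert bd.hbond_metal == pytest.approx(-eps, abs=1e-9)
        # ligators sit > 3 A from the acceptor; their 12-6 tails are small
        assert abs(bd.total - (-eps)) < 0.6
        assert bd.total == pytest.approx(bd.vdw + bd.hbond_metal
                                         + bd.electrostatic, abs=1e-9)

    def test_matches_bruteforce_double_loop(self):
        prob = pocket_problem(PocketSpec(verify_random_poses=0), seed=3)
        lig, rec, params = prob.ligand, prob.receptor, prob.params
        bd = intermolecular_energy(lig, rec, params,
                                   lj_cutoff=1e6, elec_cutoff=1e6)
        from coordock.scoring import COULOMB_CONSTANT
        total = 0.0
        mpos = lig.coords[lig.metal_index]
        dpos = lig.coords[lig.dummy_index]
        for a in lig.atoms:
            if a.is_dummy:
                continue
            for b in rec.atoms:
                r = float(np.linalg.norm(a.coords - b.coords))
                eps, rmin, exps = params.get_pair(a.ad_type, b.ad_type)
                if a.index == lig.metal_index and b.ad_type in ("NA", "OA", "SA"):
                    from coordock.scoring import hbond_weight
                    w = hbond_weight(mpos, dpos, b.coords)
                    x = rmin / r
                    total += eps * (5 * x**12 - 6 * w * x**10)
                else:
                    total += lj_energy(r, eps, rmin, exps)
                total += electrostatic_energy(a.partial_charge, b.partial_charge, r)
        assert bd.total == pytest.approx(total, abs=1e-3)

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation
        prob = pocket_problem(PocketSpec(verify_random_poses=0), seed=4)
        bd0 = intermolecular_energy(prob.ligand, prob.receptor, prob.params)
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.2]).as_matrix()
        shift = np.array([5.0, -3.0, 1.0])
        lig2 = prob.ligand
        rec2 = prob.receptor
        old_lig = lig2.coords
        old_rec = rec2.coords
        lig2.set_coords(old_lig @ rot.T + shift)
        for a, c in zip(rec2.atoms, old_rec @ rot.T + shift):
            a.coords = c
        bd1 = intermolecular_energy(lig2, rec2, prob.params)
        assert bd1.total == pytest.approx(bd0.total, abs=1e-9)

    def test_removing_dummy_only_deepens_metal_terms(self):
        lig, rec, params = _single_pair_system()
        with_dummy = intermolecular_energy(lig, rec, params).hbond_metal
        lig.atoms = [a for a in lig.atoms if not a.is_dummy]
        lig.dummy_index = None
        without = intermolecular_energy(lig, rec, params).hbond_metal
        assert without <= with_dummy + 1e-12

    def test_dummy_contributes_no_direct_energy(self):
        lig, rec, params = _single_pair_system()
        e_with = intermolecular_energy(lig, rec, params)
        # move the acceptor off-axis: only the angular weight may change;
        # give the dummy a fake charge path by checking qq row is zeroed
        model = EnergyModel(lig, rec, params)
        assert np.all(model.qq[lig.dummy_index] == 0.0)
        assert not model.active[lig.dummy_index].any()
        assert e_with.total == pytest.approx(e_with.vdw + e_with.hbond_metal
                                             + e_with.electrostatic, abs=1e-9)
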