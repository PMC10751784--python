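"""Genome handling, randomization, local search and GA contracts.

The expensive planted-pose recovery benchmark lives in the acceptance suite;
here the GA runs at reduced size to check its contracts.
"""
import numpy as np
import pytest

from coordock.docking import (DockingBox, GAConfig, Genome, GenomeEnergy,
                              LocalSearchConfig, ga_dock, local_search,
                              randomize)
from coordock.evaluation import ligand_rmsd
from coordock.fixtures import PocketSpec, pocket_problem
from coordock.scoring import intermolecular_energy


@pytest.fixture(scope="module")
def pocket():
    return pocket_problem(PocketSpec(verify_random_poses=0), seed=3)


SMALL = GAConfig(population=20, generations=25)


class TestBoxAndGenome:
    def test_box_validation(self):
        with pytest.raises(ValueError):
            DockingBox(center=np.zeros(3), size=np.array([1.0, -1.0, 1.0]))

    def test_genome_quaternion_normalized(self):
        g = Genome(translation=np.zeros(3), orientation=np.array([2.0, 0, 0, 0]),
                   torsions=np.zeros(1))
        assert np.linalg.norm(g.orientation) == pytest.approx(1.0, abs=1e-12)

    def test_vector_roundtrip(self):
        g = Genome(translation=np.array([1.0, 2, 3]),
                   orientation=np.array([0.5, 0.5, 0.5, 0.5]),
                   torsions=np.array([0.3, -0.7]))
        back = Genome.from_vector(g.as_vector())
        np.testing.assert_allclose(back.as_vector(), g.as_vector())


class TestRandomize:
    def test_fixed_seed_reproducible(self, pocket):
        a = randomize(pocket.ligand, pocket.box, np.random.default_rng(9))
        b = randomize(pocket.ligand, pocket.box, np.random.default_rng(9))
        np.testing.assert_array_equal(a.as_vector(), b.as_vector())

    def test_translation_uniform_in_box(self, pocket):
        rng = np.random.default_rng(10)
        draws = np.array([randomize(pocket.ligand, pocket.box, rng).translation
                          for _ in range(10_000)])
        assert np.all(np.abs(draws - pocket.box.center) <= pocket.box.size / 2)
        se = (pocket.box.size / np.sqrt(12)) / np.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - pocket.box.center) < 3 * se)

    def test_rigid_ligand_empty_torsions(self):
        prob = pocket_problem(PocketSpec(n_torsions=0, verify_random_poses=0),
                              seed=1)
        g = randomize(prob.ligand, prob.box, np.random.default_rng(0))
        assert g.torsions.size == 0

    def test_orientation_uniform_no_hemisphere_bias(self, pocket):
        rng = np.random.default_rng(11)
        qs = np.array([randomize(pocket.ligand, pocket.box, rng).orientation
                       for _ in range(4000)])
        # q and -q are the same rotation; fold and check axis components
        zmean = np.abs(qs[:, 1:]).mean(axis=0)
        assert np.all(np.abs(zmean - zmean.mean()) < 0.02)


class TestLocalSearch:
    def test_descent_contract(self, pocket):
        em = GenomeEnergy(pocket.ligand, pocket.receptor, pocket.params,
                          pocket.box)
        rng = np.random.default_rng(12)
        g0 = randomize(pocket.ligand, pocket.box, rng)
        e0 = em.objective(g0)
        g1 = local_search(g0, em.objective_vector,
                          LocalSearchConfig(iterations=100), rng)
        assert em.objective(g1) <= e0 + 1e-12

    def test_quadratic_converges_to_minimum(self):
        target = np.array([1.0, -2.0, 0.5])

        def energy(v):
            q = v[3:7] / np.linalg.norm(v[3:7])
            return float(((v[:3] - target) ** 2).sum() + (1 - q[0]) ** 2)

        g0 = Genome(translation=np.zeros(3),
                    orientation=np.array([0.0, 1.0, 0, 0]),
                    torsions=np.zeros(0))
        g1 = local_search(g0, energy, LocalSearchConfig(iterations=3000),
                          np.random.default_rng(13))
        np.testing.assert_allclose(g1.translation, target, atol=0.05)

    def test_stationary_at_optimum(self):
        def energy(v):
            return float((v[:3] ** 2).sum())
        g0 = Genome(translation=np.zeros(3),
                    orientation=np.array([1.0, 0, 0, 0]), torsions=np.zeros(0))
        g1 = local_search(g0, energy, LocalSearchConfig(iterations=50),
                          np.random.default_rng(14))
        assert energy(g1.as_vector()) == 0.0


class TestGADock:
    def test_same_seed_identical_poses(self, pocket):
        kw = dict(n_runs=2, ga_config=SMALL, seed=21)
        a = ga_dock(pocket.ligand, pocket.receptor, pocket.params, pocket.box, **kw)
        b = ga_dock(pocket.ligand, pocket.receptor, pocket.params, pocket.box, **kw)
        for pa, pb in zip(a, b):
            assert pa.energy == pb.energy
            np.testing.assert_array_equal(pa.coordinates, pb.coordinates)

    def test_poses_sorted_and_energy_consistent(self, pocket):
        poses = ga_dock(pocket.ligand, pocket.receptor, pocket.params,
                        pocket.box, n_runs=3, ga_config=SMALL, seed=22)
        energies = [p.energy for p in poses]
        assert energies == sorted(energies)
        for p in poses:
            again = intermolecular_energy(pocket.ligand, pocket.receptor,
                                          pocket.params,
                                          ligand_coords=p.coordinates)
            assert p.energy == pytest.approx(again.total, abs=1e-6)

    def test_translating_receptor_and_box_translates_poses(self, pocket):
        import copy
        shift = np.array([3.0, -2.0, 1.0])
        poses0 = ga_dock(pocket.ligand, pocket.receptor, pocket.params,
                         pocket.box, n_runs=1, ga_config=SMALL, seed=23)
        rec2 = copy.deepcopy(pocket.receptor)
        for a in rec2.atoms:
            a.coords = a.coords + shift
        box2 = DockingBox(center=pocket.box.center + shift,
                          size=pocket.box.size.copy())
        poses1 = ga_dock(pocket.ligand, rec2, pocket.params, box2,
                         n_runs=1, ga_config=SMALL, seed=23)
        assert poses1[0].energy == pytest.approx(poses0[0].energy, abs=1e-6)
        np.testing.assert_allclose(poses1[0].coordinates,
                                   poses0[0].coordinates + shift, atol=1e-6)

    def test_tiny_population_rejected(self, pocket):
        with pytest.raises(ValueError, match="population"):
            ga_dock(pocket.ligand, pocket.receptor, pocket.params, pocket.box,
                    ga_config=GAConfig(population=3), seed=0)

    def test_rigid_search_beats_coarse_grid(self):
        """One GA run on a rigid ligand must match or beat an exhaustive
        coarse grid over the six rigid degrees of freedom."""
        prob = pocket_problem(PocketSpec(n_torsions=0, verify_random_poses=0),
                              seed=2)
        em = GenomeEnergy(prob.ligand, prob.receptor, prob.params, prob.box)
        best_grid = np.inf
        steps = np.linspace(-2.0, 2.0, 5)
        quats = [np.array([1.0, 0, 0, 0]), np.array([0.0, 1, 0, 0]),
                 np.array([0.0, 0, 1, 0]), np.array([0.0, 0, 0, 1]),
                 np.array([0.5, 0.5, 0.5, 0.5]), np.array([0.5, -0.5, 0.5, -0.5])]
        for dx in steps:
            for dy in steps:
                for dz in steps:
                    for q in quats:
                        g = Genome(translation=prob.box.center + [dx, dy, dz],
                                   orientation=q, torsions=np.zeros(0))
                        best_grid = min(best_grid, em.objective(g))
        poses = ga_dock(prob.ligand, prob.receptor, prob.params, prob.box,
                        n_runs=2, ga_config=GAConfig(population=30,
                                                     generations=40), seed=5)
        assert poses[0].energy <= best_grid + 1e-6
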