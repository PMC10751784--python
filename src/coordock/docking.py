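"""Genetic-algorithm pose search over translation, rigid rotation and torsions.

The genome is (translation of the root atom, unit quaternion, torsion angles).
Each docking run is an independent GA started from a uniformly randomized
genome (uniform position in the box, uniform rotation, uniform torsions) so
the result carries no memory of the input pose; the best genome of each run
becomes one pose, and ``n_runs`` runs yield the ranked pose list.

The GA is a desk-scale Lamarckian variant: tournament selection, two-point
crossover over genome segments, Gaussian mutation, elitism, and Solis-Wets
stochastic hill descent applied to the best fraction of each generation (and
to each run's final best). Reported pose energies are pure intermolecular
energies; the GA objective additionally carries a quadratic out-of-box
penalty on the root atom and a simple torsion-dependent intramolecular LJ
term between moving branches.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atom_typing import apply_torsions
from .mol_model import Ligand, Receptor, TorsionTree
from .scoring import EnergyBreakdown, EnergyModel, LJParamSet

__all__ = ["DockingBox", "Genome", "Pose", "GAConfig", "LocalSearchConfig",
           "randomize", "ga_dock", "local_search", "GenomeEnergy"]


@dataclass
class DockingBox:
    center: np.ndarray
    size: np.ndarray = field(default_factory=lambda: np.array([20.0, 20.0, 20.0]))

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.size = np.asarray(self.size, dtype=float)
        if self.size.shape != (3,) or np.any(self.size <= 0):
            raise ValueError("box edge lengths must be positive")

    def contains(self, point: np.ndarray) -> bool:
        return bool(np.all(np.abs(point - self.center) <= self.size / 2 + 1e-9))


@dataclass
class Genome:
    translation: np.ndarray        # absolute root-atom position, Å
    orientation: np.ndarray        # unit quaternion (w, x, y, z)
    torsions: np.ndarray           # radians, one per rotatable bond

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        self.torsions = np.asarray(self.torsions, dtype=float)
        n = np.linalg.norm(self.orientation)
        if abs(n - 1.0) > 1e-9:
            if n < 1e-12:
                raise ValueError("zero quaternion")
            self.orientation = self.orientation / n

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.translation, self.orientation, self.torsions])

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "Genome":
        return cls(translation=v[:3], orientation=v[3:7], torsions=v[7:])


@dataclass
class Pose:
    coordinates: np.ndarray
    energy: float
    genome: Genome
    breakdown: EnergyBreakdown | None = None


@dataclass
class GAConfig:
    population: int = 50
    generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.2
    sigma_translation: float = 1.0        # Å
    sigma_rotation: float = np.radians(30.0)
    sigma_torsion: float = np.radians(30.0)
    elitism: int = 1
    immigrant_fraction: float = 0.1       # fresh random genomes per generation
    local_search_fraction: float = 0.1
    local_search_iterations: int = 25
    tournament_size: int = 2


@dataclass
class LocalSearchConfig:
    iterations: int = 100
    rho_initial: float = 0.3
    rho_min: float = 1e-3
    expansion: float = 2.0
    contraction: float = 0.5
    success_limit: int = 4
    failure_limit: int = 4


# preset mirroring the original AutoDock4 defaults, for users who want them
AUTODOCK_PRESET = GAConfig(population=150, generations=27000 // 150)


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


class GenomeEnergy:
    """Maps genomes to coordinates and objective values for one ligand/pocket.

    Coordinates: torsions are applied to the input conformer, the result is
    rotated about the root atom by the genome quaternion, and the root is
    placed at the genome translation. The GA objective is the intermolecular
    energy plus an out-of-box quadratic penalty on the root atom and the
    torsion-dependent intramolecular LJ between atoms separated by the
    rotatable bonds (1-4 and beyond).
    """

    BOX_PENALTY = 50.0  # kcal/mol/Å², steep enough to keep the root inside

    def __init__(self, ligand: Ligand, receptor: Receptor, params: LJParamSet,
                 box: DockingBox):
        self.model = EnergyModel(ligand, receptor, params)
        self.box = box
        self.tree = ligand.torsion_tree or TorsionTree(root=ligand.atoms[0].index)
        self.root = self.tree.root
        self.conf = ligand.coords
        self.n_torsions = self.tree.n_torsions
        # intramolecular pairs: atoms in different rigid fragments, >3 bonds apart
        self._intra_pairs = self._find_intra_pairs(ligand, params)

    def _find_intra_pairs(self, ligand: Ligand, params: LJParamSet):
        if self.n_torsions == 0:
            return None
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(a.index for a in ligand.atoms)
        g.add_edges_from((a, b) for a, b, _ in ligand.bonds)
        frag = {a.index: 0 for a in ligand.atoms}
        for k, mv in enumerate(self.tree.moving_sets, start=1):
            for i in mv:
                frag[int(i)] = k
        lengths = dict(nx.all_pairs_shortest_path_length(g, cutoff=3))
        pairs, eps, rmin = [], [], []
        for a in ligand.atoms:
            for b in ligand.atoms:
                if b.index <= a.index or a.is_dummy or b.is_dummy:
                    continue
                if frag[a.index] == frag[b.index]:
                    continue
                if b.index in lengths.get(a.index, {}):
                    continue  # 1-2, 1-3, 1-4 kept out: near-constant terms
                e, rm, _ = self.model.params.get_pair(a.ad_type, b.ad_type)
                pairs.append((a.index, b.index))
                eps.append(e)
                rmin.append(rm)
        if not pairs:
            return None
        return (np.array(pairs), np.array(eps), np.array(rmin))

    def _coords_raw(self, t: np.ndarray, q: np.ndarray,
                    tor: np.ndarray) -> np.ndarray:
        xyz = self.conf
        if self.n_torsions:
            xyz = apply_torsions(xyz, self.tree, tor)
        rot = _quat_to_matrix(q)
        return (xyz - self.conf[self.root]) @ rot.T + t

    def coordinates(self, genome: Genome) -> np.ndarray:
        return self._coords_raw(genome.translation, genome.orientation,
                                genome.torsions)

    def intra_energy(self, xyz: np.ndarray) -> float:
        if self._intra_pairs is None:
            return 0.0
        idx, eps, rmin = self._intra_pairs
        d = np.linalg.norm(xyz[idx[:, 0]] - xyz[idx[:, 1]], axis=1)
        d = np.maximum(d, 0.3)
        x = rmin / d
        x6 = x**6
        return float(np.sum(eps * (x6 * x6 - 2.0 * x6)))

    def objective(self, genome: Genome) -> float:
        return self.objective_vector(genome.as_vector())

    def objective_vector(self, v: np.ndarray) -> float:
        q = v[3:7]
        n = np.sqrt((q * q).sum())
        xyz = self._coords_raw(v[:3], q / n, v[7:])
        e = self.model.total(xyz) + self.intra_energy(xyz)
        excess = np.abs(xyz[self.root] - self.box.center) - self.box.size / 2
        np.maximum(excess, 0.0, out=excess)
        return e + self.BOX_PENALTY * float((excess * excess).sum())

    def pose(self, genome: Genome) -> Pose:
        xyz = self.coordinates(genome)
        bd = self.model.breakdown(xyz)
        return Pose(coordinates=xyz, energy=bd.total, genome=genome, breakdown=bd)


def randomize(ligand: Ligand, box: DockingBox, rng: np.random.Generator) -> Genome:
    """Unbiased initial genome: uniform root position in the box, uniform
    random rotation (normalized 4-normal quaternion), uniform torsions."""
    t = box.center + (rng.random(3) - 0.5) * box.size
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    n_tor = ligand.torsion_tree.n_torsions if ligand.torsion_tree else 0
    tor = rng.uniform(-np.pi, np.pi, size=n_tor)
    return Genome(translation=t, orientation=q, torsions=tor)


def local_search(genome: Genome, energy_fn, config: LocalSearchConfig | None = None,
                 rng: np.random.Generator | None = None) -> Genome:
    """Solis-Wets stochastic hill descent on the genome vector.

    ``energy_fn`` maps a genome vector to a scalar. The step scale expands
    after repeated successes and contracts after repeated failures; a bias
    vector accumulates the successful direction. The returned genome never
    has a higher energy than the input.
    """
    cfg = config or LocalSearchConfig()
    rng = rng or np.random.default_rng()
    v = genome.as_vector()
    dim = v.size
    scale = np.ones(dim)
    scale[:3] = 1.0          # translation, Å
    scale[3:7] = 0.1         # quaternion components
    scale[7:] = 0.3          # torsions, rad
    best = energy_fn(v)
    rho = cfg.rho_initial
    bias = np.zeros(dim)
    succ = fail = 0
    for _ in range(cfg.iterations):
        step = rng.normal(size=dim) * rho * scale + bias
        for cand_v in (v + step, v - step):
            q = cand_v[3:7]
            n = np.linalg.norm(q)
            if n < 1e-9:
                continue
            cand_v = cand_v.copy()
            cand_v[3:7] = q / n
            e = energy_fn(cand_v)
            if e < best:
                bias = 0.4 * bias + 0.2 * (cand_v - v)
                v, best = cand_v, e
                succ += 1
                fail = 0
                break
        else:
            bias *= 0.5
            fail += 1
            succ = 0
        if succ >= cfg.success_limit:
            rho *= cfg.expansion
            succ = 0
        elif fail >= cfg.failure_limit:
            rho *= cfg.contraction
            fail = 0
        if rho < cfg.rho_min:
            break
    return Genome.from_vector(v)


def _mutate(v: np.ndarray, cfg: GAConfig, rng: np.random.Generator) -> np.ndarray:
    out = v.copy()
    if rng.random() < cfg.mutation_rate:
        out[:3] += rng.normal(size=3) * cfg.sigma_translation
    if rng.random() < cfg.mutation_rate:
        axis = rng.normal(size=3)
        axis /= max(np.linalg.norm(axis), 1e-12)
        ang = rng.normal() * cfg.sigma_rotation
        dq = np.concatenate([[np.cos(ang / 2)], np.sin(ang / 2) * axis])
        w1, x1, y1, z1 = dq
        w2, x2, y2, z2 = out[3:7]
        out[3:7] = [w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
                    w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
                    w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
                    w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2]
        out[3:7] /= np.linalg.norm(out[3:7])
    for k in range(7, v.size):
        if rng.random() < cfg.mutation_rate:
            out[k] += rng.normal() * cfg.sigma_torsion
    return out


def _crossover(a: np.ndarray, b: np.ndarray, rng: np.random.Generator):
    """Two-point crossover respecting genome segments (translation,
    orientation, each torsion)."""
    bounds = [0, 3, 7] + list(range(8, a.size + 1))
    n_seg = len(bounds) - 1
    if n_seg < 2:
        return a.copy(), b.copy()
    i, j = sorted(rng.choice(n_seg, size=2, replace=False))
    c1, c2 = a.copy(), b.copy()
    lo, hi = bounds[i], bounds[j + 1]
    c1[lo:hi], c2[lo:hi] = b[lo:hi].copy(), a[lo:hi].copy()
    return c1, c2


def _ga_run(energy: GenomeEnergy, ligand: Ligand, box: DockingBox,
            cfg: GAConfig, rng: np.random.Generator) -> Genome:
    pop = [randomize(ligand, box, rng).as_vector() for _ in range(cfg.population)]
    fit = np.array([energy.objective_vector(v) for v in pop])
    if not np.any(np.isfinite(fit)):
        raise RuntimeError("no finite-energy individual after initialization; "
                           "try a larger box or fewer clashes")
    ls_cfg = LocalSearchConfig(iterations=cfg.local_search_iterations)
    n_ls = max(1, int(round(cfg.local_search_fraction * cfg.population)))
    n_imm = int(round(cfg.immigrant_fraction * cfg.population))
    for _ in range(cfg.generations):
        order = np.argsort(fit)
        new_pop = [pop[i].copy() for i in order[:cfg.elitism]]
        for _ in range(n_imm):
            new_pop.append(randomize(ligand, box, rng).as_vector())
        while len(new_pop) < cfg.population:
            # tournament selection
            picks = []
            for _ in range(2):
                cand = rng.integers(0, cfg.population, size=cfg.tournament_size)
                picks.append(pop[cand[np.argmin(fit[cand])]])
            if rng.random() < cfg.crossover_rate:
                c1, c2 = _crossover(picks[0], picks[1], rng)
            else:
                c1, c2 = picks[0].copy(), picks[1].copy()
            for c in (c1, c2):
                if len(new_pop) < cfg.population:
                    c = _mutate(c, cfg, rng)
                    c[3:7] /= np.linalg.norm(c[3:7])
                    new_pop.append(c)
        pop = new_pop
        fit = np.array([energy.objective_vector(v) for v in pop])
        # Lamarckian step: refine the current best fraction, plus a few
        # random individuals — an unrefined genome sitting in a narrow basin
        # scores poorly and would be culled before its depth ever showed
        chosen = list(np.argsort(fit)[:n_ls])
        chosen.extend(int(i) for i in rng.integers(0, cfg.population, size=3))
        for i in dict.fromkeys(chosen):
            g = local_search(Genome.from_vector(pop[i]), energy.objective_vector,
                             ls_cfg, rng)
            pop[i] = g.as_vector()
            fit[i] = energy.objective_vector(pop[i])
    best = int(np.argmin(fit))
    final = local_search(Genome.from_vector(pop[best]), energy.objective_vector,
                         LocalSearchConfig(iterations=800), rng)
    # basin-hopping polish: near-native minima are often separated by
    # sub-kcal barriers that a single stochastic descent cannot cross
    best_v = final.as_vector()
    best_e = energy.objective_vector(best_v)
    for _ in range(12):
        v = best_v.copy()
        v[:3] += rng.normal(size=3) * 0.4
        v[3:7] += rng.normal(size=4) * 0.08
        v[3:7] /= np.linalg.norm(v[3:7])
        v[7:] += rng.normal(size=v.size - 7) * 0.25
        g = local_search(Genome.from_vector(v), energy.objective_vector,
                         LocalSearchConfig(iterations=300), rng)
        e = energy.objective_vector(g.as_vector())
        if e < best_e:
            best_v, best_e = g.as_vector(), e
    # deterministic derivative-free polish to the bottom of the basin
    from scipy.optimize import minimize
    res = minimize(energy.objective_vector, best_v, method="Powell",
                   options={"maxfev": 4000, "xtol": 1e-8, "ftol": 1e-10})
    if res.fun < best_e:
        best_v = res.x
    return Genome.from_vector(best_v)


def ga_dock(ligand: Ligand, receptor: Receptor, params: LJParamSet,
            box: DockingBox, n_runs: int = 10, ga_config: GAConfig | None = None,
            seed: int | np.random.SeedSequence = 0) -> list[Pose]:
    """Run ``n_runs`` independent GA searches and return poses sorted by energy.

    Fully reproducible for a given seed. Each run starts from a fresh
    :func:`randomize` genome so the input pose introduces no bias.
    """
    cfg = ga_config or GAConfig()
    if cfg.population < 4:
        raise ValueError("population must be at least 4")
    energy = GenomeEnergy(ligand, receptor, params, box)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    poses = []
    for child in ss.spawn(n_runs):
        rng = np.random.default_rng(child)
        genome = _ga_run(energy, ligand, box, cfg, rng)
        poses.append(energy.pose(genome))
    poses.sort(key=lambda p: p.energy)
    return poses
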