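"""Deterministic generators of toy complexes, pockets and fitting problems.

Real benchmark data for metal-complex docking means curated PDB entries plus
quantum-derived charges; none of the contracts in this package depend on
that, only on typed, charged atoms at known positions. These generators
therefore build abstract but geometrically sensible objects:

* :func:`make_toy_complex` — a metal with ideal-geometry ligating nitrogens
  and an optional organic arm contributing rotatable bonds;
* :func:`make_pocket` — a rigid shell of typed receptor atoms arranged so a
  planted ligand pose sits at (very nearly) the energy minimum: each anchor
  atom is placed exactly at its pair's R_min from a designated ligand atom,
  where the pair force vanishes;
* :func:`make_fit_problem` — training pairs whose docked-pose error is
  minimized at a known well-depth vector, plus a fast surrogate dock
  function, enabling parameter-recovery tests of the Monte Carlo fitter.

Everything is a pure function of (spec, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .atom_typing import assign_types, build_torsion_tree
from .coordination import add_vacancy_dummy
from .docking import DockingBox, Genome, Pose, GenomeEnergy, randomize
from .mol_model import Atom, Ligand, Receptor, perceive_bonds, write_pdbqt, write_xyz
from .param_opt import TrainingPair
from .scoring import (LJParamSet, default_params, mehler_solmajer_dielectric,
                      COULOMB_CONSTANT, _MS_B, _MS_K, _MS_LAMBDA)

__all__ = ["PocketSpec", "make_toy_complex", "make_pocket", "make_fit_problem",
           "surrogate_dock", "axial_equilibrium", "write_fit_manifest"]

GEOMETRIES: dict[str, np.ndarray] = {
    "linear": np.array([[1, 0, 0], [-1, 0, 0]], float),
    "trigonal-planar": np.array(
        [[1, 0, 0], [-0.5, np.sqrt(3) / 2, 0], [-0.5, -np.sqrt(3) / 2, 0]]),
    "fac": np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]], float),
    "square-planar": np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]], float),
    "tetrahedral": np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3),
    "square-pyramidal": np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, -1]], float),
    "trigonal-bipyramidal": np.array(
        [[0, 0, 1], [0, 0, -1], [1, 0, 0], [-0.5, np.sqrt(3) / 2, 0],
         [-0.5, -np.sqrt(3) / 2, 0]]),
    "octahedral": np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                            [0, 0, 1], [0, 0, -1]], float),
}

DEFAULT_GEOMETRY = {2: "linear", 3: "trigonal-planar", 4: "square-planar",
                    5: "square-pyramidal", 6: "octahedral"}

METAL_LIGATOR_DISTANCE = 2.0   # Å
CC_BOND = 1.52                 # Å, arm bond length
ARM_HALF_ANGLE = np.radians(35.0)
METAL_CHARGE = 0.4             # e, toy partial charge on the metal


def make_toy_complex(metal: str = "Ru", coordination_number: int = 5,
                     n_torsions: int = 1, seed: int = 0,
                     geometry: str | None = None, formal_charge: float = 0.0,
                     arm_terminal: str = "C") -> Ligand:
    """Metal at the origin, ligating N atoms at ideal geometry, and (for
    ``n_torsions > 0``) a zigzag heavy-atom arm on the +x ligator providing
    exactly the requested number of rotatable bonds. Charges are toy values
    summing to ``formal_charge``. Deterministic for a given argument set.
    """
    cn = coordination_number
    if cn not in DEFAULT_GEOMETRY:
        raise ValueError(f"coordination number must be 2-6, got {cn}")
    if n_torsions > 10:
        raise ValueError("more than 10 rotatable bonds is not supported")
    gname = geometry or DEFAULT_GEOMETRY[cn]
    dirs = GEOMETRIES[gname]
    if len(dirs) != cn:
        raise ValueError(f"geometry {gname!r} has {len(dirs)} sites, not {cn}")
    atoms = [Atom(index=0, element=metal, coords=np.zeros(3),
                  partial_charge=METAL_CHARGE)]
    ligator_charge = (formal_charge - METAL_CHARGE) / cn
    for k, d in enumerate(dirs):
        atoms.append(Atom(index=k + 1, element="N",
                          coords=METAL_LIGATOR_DISTANCE * d,
                          partial_charge=ligator_charge))
    if n_torsions > 0:
        # arm on the +x ligator: n_torsions + 2 heavy atoms in a zigzag
        n_arm = n_torsions + 2
        pos = atoms[1].coords.copy()
        for k in range(n_arm):
            step = CC_BOND * np.array([np.cos(ARM_HALF_ANGLE),
                                       np.sin(ARM_HALF_ANGLE) * (1 if k % 2 == 0 else -1),
                                       0.0])
            pos = pos + step
            el = arm_terminal if k == n_arm - 1 else "C"
            atoms.append(Atom(index=len(atoms), element=el, coords=pos.copy()))
    lig = Ligand(atoms=atoms)
    lig.bonds = perceive_bonds(atoms)
    assign_types(lig)
    lig.torsion_tree = build_torsion_tree(lig)
    lig.validate()
    return lig


@dataclass
class PocketSpec:
    """Recipe for a planted-pose pocket.

    ``metal_eps_oa`` is the generating well depth of the planted metal-OA
    coordination bond: the pocket emulates a complex docked under an already
    fitted parameter set, where the coordination term is the dominant,
    direction-weighted feature (fitted depths in this force field reach
    ~5-6 kcal/mol), not under the 2 kcal/mol pre-fit placeholder.
    """
    metal: str = "Ru"
    coordination_number: int = 5
    n_torsions: int = 1
    metal_eps_oa: float = 5.0       # kcal/mol, generating coordination depth
    shell_atoms: int = 8
    shell_radius: float = 8.5       # Å shell radius around the planted metal;
                                    # beyond the LJ cutoff the shell is inert
                                    # bulk, so the planted optimum stays where
                                    # the anchor construction puts it
    shell_clearance: float = 3.4    # Å min distance cage <-> ligand/anchors
    box_edge: float = 10.0          # Å
    anchor_charge: float = -0.4     # e, carboxylate-like axial acceptor: adds
                                    # an electrostatic funnel only the metal
                                    # (the one positive ligand atom) feels
    verify_random_poses: int = 10_000


@dataclass
class PocketProblem:
    """A planted docking problem: everything needed to dock and to score."""
    ligand: Ligand
    receptor: Receptor
    planted: Pose
    box: DockingBox
    params: LJParamSet


def pocket_problem(spec: PocketSpec | None = None, seed: int = 0) -> PocketProblem:
    """Build a rigid pocket around a planted toy-complex pose.

    Anchors: an OA acceptor on the vacancy axis at the metal-OA R_min (the
    coordination site the docking should recover) and — when the ligand has
    an arm — an HD donor at the HD-OA R_min from the arm's terminal oxygen,
    which pins the arm torsion and the rotation about the vacancy axis. Each
    anchor sits exactly at its pair's minimum-energy distance from its
    designated ligand atom, so the pair forces vanish at the planted pose. A
    shell of carbon atoms at ``shell_radius`` provides bulk. At generation
    time the planted pose is verified to score below ``verify_random_poses``
    random poses under the generating parameters.
    """
    spec = spec or PocketSpec()
    rng = np.random.default_rng(seed)
    lig = make_toy_complex(metal=spec.metal,
                           coordination_number=spec.coordination_number,
                           n_torsions=spec.n_torsions, seed=seed,
                           arm_terminal="O" if spec.n_torsions > 0 else "C")
    # seeded rigid rotation of the whole problem: pockets differ genuinely in
    # genome space while the anchor construction (and hence the location of
    # the optimum) is carried along equivariantly
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    for a in lig.atoms:
        a.coords = rot @ a.coords
    add_vacancy_dummy(lig, vacant_site=True)
    lig.torsion_tree = build_torsion_tree(lig)
    params = default_params(metals=(spec.metal,))
    params.set_metal_epsilon(spec.metal, "OA", spec.metal_eps_oa)

    metal_pos = lig.atoms[lig.metal_index].coords
    dummy_dir = lig.atoms[lig.dummy_index].coords - metal_pos
    dummy_dir = dummy_dir / np.linalg.norm(dummy_dir)

    rec_atoms: list[Atom] = []

    def add(element, ad_type, coords, charge=0.0, tag="PKT:1:A"):
        rec_atoms.append(Atom(index=len(rec_atoms), element=element,
                              coords=np.asarray(coords, float),
                              partial_charge=charge, ad_type=ad_type,
                              residue_tag=tag))

    # axial acceptor at the metal-OA R_min along the vacancy axis; a cap of
    # carbons behind it (carboxylate-carbon-like) forces the coordination
    # approach to come from the planted side — a bare acceptor point would
    # accept the metal from any direction
    _, rmin_moa, _ = params.get_pair(spec.metal, "OA")
    anchor_pos = metal_pos + rmin_moa * dummy_dir
    add("O", "OA", anchor_pos, charge=spec.anchor_charge)
    e1 = np.array([1.0, 0, 0])
    if abs(float(e1 @ dummy_dir)) > 0.9:
        e1 = np.array([0, 1.0, 0])
    u = np.cross(dummy_dir, e1)
    u /= np.linalg.norm(u)
    v = np.cross(dummy_dir, u)
    cap_tilt = np.radians(45.0)
    for phi in (0.0, 2 * np.pi / 3, 4 * np.pi / 3):
        cap_dir = (np.cos(cap_tilt) * dummy_dir
                   + np.sin(cap_tilt) * (np.cos(phi) * u + np.sin(phi) * v))
        add("C", "C", anchor_pos + 2.2 * cap_dir)
    # steric notch around an off-axis ligating nitrogen: carbons at their
    # pair R_min bracket the +y ligator so rotations about the anchor axis
    # run into a wall. Walls only repel, so unlike donor wells they cannot
    # seed decoy minima of their own
    lig_n = lig.atoms[3]  # +y ligator for the default geometries
    n_dir = lig_n.coords - metal_pos
    n_dir = n_dir / np.linalg.norm(n_dir)
    _, rmin_cna, _ = params.get_pair("C", "NA")
    for perp in (np.cross(n_dir, dummy_dir), dummy_dir):
        perp = perp / np.linalg.norm(perp)
        for sgn in (1.0, -1.0):
            p = lig_n.coords + sgn * rmin_cna * perp
            if np.min(np.linalg.norm(lig.coords - p, axis=1)) < rmin_cna - 1e-6:
                continue
            add("C", "C", p)
    # clamp on the first arm carbon: that atom is rigid with the core but
    # sits far off the vacancy axis, so walls around it pin the rotation
    # about that axis — a mode the arm torsion could otherwise compensate
    # while every anchor stayed satisfied
    if spec.n_torsions > 0:
        c_first = lig.atoms[1 + spec.coordination_number]
        arm_dir = c_first.coords - metal_pos
        arm_dir = arm_dir / np.linalg.norm(arm_dir)
        _, rmin_cc, _ = params.get_pair("C", "C")
        for perp in (np.cross(arm_dir, dummy_dir), dummy_dir):
            perp = perp / np.linalg.norm(perp)
            for sgn in (1.0, -1.0):
                p = c_first.coords + sgn * rmin_cc * perp
                if np.min(np.linalg.norm(lig.coords - p, axis=1)) < rmin_cc - 1.0:
                    continue
                add("C", "C", p)
    # arm lock: donor hydrogen (with its carbon parent — a bare H could bury
    # itself between several acceptors, which real donors cannot do) off the
    # arm's terminal oxygen; too far from the core to be reachable by the
    # ligating nitrogens while the metal stays coordinated
    if spec.n_torsions > 0:
        term = lig.atoms[max(a.index for a in lig.atoms if not a.is_dummy)]
        t_dir = term.coords - lig.atoms[1].coords
        t_dir = t_dir / np.linalg.norm(t_dir)
        _, rmin_hdoa, _ = params.get_pair("HD", "OA")
        h_pos = term.coords + rmin_hdoa * t_dir
        add("H", "HD", h_pos, charge=0.08)
        add("C", "C", h_pos + 1.1 * t_dir, charge=0.0)
    # sparse far carbon shell: bulk context without offering a nonspecific
    # adsorption surface that could compete with the anchor contacts (this
    # force field carries no desolvation term, so dense walls would bind)
    lig_xyz = lig.coords
    placed = guard = 0
    while placed < spec.shell_atoms and guard < 10_000:
        guard += 1
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        p = metal_pos + spec.shell_radius * v
        others = np.array([a.coords for a in rec_atoms])
        if np.min(np.linalg.norm(lig_xyz - p, axis=1)) < spec.shell_clearance:
            continue
        if len(others) and np.min(np.linalg.norm(others - p, axis=1)) < 4.0:
            continue
        add("C", "C", p)
        placed += 1
    receptor = Receptor(atoms=rec_atoms)

    box = DockingBox(center=metal_pos.copy(),
                     size=np.full(3, float(spec.box_edge)))
    energy = GenomeEnergy(lig, receptor, params, box)
    planted_genome = Genome(translation=lig.coords[energy.root],
                            orientation=np.array([1.0, 0, 0, 0]),
                            torsions=np.zeros(lig.torsion_tree.n_torsions))
    planted = energy.pose(planted_genome)
    if spec.verify_random_poses:
        check_rng = np.random.default_rng(np.random.SeedSequence([seed, 3221]))
        e_planted = energy.objective(planted_genome)
        for _ in range(spec.verify_random_poses):
            g = randomize(lig, box, check_rng)
            if energy.objective(g) < e_planted:
                raise RuntimeError(
                    "pocket generation failed: a random pose scored below the "
                    "planted pose")
    return PocketProblem(ligand=lig, receptor=receptor, planted=planted,
                         box=box, params=params)


def make_pocket(spec: PocketSpec | None = None, seed: int = 0
                ) -> tuple[Receptor, Pose, DockingBox]:
    """Receptor, planted reference pose and box; see :func:`pocket_problem`."""
    prob = pocket_problem(spec, seed)
    return prob.receptor, prob.planted, prob.box


# ---------------------------------------------------------------------------
# parameter-fit problems
# ---------------------------------------------------------------------------

def axial_equilibrium(epsilon: float, rmin: float, exponents: tuple[int, int],
                      q_product: float, r_cap: float | None = None) -> float:
    """Equilibrium metal-anchor distance for one LJ pair opposed by a
    like-charge screened Coulomb repulsion.

    Solves dE/dr = 0 on the attractive branch to high precision; when the
    well is too shallow to bind against the repulsion, the capped distance
    ``r_cap`` (default R_min + 3 Å) is returned — the complex unbinds.
    """
    cap = r_cap if r_cap is not None else rmin + 3.0
    k = COULOMB_CONSTANT * q_product

    def dE(r):
        r = np.asarray(r, dtype=float)
        x = rmin / r
        if exponents == (12, 6):
            dlj = epsilon * (-12 * x**12 + 12 * x**6) / r
        else:
            dlj = epsilon * (-60 * x**12 + 60 * x**10) / r
        ms = mehler_solmajer_dielectric(r)
        lam = _MS_LAMBDA * _MS_B
        e = np.exp(-lam * r)
        dms = _MS_B * _MS_K * lam * e / (1.0 + _MS_K * e) ** 2
        dc = -k * (ms + r * dms) / (ms * ms * r * r)
        return dlj + dc

    if epsilon <= 0:
        return cap
    grid = np.linspace(0.9 * rmin, cap, 400)
    vals = dE(grid)
    pos = np.where(vals > 0)[0]
    if len(pos) == 0:
        return cap
    i = pos[0]
    if i == 0:
        return float(grid[0])
    return float(brentq(lambda r: float(dE(r)), grid[i - 1], grid[i], xtol=1e-12))


@dataclass
class _FitPair:
    pair: TrainingPair
    probe_type: str
    anchor_pos: np.ndarray
    q_product: float
    template_coords: np.ndarray
    axis: np.ndarray


def make_fit_problem(true_eps: dict[str, float] | tuple[float, float, float, float],
                     n_pairs: int = 4, seed: int = 0, metal: str = "Ru",
                     params: LJParamSet | None = None):
    """Training pairs whose pose error is minimized at ``true_eps``.

    Each pair is a toy complex facing a single anchor of one probed type
    (cycling HD, NA, OA, SA); the reference coordinates put the metal at the
    equilibrium distance computed under ``true_eps``. Returns
    ``(training_set, dock_fn, fit_pairs)`` where ``dock_fn`` is the surrogate
    docker: it re-equilibrates the dominant metal-anchor interaction under
    the current parameters and returns the 10 identical poses of its single
    deterministic minimum.
    """
    order = ("HD", "NA", "OA", "SA")
    if not isinstance(true_eps, dict):
        true_eps = dict(zip(order, true_eps))
    params = params or default_params(metals=(metal,))
    anchor_element = {"HD": "H", "NA": "N", "OA": "O", "SA": "S"}
    anchor_charge = 0.05
    training, fit_pairs = [], []
    for k in range(n_pairs):
        t = order[k % 4]
        lig = make_toy_complex(metal=metal, coordination_number=5, n_torsions=0,
                               seed=seed + k)
        add_vacancy_dummy(lig, vacant_site=True)
        lig.torsion_tree = build_torsion_tree(lig)
        _, rmin, exps = params.get_pair(metal, t)
        qprod = METAL_CHARGE * anchor_charge
        r_true = axial_equilibrium(true_eps[t], rmin, exps, qprod)
        anchor_pos = np.zeros(3)
        axis = np.array([0.0, 0.0, 1.0])
        # reference: metal below the anchor at the true equilibrium distance
        ref = lig.coords + (anchor_pos - r_true * axis)
        # ligand file/planted coords: start from a deliberately wrong distance
        start = lig.coords + (anchor_pos - (rmin + 1.0) * axis)
        lig.set_coords(start)
        rec_atoms = [Atom(index=0, element=anchor_element[t],
                          coords=anchor_pos.copy(), partial_charge=anchor_charge,
                          ad_type=t, residue_tag="ANC:1:A")]
        for j, sv in enumerate(((4.0, 0, 2.0), (-4.0, 0, 2.0), (0, 4.0, 2.0))):
            rec_atoms.append(Atom(index=j + 1, element="C",
                                  coords=np.array(sv, float), ad_type="C",
                                  residue_tag="PKT:2:A"))
        receptor = Receptor(atoms=rec_atoms)
        box = DockingBox(center=anchor_pos - rmin * axis, size=np.full(3, 20.0))
        pair = TrainingPair(ligand=lig, receptor=receptor, reference_coords=ref,
                            box=box, label=f"{metal}-{t}-{k}")
        training.append(pair)
        fit_pairs.append(_FitPair(pair=pair, probe_type=t, anchor_pos=anchor_pos,
                                  q_product=qprod, template_coords=lig.coords,
                                  axis=axis))

    lookup = {id(fp.pair): fp for fp in fit_pairs}

    def dock_fn(pair: TrainingPair, p: LJParamSet, seed_: int,
                n_poses: int = 10) -> list[np.ndarray]:
        fp = lookup[id(pair)]
        eps, rmin, exps = p.get_pair(metal, fp.probe_type)
        r_hat = axial_equilibrium(eps, rmin, exps, fp.q_product)
        metal_xyz = fp.anchor_pos - r_hat * fp.axis
        shift = metal_xyz - fp.template_coords[pair.ligand.metal_index]
        coords = fp.template_coords + shift
        return [coords.copy() for _ in range(n_poses)]

    return training, dock_fn, fit_pairs


def write_fit_manifest(training: list[TrainingPair], out_dir: str | Path) -> Path:
    """Write ligand XYZ / receptor PDBQT / reference XYZ files plus the
    fit-params manifest TSV; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = ["ligand\treceptor\treference\tcx\tcy\tcz\tsx\tsy\tsz"]
    for i, pair in enumerate(training):
        lp = out / f"ligand_{i}.xyz"
        rp = out / f"receptor_{i}.pdbqt"
        fp = out / f"reference_{i}.xyz"
        write_xyz(pair.ligand, lp)
        write_pdbqt(pair.receptor, rp)
        ref_lig = Ligand(atoms=[Atom(index=a.index, element=a.element,
                                     coords=c, partial_charge=a.partial_charge)
                                for a, c in zip(pair.ligand.atoms,
                                                pair.reference_coords)])
        write_xyz(ref_lig, fp)
        c, s = pair.box.center, pair.box.size
        rows.append(f"{lp}\t{rp}\t{fp}\t{c[0]:g}\t{c[1]:g}\t{c[2]:g}"
                    f"\t{s[0]:g}\t{s[1]:g}\t{s[2]:g}")
    manifest = out / "manifest.tsv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest
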