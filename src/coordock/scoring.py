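"""Pairwise intermolecular energy: Lennard-Jones 12-6/12-10, metal parameters,
screened electrostatics and the dummy-directed metal hydrogen-bond weight.

Two LJ forms are used, both normalized so the well depth is exactly -ε at
r = R_min:

    (12,6)  : E(r) = ε [ (R_min/r)^12 - 2 (R_min/r)^6 ]
    (12,10) : E(r) = ε [ 5 (R_min/r)^12 - 6 (R_min/r)^10 ]

The 12-10 form is the hydrogen-bond-like potential used for the metal's
interaction with acceptor types NA/OA/SA (a coordination bond is directional
and polar, like a hydrogen bond); the 12-6 form covers everything else,
including the metal-HD term that approximates metal-assisted deprotonation of
e.g. cysteine S-H. Electrostatics follow the AutoDock lineage: a Coulomb term
screened by the Mehler-Solmajer sigmoidal distance-dependent dielectric.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mol_model import Ligand, MoleculeError, Receptor
from .periodic import (ACCEPTOR_TYPES, METAL_RII_DEFAULT, METALS, ORGANIC_TYPES,
                       VDW_EPS, VDW_RII, is_metal)

__all__ = [
    "LJParamSet", "EnergyBreakdown", "EnergyModel",
    "lj_energy", "load_params", "default_params",
    "hbond_weight", "electrostatic_energy", "intermolecular_energy",
    "COULOMB_CONSTANT",
]

COULOMB_CONSTANT = 332.06   # kcal Å / (mol e^2)

# printed metal-pair defaults: R_min (Å) per protein type and the fixed
# metal-metal well depth (iron's value)
METAL_RMIN = {"HD": 1.00, "NA": 2.20, "OA": 2.25, "SA": 2.30}
METAL_METAL_EPSILON = 0.010   # kcal/mol
DEFAULT_METAL_EPSILON = 2.0   # kcal/mol starting value before any fitting

# Mehler-Solmajer sigmoidal dielectric constants
_MS_EPS0 = 78.4
_MS_A = -8.5525
_MS_LAMBDA = 0.003627
_MS_K = 7.7839
_MS_B = _MS_EPS0 - _MS_A

LJ_CUTOFF = 8.0       # Å
ELEC_CUTOFF = 20.0    # Å


def lj_energy(r, epsilon: float, rmin: float, exponents: tuple[int, int] = (12, 6)):
    """Lennard-Jones energy (kcal/mol) at separation ``r`` (Å); vectorized."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("separation must be positive")
    x = rmin / r
    if exponents == (12, 6):
        e = epsilon * (x**12 - 2.0 * x**6)
    elif exponents == (12, 10):
        e = epsilon * (5.0 * x**12 - 6.0 * x**10)
    else:
        raise ValueError(f"unsupported exponent pair {exponents}")
    return float(e) if e.ndim == 0 else e


def mehler_solmajer_dielectric(r):
    r = np.asarray(r, dtype=float)
    return _MS_A + _MS_B / (1.0 + _MS_K * np.exp(-_MS_LAMBDA * _MS_B * r))


def electrostatic_energy(q_i: float, q_j: float, r):
    """Screened Coulomb energy, kcal/mol."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("separation must be positive")
    e = COULOMB_CONSTANT * q_i * q_j / (mehler_solmajer_dielectric(r) * r)
    return float(e) if e.ndim == 0 else e


def hbond_weight(metal_pos, dummy_pos, acceptor_pos) -> float:
    """Angular weight in [0,1] for the metal-acceptor coordination well.

    w = cos²θ with θ the angle between metal->dummy and metal->acceptor,
    zero beyond 90°. Without a dummy the interaction is isotropic (w = 1).
    """
    if dummy_pos is None:
        return 1.0
    u = np.asarray(dummy_pos, float) - np.asarray(metal_pos, float)
    v = np.asarray(acceptor_pos, float) - np.asarray(metal_pos, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        return 1.0
    c = float(u @ v / (nu * nv))
    return c * c if c > 0.0 else 0.0


# ---------------------------------------------------------------------------
# parameter set
# ---------------------------------------------------------------------------

@dataclass
class LJParamSet:
    """Per ordered-type-pair well depth (kcal/mol), R_min (Å) and exponents.

    Lookup is symmetric. Unlisted pairs are derived lazily by Lorentz-
    Berthelot combination of the like-pair table (12,6), so the set stays
    closed over any metal element that appears.
    """
    pairs: dict[tuple[str, str], tuple[float, float, tuple[int, int]]] = field(
        default_factory=dict)
    metal_rii: dict[str, float] = field(default_factory=dict)
    metal_epsilon_self: dict[str, float] = field(default_factory=dict)
    solvation_volume: dict[str, float] = field(default_factory=dict)  # stored, unused

    def set_pair(self, ti: str, tj: str, epsilon: float, rmin: float,
                 exponents: tuple[int, int] = (12, 6)) -> None:
        if epsilon < 0 or rmin <= 0:
            raise ValueError(f"invalid LJ parameters for ({ti},{tj}): "
                             f"ε={epsilon}, R_min={rmin}")
        key = tuple(sorted((ti, tj)))
        self.pairs[key] = (float(epsilon), float(rmin), exponents)

    def get_pair(self, ti: str, tj: str) -> tuple[float, float, tuple[int, int]]:
        key = tuple(sorted((ti, tj)))
        hit = self.pairs.get(key)
        if hit is not None:
            return hit
        derived = self._combine(ti, tj)
        if derived is None:
            raise MoleculeError(f"no LJ parameters for type pair ({ti}, {tj})")
        self.pairs[key] = derived
        return derived

    def _like_pair(self, t: str) -> tuple[float, float] | None:
        """(Rii, eps_ii) for a single type."""
        if t in VDW_RII:
            return VDW_RII[t], VDW_EPS[t]
        if is_metal(t):
            return (self.metal_rii.get(t, METAL_RII_DEFAULT),
                    self.metal_epsilon_self.get(t, METAL_METAL_EPSILON))
        return None

    def _combine(self, ti: str, tj: str):
        a, b = self._like_pair(ti), self._like_pair(tj)
        if a is None or b is None:
            return None
        rmin = 0.5 * (a[0] + b[0])
        eps = float(np.sqrt(a[1] * b[1]))
        return (eps, rmin, (12, 6))

    def metal_epsilons(self, metal: str) -> dict[str, float]:
        """Current well depths of the four fitted metal-protein terms."""
        return {t: self.get_pair(metal, t)[0] for t in ("HD", "NA", "OA", "SA")}

    def set_metal_epsilon(self, metal: str, protein_type: str, epsilon: float) -> None:
        _, rmin, exps = self.get_pair(metal, protein_type)
        self.set_pair(metal, protein_type, epsilon, rmin, exps)


def default_params(metals: tuple[str, ...] = ()) -> LJParamSet:
    """Build the shipped default table.

    Organic pairs: Lorentz-Berthelot 12-6 from the AutoDock4-lineage like-pair
    table, with explicit 12-10 hydrogen-bond wells for HD against NA/OA/SA.
    Metal pairs: R_min HD/NA/OA/SA = 1.00/2.20/2.25/2.30 Å with a 2 kcal/mol
    placeholder well depth awaiting fitting; 12-10 for the acceptor types,
    12-6 for HD; metal-metal ε pinned at 0.010 kcal/mol.
    """
    ps = LJParamSet()
    for i, ti in enumerate(ORGANIC_TYPES):
        for tj in ORGANIC_TYPES[i:]:
            eps = float(np.sqrt(VDW_EPS[ti] * VDW_EPS[tj]))
            rmin = 0.5 * (VDW_RII[ti] + VDW_RII[tj])
            ps.set_pair(ti, tj, eps, rmin, (12, 6))
    # donor-H / acceptor hydrogen bonds (AutoDock4 values)
    ps.set_pair("HD", "OA", 5.0, 1.9, (12, 10))
    ps.set_pair("HD", "NA", 5.0, 1.9, (12, 10))
    ps.set_pair("HD", "SA", 1.0, 2.5, (12, 10))
    for m in metals:
        _add_metal_defaults(ps, m)
    return ps


def _add_metal_defaults(ps: LJParamSet, metal: str) -> None:
    if not is_metal(metal):
        raise ValueError(f"{metal!r} is not a recognized metal element")
    ps.set_pair(metal, "HD", DEFAULT_METAL_EPSILON, METAL_RMIN["HD"], (12, 6))
    for t in ACCEPTOR_TYPES:
        ps.set_pair(metal, t, DEFAULT_METAL_EPSILON, METAL_RMIN[t], (12, 10))
    ps.set_pair(metal, metal, METAL_METAL_EPSILON, ps.metal_rii.get(metal, METAL_RII_DEFAULT),
                (12, 6))


def _parse_exponents(token: str) -> tuple[int, int]:
    for sep in (",", "-", "/"):
        if sep in token:
            m, n = token.split(sep)
            return (int(m), int(n))
    raise ValueError(f"cannot parse exponent pair {token!r}")


def load_params(path: str | Path | None = None,
                metals: tuple[str, ...] = (),
                defaults: LJParamSet | None = None) -> LJParamSet:
    """Load LJ parameters: shipped defaults overlaid with a user table.

    The user file holds whitespace-separated ``TYPE_I TYPE_J EPS RMIN EXP``
    lines ('#' comments), e.g. ``Mo HD 5.62 1.00 12,6``.
    """
    ps = defaults if defaults is not None else default_params(metals)
    for m in metals:
        if tuple(sorted((m, "HD"))) not in ps.pairs:
            _add_metal_defaults(ps, m)
    if path is None:
        return ps
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"{path}:{lineno}: expected 'TYPE_I TYPE_J EPS RMIN EXP'")
        ti, tj = parts[0], parts[1]
        try:
            eps, rmin = float(parts[2]), float(parts[3])
            exps = _parse_exponents(parts[4])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
        if eps < 0 or rmin <= 0:
            raise ValueError(f"{path}:{lineno}: ε and R_min must be non-negative/positive")
        for t in (ti, tj):
            if is_metal(t) and tuple(sorted((t, "HD"))) not in ps.pairs:
                _add_metal_defaults(ps, t)
        ps.set_pair(ti, tj, eps, rmin, exps)
    return ps


def example_override_path() -> Path:
    """Shipped example override file (the two published Mo well depths)."""
    return Path(importlib.resources.files("coordock") / "data" / "mo_example_params.txt")


# ---------------------------------------------------------------------------
# energy evaluation
# ---------------------------------------------------------------------------

@dataclass
class EnergyBreakdown:
    vdw: float
    hbond_metal: float
    electrostatic: float

    @property
    def total(self) -> float:
        return self.vdw + self.hbond_metal + self.electrostatic


class EnergyModel:
    """Precomputed ligand-receptor pair tables for fast repeated scoring.

    Dummy atoms contribute no direct pair energy; their only role is the
    angular weight on the metal's 12-10 acceptor wells.
    """

    def __init__(self, ligand: Ligand, receptor: Receptor, params: LJParamSet,
                 lj_cutoff: float = LJ_CUTOFF, elec_cutoff: float = ELEC_CUTOFF):
        self.ligand = ligand
        self.receptor = receptor
        self.params = params
        self.lj_cutoff = lj_cutoff
        self.elec_cutoff = elec_cutoff
        lat = [a.ad_type for a in ligand.atoms]
        rat = [a.ad_type for a in receptor.atoms]
        if any(t is None for t in lat) or any(t is None for t in rat):
            raise MoleculeError("all atoms must be typed before scoring")
        n, m = ligand.n_atoms, receptor.n_atoms
        self.eps = np.zeros((n, m))
        self.rmin = np.ones((n, m))
        self.form1210 = np.zeros((n, m), dtype=bool)
        self.metal_hb = np.zeros((n, m), dtype=bool)  # metal-acceptor 12-10 pairs
        self.active = np.ones((n, m), dtype=bool)
        self.dummy_index = ligand.dummy_index
        self.metal_index = ligand.metal_index
        for i, a in enumerate(ligand.atoms):
            if a.is_dummy:
                self.active[i, :] = False
                continue
            for j, b in enumerate(receptor.atoms):
                eps, rmin, exps = params.get_pair(a.ad_type, b.ad_type)
                self.eps[i, j] = eps
                self.rmin[i, j] = rmin
                if exps == (12, 10):
                    self.form1210[i, j] = True
                    if i == self.metal_index and b.ad_type in ACCEPTOR_TYPES:
                        self.metal_hb[i, j] = True
        self.qq = COULOMB_CONSTANT * np.outer(ligand.charges, receptor.charges)
        if self.dummy_index is not None:
            self.qq[self.dummy_index, :] = 0.0
        self.rxyz = receptor.coords
        # flat active-pair views for the fast path
        li, rj = np.nonzero(self.active)
        self._li, self._rj = li, rj
        self._f_eps = self.eps[li, rj]
        self._f_rmin = self.rmin[li, rj]
        self._f_1210 = self.form1210[li, rj]
        self._f_hb = self.metal_hb[li, rj]
        self._f_qq = self.qq[li, rj]

    def breakdown(self, ligand_coords: np.ndarray | None = None) -> EnergyBreakdown:
        xyz = self.ligand.coords if ligand_coords is None else np.asarray(ligand_coords)
        diff = xyz[self._li] - self.rxyz[self._rj]
        r = np.sqrt((diff * diff).sum(axis=-1))
        np.maximum(r, 1e-6, out=r)
        within_lj = r < self.lj_cutoff
        x = np.where(within_lj, self._f_rmin / r, 0.0)
        x2 = x * x
        x6 = x2 * x2 * x2
        x10 = x6 * x2 * x2
        x12 = x6 * x6
        # angular weight on the attractive well of metal-acceptor 12-10 pairs
        w = 1.0
        if self.dummy_index is not None and self.metal_index is not None \
                and self._f_hb.any():
            mi = self.metal_index
            u = xyz[self.dummy_index] - xyz[mi]
            u = u / max(np.linalg.norm(u), 1e-12)
            v = self.rxyz[self._rj] - xyz[mi]
            nv = np.maximum(np.sqrt((v * v).sum(axis=-1)), 1e-12)
            c = (v @ u) / nv
            w = np.where(self._f_hb & (c > 0), c * c,
                         np.where(self._f_hb, 0.0, 1.0))
        lj = np.where(self._f_1210,
                      self._f_eps * (5.0 * x12 - 6.0 * w * x10),
                      self._f_eps * (x12 - 2.0 * x6))
        lj[~within_lj] = 0.0
        hb_term = float(lj[self._f_hb].sum()) if self._f_hb.any() else 0.0
        vdw_term = float(lj.sum()) - hb_term
        elec = np.where(r < self.elec_cutoff,
                        self._f_qq / (mehler_solmajer_dielectric(r) * r), 0.0)
        return EnergyBreakdown(vdw=vdw_term, hbond_metal=hb_term,
                               electrostatic=float(elec.sum()))

    def total(self, ligand_coords: np.ndarray | None = None) -> float:
        """Total energy only — same arithmetic as :meth:`breakdown` without
        the component bookkeeping (hot path for the GA)."""
        xyz = self.ligand.coords if ligand_coords is None else np.asarray(ligand_coords)
        diff = xyz[self._li] - self.rxyz[self._rj]
        r = np.sqrt((diff * diff).sum(axis=-1))
        np.maximum(r, 1e-6, out=r)
        within_lj = r < self.lj_cutoff
        x = np.where(within_lj, self._f_rmin / r, 0.0)
        x2 = x * x
        x6 = x2 * x2 * x2
        x10 = x6 * x2 * x2
        x12 = x6 * x6
        w = 1.0
        if self.dummy_index is not None and self.metal_index is not None \
                and self._f_hb.any():
            mi = self.metal_index
            u = xyz[self.dummy_index] - xyz[mi]
            u = u / max(np.linalg.norm(u), 1e-12)
            v = self.rxyz[self._rj] - xyz[mi]
            nv = np.maximum(np.sqrt((v * v).sum(axis=-1)), 1e-12)
            c = (v @ u) / nv
            w = np.where(self._f_hb & (c > 0), c * c,
                         np.where(self._f_hb, 0.0, 1.0))
        lj = np.where(self._f_1210,
                      self._f_eps * (5.0 * x12 - 6.0 * w * x10),
                      self._f_eps * (x12 - 2.0 * x6))
        total = float(lj[within_lj].sum())
        total += float(np.where(r < self.elec_cutoff,
                                self._f_qq / (mehler_solmajer_dielectric(r) * r),
                                0.0).sum())
        return total


def intermolecular_energy(ligand: Ligand, receptor: Receptor, params: LJParamSet,
                          ligand_coords: np.ndarray | None = None,
                          lj_cutoff: float = LJ_CUTOFF,
                          elec_cutoff: float = ELEC_CUTOFF) -> EnergyBreakdown:
    """Ligand-receptor interaction energy; see :class:`EnergyModel`."""
    model = EnergyModel(ligand, receptor, params, lj_cutoff, elec_cutoff)
    return model.breakdown(ligand_coords)
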