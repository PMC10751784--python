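"""Monte Carlo fitting of the four metal well depths (HD, NA, OA, SA).

The four ε values of one metal's protein-facing LJ terms are optimized
against a training set of reference complexes. Starting from 2 kcal/mol
each, the parameters are swept in the fixed order HD → NA → OA → SA; for
each parameter, candidate values are drawn uniformly from [0, 7] kcal/mol
(250 draws by default). Every candidate is evaluated by re-docking the whole
training set (10 poses per pair) and computing the total RMSD — the flat
mean over all pairs and poses. The default acceptance is greedy: a candidate
is kept iff its total RMSD does not exceed the best seen so far; a Metropolis
mode with configurable temperature is available for users who prefer an
annealing-style search.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .docking import DockingBox
from .evaluation import ligand_rmsd, total_rmsd
from .mol_model import Ligand, Receptor
from .scoring import LJParamSet

logger = logging.getLogger(__name__)

__all__ = ["MCState", "TrainingPair", "propose_epsilon", "mc_optimize",
           "EPSILON_RANGE", "PARAMETER_ORDER"]

EPSILON_RANGE = (0.0, 7.0)       # kcal/mol, uniform proposal support
PARAMETER_ORDER = ("HD", "NA", "OA", "SA")
DEFAULT_INIT_EPSILON = 2.0       # kcal/mol
DEFAULT_SAMPLES_PER_PARAM = 250


@dataclass
class TrainingPair:
    ligand: Ligand
    receptor: Receptor
    reference_coords: np.ndarray
    box: DockingBox
    label: str = ""


@dataclass
class MCState:
    epsilon_current: dict[str, float]
    rmsd_best: float
    history: list[dict] = field(default_factory=list)
    seed: int | None = None

    @property
    def epsilon_vector(self) -> np.ndarray:
        return np.array([self.epsilon_current[t] for t in PARAMETER_ORDER])


def propose_epsilon(rng: np.random.Generator) -> float:
    """One candidate well depth: uniform on [0, 7] kcal/mol."""
    return float(rng.uniform(*EPSILON_RANGE))


def _evaluate(training_set, dock_fn, params, metal, rmsd_mode, seed_seq):
    """Dock every pair and return the total RMSD; failed pairs are skipped
    with a warning (N adjusts automatically)."""
    rows = []
    for pair, child in zip(training_set, seed_seq.spawn(len(training_set))):
        seed = int(child.generate_state(1)[0] % (2**31))
        try:
            poses = dock_fn(pair, params, seed)
        except Exception as exc:
            warnings.warn(f"docking failed for pair {pair.label or '?'}: {exc}; "
                          "pair skipped", stacklevel=2)
            continue
        rows.append([ligand_rmsd(pair.ligand, np.asarray(p), pair.reference_coords,
                                 matching_mode=rmsd_mode) for p in poses])
    if not rows:
        raise RuntimeError("every training pair failed to dock")
    return total_rmsd(np.array(rows))


def mc_optimize(training_set: list[TrainingPair], dock_fn, metal: str,
                params: LJParamSet,
                init_epsilon: float = DEFAULT_INIT_EPSILON,
                samples_per_param: int = DEFAULT_SAMPLES_PER_PARAM,
                acceptance_mode: str = "greedy",
                temperature: float = 0.1,
                rmsd_mode: str = "ordered",
                seed: int = 0) -> MCState:
    """Coordinate-wise Monte Carlo optimization of the metal ε values.

    ``dock_fn(pair, params, seed) -> list of pose coordinate arrays`` must
    produce the poses for one training pair under the current parameters
    (the GA docker or any conforming surrogate). ``params`` is modified in
    place and holds the accepted values on return; the full proposal history
    (parameter, candidate, total RMSD, accepted flag, seed) is kept for audit.
    """
    if not training_set:
        raise ValueError("training set is empty")
    if acceptance_mode not in ("greedy", "metropolis"):
        raise ValueError(f"unknown acceptance mode {acceptance_mode!r}")
    root = np.random.SeedSequence(seed)
    for t in PARAMETER_ORDER:
        params.set_metal_epsilon(metal, t, init_epsilon)
    state = MCState(epsilon_current={t: init_epsilon for t in PARAMETER_ORDER},
                    rmsd_best=np.inf, seed=seed)
    if samples_per_param <= 0:
        return state
    accept_rng = np.random.default_rng(root.spawn(1)[0])
    state.rmsd_best = _evaluate(training_set, dock_fn, params, metal,
                                rmsd_mode, root.spawn(1)[0])
    for t in PARAMETER_ORDER:
        for _ in range(samples_per_param):
            sweep_seq = root.spawn(1)[0]
            proposal_rng = np.random.default_rng(sweep_seq)
            eps_i = propose_epsilon(proposal_rng)
            previous = state.epsilon_current[t]
            params.set_metal_epsilon(metal, t, eps_i)
            rmsd_i = _evaluate(training_set, dock_fn, params, metal,
                               rmsd_mode, sweep_seq)
            if acceptance_mode == "greedy":
                accept = rmsd_i <= state.rmsd_best
            else:
                accept = (rmsd_i <= state.rmsd_best or
                          accept_rng.random() <
                          np.exp(-(rmsd_i - state.rmsd_best) / temperature))
            state.history.append({"parameter": t, "proposed": eps_i,
                                  "rmsd": rmsd_i, "accepted": accept,
                                  "seed_entropy": sweep_seq.entropy})
            if accept:
                state.epsilon_current[t] = eps_i
                # greedy: rmsd_i <= best by construction, so this is monotone;
                # metropolis: tracks the currently accepted set, may go up
                state.rmsd_best = rmsd_i
            else:
                params.set_metal_epsilon(metal, t, previous)
        logger.info("parameter %s: ε = %.3f kcal/mol, best total RMSD %.3f Å",
                    t, state.epsilon_current[t], state.rmsd_best)
    return state
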