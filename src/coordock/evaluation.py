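"""Pose accuracy metrics: in-place RMSD, training-set aggregation, and the
RMSD-versus-resolution report.

Docked poses live in the receptor frame, so the RMSD against the reference
(crystallographic) coordinates is computed in place — no re-superposition.
The aggregate objective used for parameter fitting is the flat arithmetic
mean of the per-pair, per-pose RMSD matrix (N complex pairs × M poses).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)

__all__ = ["pose_rmsd", "ligand_rmsd", "total_rmsd", "resolution_report",
           "RMSDReport", "kabsch"]


@dataclass
class RMSDReport:
    per_pair_per_pose: np.ndarray          # (N, M) Å
    total: float                           # flat mean
    per_metal_average: dict[str, float] | None = None
    resolution_average: dict[str, float] | None = None
    difference: dict[str, float] | None = None


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    d = a - b
    return float(np.sqrt((d * d).sum() / len(a)))


def pose_rmsd(pose: np.ndarray, reference: np.ndarray,
              matching_mode: str = "ordered",
              elements: list[str] | None = None) -> float:
    """In-place RMSD (Å) between a docked pose and reference coordinates.

    ``matching_mode='ordered'`` compares atoms by position in the arrays;
    ``'element-matched'`` solves the optimal per-element assignment so that
    symmetry-equivalent atoms (e.g. the two halves of a C2 ligand) do not
    inflate the value. Dummy atoms must be excluded by the caller (see
    :func:`ligand_rmsd`).
    """
    pose = np.asarray(pose, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if pose.shape != reference.shape:
        raise ValueError(f"atom-count mismatch: pose has {len(pose)}, "
                         f"reference has {len(reference)}")
    if matching_mode == "ordered":
        return _rmsd(pose, reference)
    if matching_mode != "element-matched":
        raise ValueError(f"unknown matching mode {matching_mode!r}")
    if elements is None:
        raise ValueError("element-matched mode needs the element list")
    if len(elements) != len(pose):
        raise ValueError("element list length mismatch")
    sq = 0.0
    for el in sorted(set(elements)):
        idx = [i for i, e in enumerate(elements) if e == el]
        cost = ((pose[idx][:, None, :] - reference[idx][None, :, :])**2).sum(axis=-1)
        ri, ci = linear_sum_assignment(cost)
        sq += float(cost[ri, ci].sum())
    return float(np.sqrt(sq / len(pose)))


def ligand_rmsd(ligand, pose_coords: np.ndarray, reference_coords: np.ndarray,
                matching_mode: str = "ordered",
                include_hydrogens: bool = True) -> float:
    """RMSD between a ligand pose and a reference conformation of the same
    ligand, skipping the vacancy dummy. All-atom when hydrogens are present
    in both; pass ``include_hydrogens=False`` for heavy-atom RMSD (logged)."""
    keep = [a.index for a in ligand.atoms if not a.is_dummy]
    if not include_hydrogens:
        keep = [i for i in keep if ligand.atoms[i].element != "H"]
        logger.info("heavy-atom RMSD (hydrogens excluded)")
    els = [ligand.atoms[i].element for i in keep]
    return pose_rmsd(np.asarray(pose_coords)[keep], np.asarray(reference_coords)[keep],
                     matching_mode=matching_mode, elements=els)


def total_rmsd(per_pair_per_pose) -> float:
    """Fitting objective: mean over all N·M pair/pose RMSD entries (equal to
    the mean of per-pair means when every pair has the same pose count)."""
    m = np.asarray(per_pair_per_pose, dtype=float)
    if m.size == 0:
        raise ValueError("empty RMSD matrix")
    return float(m.mean())


def resolution_report(per_metal_rmsd_avg: dict[str, float],
                      per_metal_resolution_avg: dict[str, float]) -> dict[str, float]:
    """Difference between the mean docking RMSD and the mean crystallographic
    resolution per metal, rounded to 3 decimals. The resolution is the
    inherent uncertainty of the experimental coordinates, so a difference
    near zero means the docking error is within the experimental error."""
    if set(per_metal_rmsd_avg) != set(per_metal_resolution_avg):
        missing = set(per_metal_rmsd_avg) ^ set(per_metal_resolution_avg)
        raise KeyError(f"metal keys do not match: {sorted(missing)}")
    return {m: round(per_metal_rmsd_avg[m] - per_metal_resolution_avg[m], 3)
            for m in per_metal_rmsd_avg}


def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Least-squares superposition: returns (rotation R, translation t) with
    ``mobile @ R.T + t`` optimally aligned onto ``target``."""
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    t = ct - cm @ r.T
    return r, t
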