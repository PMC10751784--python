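"""Similarity metrics for train/test curation of complex-protein pairs.

Compounds are compared by the Tanimoto coefficient over hashed linear-path
fingerprints; proteins are compared by a TM-score over corresponding Cα (or
any representative) coordinates. The pair that in total differs most from
the rest of a data set is held out as the test sample, so the fitted
parameters are validated on the least redundant member.
"""
from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np

from .evaluation import kabsch
from .mol_model import Ligand

__all__ = ["Fingerprint", "TMScoreResult", "fingerprint", "tanimoto",
           "tm_score", "tm_d0", "align_sequences", "select_test_pair"]

FINGERPRINT_BITS = 2048
MAX_PATH_LENGTH = 7
MIN_TM_RESIDUES = 20


@dataclass
class Fingerprint:
    bits: np.ndarray  # boolean vector

    @property
    def n_bits(self) -> int:
        return int(self.bits.size)

    @property
    def count(self) -> int:
        return int(self.bits.sum())


def _path_strings(ligand: Ligand) -> set[str]:
    """Canonical element/bond-order strings for all simple paths of 1..7 atoms.

    A path and its reverse hash identically (the lexicographically smaller
    rendering is kept), which makes the fingerprint independent of atom
    numbering.
    """
    order_of = {}
    adj: dict[int, list[int]] = {a.index: [] for a in ligand.atoms}
    for a, b, o in ligand.bonds:
        adj[a].append(b)
        adj[b].append(a)
        order_of[frozenset((a, b))] = o
    el = {a.index: a.element for a in ligand.atoms}
    out: set[str] = set()

    def extend(path: list[int]) -> None:
        tokens = []
        for k, i in enumerate(path):
            if k:
                tokens.append(f"{order_of[frozenset((path[k - 1], i))]:g}")
            tokens.append(el[i])
        s = "-".join(tokens)
        rev = "-".join(reversed(tokens))
        out.add(min(s, rev))
        if len(path) >= MAX_PATH_LENGTH:
            return
        for j in adj[path[-1]]:
            if j not in path:
                extend(path + [j])

    for a in ligand.atoms:
        if not a.is_dummy:
            extend([a.index])
    return out


def fingerprint(ligand: Ligand, n_bits: int = FINGERPRINT_BITS) -> Fingerprint:
    """Hashed linear-path fingerprint folded to ``n_bits`` bits; deterministic
    and invariant to atom order. A single atom still sets at least one bit."""
    bits = np.zeros(n_bits, dtype=bool)
    for s in _path_strings(ligand):
        h = int.from_bytes(hashlib.sha1(s.encode()).digest()[:8], "big")
        bits[h % n_bits] = True
    return Fingerprint(bits=bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|A∩B| / (|A| + |B| - |A∩B|), in [0, 1]; two empty prints give 0."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")
    inter = int((a.bits & b.bits).sum())
    union = a.count + b.count - inter
    if union == 0:
        warnings.warn("both fingerprints are empty; Tanimoto defined as 0",
                      stacklevel=2)
        return 0.0
    return inter / union


# ---------------------------------------------------------------------------
# TM-score
# ---------------------------------------------------------------------------

@dataclass
class TMScoreResult:
    score: float
    aligned_length: int
    d0: float
    distances: np.ndarray  # per-residue, after the best superposition


def tm_d0(length: int) -> float:
    """Length-dependent distance scale, floored at 0.5 Å."""
    if length <= 15:
        return 0.5
    return max(0.5, 1.24 * (length - 15) ** (1.0 / 3.0) - 1.8)


def _tm_from_superposition(mob, tgt, sub, d0):
    r, t = kabsch(mob[sub], tgt[sub])
    moved = mob @ r.T + t
    d = np.linalg.norm(moved - tgt, axis=1)
    return float(np.mean(1.0 / (1.0 + (d / d0) ** 2))), d


def tm_score(coords_a: np.ndarray, coords_b: np.ndarray,
             correspondence: list[tuple[int, int]] | None = None) -> TMScoreResult:
    """TM-score of structure ``a`` against reference ``b``.

    ``correspondence`` maps residue indices of ``a`` onto ``b`` (identical
    lengths are paired positionally when omitted; use
    :func:`align_sequences` to build one from sequences). The score is
    (1/L) Σ 1/(1+(d_i/d0)²) over the reference length L, maximized by
    iterative Kabsch superposition seeded from full-length and fragment
    alignments, with the inclusion set refined until it is stable.
    """
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    if correspondence is None:
        if len(a) != len(b):
            raise ValueError("equal lengths required when no correspondence is given")
        correspondence = list(zip(range(len(a)), range(len(b))))
    if len(correspondence) < MIN_TM_RESIDUES:
        raise ValueError(f"at least {MIN_TM_RESIDUES} matched residues required, "
                         f"got {len(correspondence)}")
    ia = [i for i, _ in correspondence]
    ib = [j for _, j in correspondence]
    mob, tgt = a[ia], b[ib]
    L = len(b)  # normalized by the reference length
    n = len(mob)
    d0 = tm_d0(L)
    best_score, best_d = -1.0, None
    seeds = [np.arange(n)]
    for frac in (2, 4):
        flen = max(MIN_TM_RESIDUES // 2, n // frac)
        for start in range(0, n - flen + 1, max(1, flen // 2)):
            seeds.append(np.arange(start, start + flen))
    for sub in seeds:
        score, d = _tm_from_superposition(mob, tgt, sub, d0)
        # refine: keep residues closer than a shrinking cut, re-superpose
        for cut in (d0 * 2, d0, d0 / 2):
            keep = np.where(d < max(cut, 0.5))[0]
            if len(keep) < 3:
                break
            score2, d2 = _tm_from_superposition(mob, tgt, keep, d0)
            if score2 > score:
                score, d = score2, d2
        if score > best_score:
            best_score, best_d = score, d
    # reference length normalization: unmatched reference residues count 0
    final = best_score * n / L
    return TMScoreResult(score=min(final, 1.0), aligned_length=n, d0=d0,
                         distances=best_d)


def align_sequences(seq_a: str, seq_b: str) -> list[tuple[int, int]]:
    """Global alignment (BLOSUM62, affine gaps) giving a residue
    correspondence between two one-letter sequences."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seq_a, seq_b)[0]
    pairs: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    return pairs


def select_test_pair(tanimoto_matrix: np.ndarray, tm_matrix: np.ndarray,
                     ids: list[str] | None = None):
    """Index (or id) of the entry least similar to the rest of the set:
    minimizes the mean of (mean off-diagonal Tanimoto, mean off-diagonal
    TM-score); ties break to the lowest index."""
    t = np.asarray(tanimoto_matrix, float)
    s = np.asarray(tm_matrix, float)
    if t.shape != s.shape or t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    n = t.shape[0]
    if n < 2:
        raise ValueError("need at least two entries to select a test pair")
    combined = np.empty(n)
    for i in range(n):
        others = [j for j in range(n) if j != i]
        combined[i] = 0.5 * (t[i, others].mean() + s[i, others].mean())
    best = int(np.argmin(combined))
    return ids[best] if ids is not None else best
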