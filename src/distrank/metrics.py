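"""Structure superposition and similarity scores.

Implements the least-squares (Kabsch) superposition primitive and, on top of
it, the two pool-ranking currencies of model quality assessment:

* **GDT-TS** — mean over the 1/2/4/8 A cutoffs of the maximal fraction of
  corresponding Ca atoms that can be brought within the cutoff by a rigid
  superposition.
* **TM-score** — length-normalised superposition score
  ``max (1/L_ref) sum 1/(1+(d_i/d0)^2)`` with
  ``d0 = 1.24 (L_ref-15)^(1/3) - 1.8`` floored at 0.5 A.

Both scores search superpositions heuristically: seed fits from contiguous
fragments (lengths 4, 8, 16 and the full chain, stride 4), each refined by
iterating superpose -> keep residues within the cutoff -> re-superpose.  For
chains of up to :data:`EXHAUSTIVE_MAX` corresponding residues the seeds are
*all* residue subsets of size >= 3, which makes the per-cutoff maxima exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .structio import Structure

__all__ = [
    "Superposition",
    "SimilarityScore",
    "kabsch",
    "superpose",
    "rmsd",
    "gdt_ts",
    "tm_score",
    "tm_d0",
    "pairwise_matrix",
    "EXHAUSTIVE_MAX",
]

GDT_CUTOFFS = (1.0, 2.0, 4.0, 8.0)
#: chains with at most this many corresponding residues get the exact
#: all-subsets superposition search instead of fragment seeding
EXHAUSTIVE_MAX = 12


@dataclass
class Superposition:
    """Optimal rigid transform mapping coordinates *a* onto *b*.

    ``apply(x)`` returns ``x @ rotation.T + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, x: np.ndarray) -> np.ndarray:
        return x @ self.rotation.T + self.translation


@dataclass
class SimilarityScore:
    gdt_ts: float
    tm_score: float
    rmsd: float


def kabsch(a: np.ndarray, b: np.ndarray) -> Superposition:
    """Least-squares superposition of point set *a* onto *b*.

    Returns the proper rotation (reflections corrected) and translation
    minimising the RMSD of ``a`` mapped onto ``b``.  Requires N >= 3
    non-collinear points.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("inputs must be matching N x 3 arrays")
    n = a.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 points")
    ac = a.mean(axis=0)
    bc = b.mean(axis=0)
    h = (a - ac).T @ (b - bc)
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 1e-10 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    moved = (a - ac) @ rot.T + bc
    val = float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=bc - rot @ ac, rmsd=val)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD after optimal superposition of *a* onto *b*."""
    return kabsch(a, b).rmsd


def _correspondence(model: Structure, reference: Structure):
    """Index arrays of the residue_index intersection, model-side then ref-side."""
    common, ia, ib = np.intersect1d(
        model.residue_index, reference.residue_index, return_indices=True)
    if len(common) < 3:
        raise ValueError("fewer than 3 corresponding residues")
    return model.ca_coords[ia], reference.ca_coords[ib]


def _fit(a, b, sel):
    """Kabsch on the selected subset; None if degenerate."""
    try:
        return kabsch(a[sel], b[sel])
    except ValueError:
        return None


def _seed_selections(n: int) -> list[np.ndarray]:
    """All residue subsets of size >= 3 (the exact small-chain search space);
    the fragment-seeded heuristic for larger chains lives in ``_search``."""
    idx = np.arange(n)
    return [np.array(c) for k in range(3, n + 1)
            for c in combinations(idx, k)]


def gdt_ts(model: Structure, reference: Structure) -> float:
    """Global distance test total score of *model* against *reference*.

    Residues correspond via their 1-based residue numbers; the fraction
    denominator is the number of corresponding residues.
    """
    a, b = _correspondence(model, reference)
    n = a.shape[0]
    if n > EXHAUSTIVE_MAX:
        from ._search import gdt_fractions

        fr = gdt_fractions(np.ascontiguousarray(a), np.ascontiguousarray(b),
                           np.array(GDT_CUTOFFS))
        return float(np.mean(fr))
    # exhaustive path: every extension re-fit is itself a subset fit, so
    # enumerating all subsets of size >= 3 already attains the maxima
    best = {c: 0.0 for c in GDT_CUTOFFS}
    for sel in _seed_selections(n):
        sp = _fit(a, b, sel)
        if sp is None:
            continue
        d = np.linalg.norm(sp.apply(a) - b, axis=1)
        for cut in GDT_CUTOFFS:
            frac = np.mean(d <= cut)
            if frac > best[cut]:
                best[cut] = frac
    return float(np.mean([best[c] for c in GDT_CUTOFFS]))


def tm_d0(l_ref: int) -> float:
    """TM-score normalisation distance d0, floored at 0.5 A."""
    if l_ref > 15:
        return max(1.24 * (l_ref - 15) ** (1.0 / 3.0) - 1.8, 0.5)
    return 0.5


def _tm_search(a: np.ndarray, b: np.ndarray, l_ref: int):
    """Seed-and-extend search maximising the TM objective of *a* onto *b*."""
    d0 = tm_d0(l_ref)
    n = a.shape[0]
    if n > EXHAUSTIVE_MAX:
        from ._search import tm_search as _tm_core

        best, rot, trans = _tm_core(
            np.ascontiguousarray(a), np.ascontiguousarray(b), l_ref, d0)
        moved = a @ rot.T + trans
        val = float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))
        return best, Superposition(rotation=rot, translation=trans, rmsd=val)

    def score(d):
        return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_ref)

    # exhaustive path (see gdt_ts): all subsets of size >= 3 as seeds
    best, best_sp = -1.0, None
    for sel in _seed_selections(n):
        sp = _fit(a, b, sel)
        if sp is None:
            continue
        d = np.linalg.norm(sp.apply(a) - b, axis=1)
        if score(d) > best:
            best, best_sp = score(d), sp
    return best, best_sp


def tm_score(model: Structure, reference: Structure) -> float:
    """TM-score of *model* against *reference* (normalised by reference length)."""
    a, b = _correspondence(model, reference)
    best, _ = _tm_search(a, b, len(reference))
    return best


def tm_superpose(model: Structure, reference: Structure) -> Superposition:
    """The superposition attaining the best TM objective found by the search."""
    a, b = _correspondence(model, reference)
    _, sp = _tm_search(a, b, len(reference))
    if sp is None:
        raise ValueError("no valid superposition found")
    return sp


def similarity(model: Structure, reference: Structure) -> SimilarityScore:
    a, b = _correspondence(model, reference)
    return SimilarityScore(
        gdt_ts=gdt_ts(model, reference),
        tm_score=tm_score(model, reference),
        rmsd=kabsch(a, b).rmsd,
    )


def superpose(model: Structure, reference: Structure) -> Superposition:
    """Kabsch superposition over the corresponding Ca atoms."""
    a, b = _correspondence(model, reference)
    return kabsch(a, b)


def pairwise_matrix(structures: list[Structure], metric: str = "gdt_ts") -> np.ndarray:
    """Symmetric matrix of pairwise similarity scores with unit diagonal.

    ``metric`` is 'gdt_ts' or 'tm_score'.  Each pair is scored once and
    mirrored (the scores are symmetric up to the search heuristic's
    tolerance).
    """
    if len(structures) < 2:
        raise ValueError("need at least 2 structures")
    fn = {"gdt_ts": gdt_ts, "tm_score": tm_score}.get(metric)
    if fn is None:
        raise ValueError(f"unknown metric {metric!r}")
    k = len(structures)
    mat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            mat[i, j] = mat[j, i] = fn(structures[i], structures[j])
    return mat
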