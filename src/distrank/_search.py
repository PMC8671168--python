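"""Numba-compiled inner loops of the superposition search.

The GDT/TM searches evaluate hundreds of Kabsch fits per structure pair
(fragment seeds times iterative extension rounds); pairwise consensus
scoring of a 30-model pool multiplies that by ~400 pairs per target, so the
inner loop is JIT-compiled.  The algorithms are identical to the pure-Python
exhaustive path in :mod:`distrank.metrics`, which doubles as their oracle in
the tests.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MAX_ROUNDS = 10
_STRIDE = 4


@njit(cache=True)
def _rot_trans(a: np.ndarray, b: np.ndarray):
    """Proper rotation/translation of the Kabsch fit of a onto b.

    Returns (ok, rot, trans); ok is False for degenerate (collinear) sets.
    """
    n = a.shape[0]
    am = np.zeros(3)
    bm = np.zeros(3)
    for k in range(n):
        am += a[k]
        bm += b[k]
    am /= n
    bm /= n
    h = np.zeros((3, 3))
    for k in range(n):
        da = a[k] - am
        db = b[k] - bm
        for i in range(3):
            for j in range(3):
                h[i, j] += da[i] * db[j]
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 1e-10 * max(s[0], 1.0):
        return False, np.eye(3), np.zeros(3)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    f = np.eye(3)
    f[2, 2] = d
    rot = vt.T @ f @ u.T
    trans = bm - rot @ am
    return True, rot, trans


@njit(cache=True)
def _sqdist(a, b, rot, trans):
    n = a.shape[0]
    d2 = np.empty(n)
    for k in range(n):
        x = rot @ a[k] + trans
        d2[k] = ((x[0] - b[k, 0]) ** 2 + (x[1] - b[k, 1]) ** 2
                 + (x[2] - b[k, 2]) ** 2)
    return d2


@njit(cache=True)
def _seed_starts(n):
    """(start, length) pairs of the fragment seeds: lengths 4/8/16/n, stride 4."""
    lengths = np.array([4, 8, 16, n])
    count = 0
    for li in range(4):
        f = lengths[li]
        if f > n or (li < 3 and f == n):
            continue
        count += (n - f) // _STRIDE + 1
    out = np.empty((count, 2), dtype=np.int64)
    w = 0
    for li in range(4):
        f = lengths[li]
        if f > n or (li < 3 and f == n):
            continue
        for start in range(0, n - f + 1, _STRIDE):
            out[w, 0] = start
            out[w, 1] = f
            w += 1
    return out


@njit(cache=True)
def gdt_fractions(a: np.ndarray, b: np.ndarray, cutoffs: np.ndarray) -> np.ndarray:
    """Per-cutoff maximal superposable fraction (fragment-seeded search)."""
    n = a.shape[0]
    ncut = cutoffs.shape[0]
    best = np.zeros(ncut)
    seeds = _seed_starts(n)
    for si in range(seeds.shape[0]):
        start, f = seeds[si, 0], seeds[si, 1]
        ok, rot, trans = _rot_trans(a[start:start + f], b[start:start + f])
        if not ok:
            continue
        d2_seed = _sqdist(a, b, rot, trans)
        for ci in range(ncut):
            c2 = cutoffs[ci] * cutoffs[ci]
            d2 = d2_seed
            frac = np.mean(d2 <= c2)
            if frac > best[ci]:
                best[ci] = frac
            prev = np.zeros(n, dtype=np.bool_)
            have_prev = False
            for _ in range(_MAX_ROUNDS):
                inside = d2 <= c2
                m = 0
                same = have_prev
                for k in range(n):
                    if inside[k]:
                        m += 1
                    if have_prev and inside[k] != prev[k]:
                        same = False
                if m < 3 or same:
                    break
                prev = inside.copy()
                have_prev = True
                ok2, rot2, trans2 = _rot_trans(a[inside], b[inside])
                if not ok2:
                    break
                d2 = _sqdist(a, b, rot2, trans2)
                frac = np.mean(d2 <= c2)
                if frac > best[ci]:
                    best[ci] = frac
    return best


@njit(cache=True)
def tm_search(a: np.ndarray, b: np.ndarray, l_ref: int, d0: float):
    """Best TM objective over the fragment-seeded search.

    Returns (score, rot, trans) of the best superposition found.
    """
    n = a.shape[0]
    sel_cut = d0 if d0 > 4.5 else 4.5
    sel_cut2 = sel_cut * sel_cut
    d02 = d0 * d0
    best = -1.0
    best_rot = np.eye(3)
    best_trans = np.zeros(3)
    seeds = _seed_starts(n)
    for si in range(seeds.shape[0]):
        start, f = seeds[si, 0], seeds[si, 1]
        ok, rot, trans = _rot_trans(a[start:start + f], b[start:start + f])
        if not ok:
            continue
        d2 = _sqdist(a, b, rot, trans)
        sc = 0.0
        for k in range(n):
            sc += 1.0 / (1.0 + d2[k] / d02)
        sc /= l_ref
        if sc > best:
            best = sc
            best_rot = rot.copy()
            best_trans = trans.copy()
        prev = np.zeros(n, dtype=np.bool_)
        have_prev = False
        for _ in range(_MAX_ROUNDS):
            inside = d2 <= sel_cut2
            m = 0
            same = have_prev
            for k in range(n):
                if inside[k]:
                    m += 1
                if have_prev and inside[k] != prev[k]:
                    same = False
            if m < 3 or same:
                break
            prev = inside.copy()
            have_prev = True
            ok2, rot, trans = _rot_trans(a[inside], b[inside])
            if not ok2:
                break
            d2 = _sqdist(a, b, rot, trans)
            sc = 0.0
            for k in range(n):
                sc += 1.0 / (1.0 + d2[k] / d02)
            sc /= l_ref
            if sc > best:
                best = sc
                best_rot = rot.copy()
                best_trans = trans.copy()
    return best, best_rot, best_trans
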