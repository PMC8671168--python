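"""Deterministic synthetic fixtures for every pipeline stage.

Real benchmarks for model quality assessment (native structures, server
model pools, predicted distance maps, deep alignments) are large external
downloads.  This module fabricates small, seeded stand-ins with the
statistical features the pipeline cares about:

* ``make_native`` — a self-avoiding Ca trace with 3.8 A virtual bonds and
  mixed helical/extended segments;
* ``make_decoys`` — a model pool around a native, perturbed by *correlated*
  (chain-smoothed) Gaussian noise at several amplitudes, with a skew knob
  controlling how many decoys get the largest noise (the hard-target regime
  where few good models exist);
* ``make_predicted_map`` / ``make_predicted_contacts`` — noisy versions of
  the native distance map standing in for a learned distance predictor;
* ``make_aux_scores`` — noisy observations of true quality standing in for
  external single-model QA columns;
* ``make_msa`` and ``make_hit_table`` — alignment fixtures for the Neff /
  coverage statistics and the domain parser.

Everything is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from . import metrics
from .domains import AlignmentHit, DomainSegment
from .evaluate import MSA
from .ranking import ModelPool
from .structio import ContactSet, DistanceMap, Structure, distance_map

__all__ = [
    "DecoySpec",
    "make_native",
    "make_decoys",
    "make_predicted_map",
    "make_predicted_contacts",
    "make_aux_scores",
    "make_msa",
    "make_hit_table",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
CA_BOND = 3.8
#: chain-smoothing length (residues) of the decoy noise; low-frequency
#: perturbations spread GDT-TS realistically instead of collapsing it
NOISE_SMOOTHING = 3.0

# helix: radius/rise/turn chosen so consecutive Ca are exactly CA_BOND apart
_HELIX_TURN = np.deg2rad(100.0)
_HELIX_RISE = 1.5
_HELIX_RADIUS = np.sqrt(CA_BOND**2 - _HELIX_RISE**2) / (2 * np.sin(_HELIX_TURN / 2))
# extended strand: planar zigzag with the same bond length
_STRAND_OFFSET = 1.0
_STRAND_STEP = np.sqrt(CA_BOND**2 - (2 * _STRAND_OFFSET) ** 2)


@dataclass
class DecoySpec:
    """Conditions of a synthetic decoy pool.

    ``mode_share`` controls how much of each decoy's displacement is a
    *shared* per-noise-level deformation (a conformational basin) versus
    individual noise.  Real pools are multi-modal: bad models concentrate
    around a few wrong conformations, which is exactly what misleads
    clustering-consensus ranking on hard targets.  ``mode_share = 0`` gives
    independent perturbations symmetric about the native.
    """

    # the default ladder spans near-perfect (GDT-TS ~ 0.97) to wrong-topology
    # (~ 0.4) models with roughly even quality spacing, so a skew-0 pool has
    # an approximately symmetric quality distribution
    n_decoys: int = 30
    noise_levels: tuple[float, ...] = (0.8, 2.0, 3.5, 5.5, 8.0)
    skew: float = 0.0
    mode_share: float = 0.85
    seed: int = 0
    groups: tuple[str, ...] = ("gA", "gB", "gC", "gD", "gE")

    def __post_init__(self) -> None:
        if self.n_decoys < 2:
            raise ValueError("need at least 2 decoys")
        if any(s <= 0 for s in self.noise_levels):
            raise ValueError("noise levels must be positive")
        if self.skew < 0:
            raise ValueError("skew must be >= 0")
        if not 0.0 <= self.mode_share < 1.0:
            raise ValueError("mode_share must lie in [0, 1)")


def _helix_points(n: int) -> np.ndarray:
    t = np.arange(n)
    return np.column_stack([
        _HELIX_RADIUS * np.cos(_HELIX_TURN * t),
        _HELIX_RADIUS * np.sin(_HELIX_TURN * t),
        _HELIX_RISE * t,
    ])


def _strand_points(n: int) -> np.ndarray:
    t = np.arange(n)
    return np.column_stack([
        _STRAND_STEP * t,
        _STRAND_OFFSET * (-1.0) ** t,
        np.zeros(n),
    ])


def _orient_segment(template: np.ndarray, aim: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Rotate a segment so its end-to-end axis points along *aim*,
    with a random roll about that axis."""
    e = template[-1] - template[0]
    ne = np.linalg.norm(e)
    na = np.linalg.norm(aim)
    if ne < 1e-9 or na < 1e-9:
        return template @ Rotation.random(random_state=rng).as_matrix().T
    align, _ = Rotation.align_vectors(aim[None] / na, e[None] / ne)
    roll = Rotation.from_rotvec(rng.uniform(0, 2 * np.pi) * aim / na)
    return template @ (roll * align).as_matrix().T


def make_native(L: int, seed: int = 0) -> Structure:
    """Self-avoiding Ca trace of length *L* with helical and extended parts.

    Helix segments (6-14 residues) alternate with extended zigzag segments
    (4-8 residues); each segment is aimed back toward the body centroid and
    re-drawn if it comes closer than 3.5 A to the existing trace (with an
    outward fallback so construction always terminates), which folds the
    chain into a compact globule.  Every virtual Ca-Ca bond is exactly
    3.8 A.  Cb positions are placed 1.53 A off the local chain axis (Ca
    reused for glycine).
    """
    if L < 10:
        raise ValueError("native length must be >= 10")
    rng = np.random.default_rng(seed)
    coords: list[np.ndarray] = []
    helical = bool(rng.integers(2))
    while len(coords) < L:
        lo, hi = (6, 15) if helical else (4, 9)
        n_seg = min(int(rng.integers(lo, hi)), L - len(coords))
        template = _helix_points(n_seg) if helical else _strand_points(n_seg)
        template = template - template[0]
        placed = None
        for attempt in range(80):
            if not coords:
                rot = Rotation.random(random_state=rng).as_matrix()
                placed = template @ rot.T
                break
            prev = np.array(coords)
            centroid = prev.mean(axis=0)
            if attempt < 60:
                u = rng.normal(size=3)
            else:  # fallback: grow away from the body, always placeable
                u = prev[-1] - centroid + 0.1 * rng.normal(size=3)
            u = u / np.linalg.norm(u)
            start = prev[-1] + CA_BOND * u
            # aim the segment's end-to-end axis toward the body so the trace
            # folds into a globule with genuine long-range contacts
            if attempt < 60:
                aim = centroid - start + rng.normal(scale=6.0, size=3)
            else:
                aim = start - centroid + rng.normal(scale=6.0, size=3)
            pts = _orient_segment(template, aim, rng)
            cand = pts + start
            # self-avoidance: new points vs all previous non-adjacent ones
            dmin = cdist(cand, prev).min()
            if dmin > 3.5 or (attempt >= 60 and dmin > 2.5):
                placed = cand
                break
        if placed is None:  # extremely unlikely; accept the last candidate
            placed = cand
        coords.extend(list(placed))
        helical = not helical
    ca = np.array(coords[:L])

    seq = "".join(rng.choice(list(AMINO_ACIDS), size=L))
    cb = ca.copy()
    for k in range(L):
        if seq[k] == "G":
            continue
        lo, hi = max(k - 1, 0), min(k + 1, L - 1)
        axis = ca[k] - 0.5 * (ca[lo] + ca[hi])
        nrm = np.linalg.norm(axis)
        if nrm < 1e-9:
            axis, nrm = np.array([0.0, 0.0, 1.0]), 1.0
        cb[k] = ca[k] + 1.53 * axis / nrm
    return Structure(
        target_id=f"synth{seed}",
        sequence=seq,
        residue_index=np.arange(1, L + 1),
        ca_coords=ca,
        cb_coords=cb,
    )


def _level_counts(spec: DecoySpec) -> list[int]:
    """How many decoys receive each noise level.

    With ``skew == 0`` the levels are weighted equally; a positive skew
    weights level k (ascending noise) by ``exp(skew * k)``, concentrating
    the pool at the largest noise so only a thin tail of good models
    remains.
    """
    k = len(spec.noise_levels)
    w = np.exp(spec.skew * np.arange(k))
    w = w / w.sum()
    counts = np.floor(w * spec.n_decoys).astype(int)
    # largest-remainder rounding
    rem = w * spec.n_decoys - counts
    for i in np.argsort(-rem)[: spec.n_decoys - counts.sum()]:
        counts[i] += 1
    return list(counts)


def _correlated_field(L: int, rng: np.random.Generator) -> np.ndarray:
    """Chain-smoothed unit-RMS displacement field for a length-L trace."""
    sm = gaussian_filter1d(rng.normal(size=(L, 3)), sigma=NOISE_SMOOTHING,
                           axis=0)
    return sm / np.sqrt(np.mean(np.sum(sm**2, axis=1)))


def make_decoys(native: Structure, spec: DecoySpec) -> ModelPool:
    """Decoy pool around *native* with per-decoy true GDT-TS stored.

    Each decoy's Ca displacement has per-atom RMS equal to its assigned
    noise level and splits into a per-level shared basin deformation
    (weight ``mode_share``) plus individual chain-correlated noise; the
    decoy is then moved by a random rigid transform.
    """
    rng = np.random.default_rng(spec.seed)
    levels = np.array([
        lvl for lvl, c in zip(spec.noise_levels, _level_counts(spec))
        for _ in range(c)])
    rng.shuffle(levels)
    L = len(native)
    rho = spec.mode_share
    modes = {lvl: _correlated_field(L, rng) for lvl in spec.noise_levels}
    ids, models, true_scores, groups = [], [], {}, []
    for d, sigma in enumerate(levels):
        own = _correlated_field(L, rng)
        noise = sigma * (rho * modes[sigma] + np.sqrt(1 - rho**2) * own)
        ca = native.ca_coords + noise
        rot = Rotation.random(random_state=rng).as_matrix()
        ca = ca @ rot.T + rng.normal(scale=20.0, size=3)
        model_id = f"m{d:03d}"
        s = Structure(
            target_id=native.target_id,
            sequence=native.sequence,
            residue_index=native.residue_index.copy(),
            ca_coords=ca,
        )
        ids.append(model_id)
        models.append(s)
        groups.append(spec.groups[d % len(spec.groups)])
        true_scores[model_id] = metrics.gdt_ts(s, native)
    return ModelPool(
        target_id=native.target_id,
        model_ids=ids,
        models=models,
        groups=groups,
        true_scores=true_scores,
    )


def make_predicted_map(native: Structure, noise_sd: float, seed: int = 0,
                       scheme: str = "ca") -> DistanceMap:
    """Noisy native distance map standing in for a learned distance predictor.

    Zero-mean noise of overall RMS *noise_sd* is added symmetrically to the
    native map; distances are clipped at 0 and the diagonal restored.  The
    noise mixes a spatially smooth component (70% of the variance) with an
    independent per-cell component: learned distance predictors err in
    whole regions (badly aligned segments, missed inter-domain contacts),
    not cell by cell, and the smooth component reproduces that structure.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    base = distance_map(native, scheme).values
    rng = np.random.default_rng(seed)
    L = base.shape[0]
    if noise_sd == 0:
        return DistanceMap(base)
    from scipy.ndimage import gaussian_filter

    smooth = gaussian_filter(rng.normal(size=(L, L)), sigma=4.0)
    smooth = smooth / np.sqrt(np.mean(smooth**2))
    rough = rng.normal(size=(L, L))
    noise = noise_sd * (np.sqrt(0.7) * smooth + np.sqrt(0.3) * rough)
    noise = (noise + noise.T) / np.sqrt(2.0)
    values = np.clip(base + noise, 0.0, None)
    np.fill_diagonal(values, 0.0)
    return DistanceMap(values)


def make_predicted_contacts(predicted: DistanceMap,
                            candidate_cut: float = 8.0) -> ContactSet:
    """Scored contact predictions derived from a predicted distance map.

    Every pair with predicted distance at most *candidate_cut* (the contact
    threshold) becomes a predicted contact whose score decreases
    monotonically with predicted distance, so top-k selection favours the
    closest predicted pairs.
    """
    v = predicted.values
    iu, ju = np.triu_indices(predicted.size, k=1)
    keep = v[iu, ju] <= candidate_cut
    pairs = [
        (int(i) + 1, int(j) + 1, float(1.0 / (1.0 + d / 8.0)))
        for i, j, d in zip(iu[keep], ju[keep], v[iu, ju][keep])]
    return ContactSet(pairs=pairs, separation_class="any")


def make_aux_scores(pool: ModelPool, noise_sd: float = 0.07, seed: int = 0,
                    n_columns: int = 2) -> pd.DataFrame:
    """Noisy observations of true quality emulating external QA columns.

    Each auxiliary column is the pool's true GDT-TS plus independent
    Gaussian noise of SD *noise_sd*, clipped to [0, 1] — the realism level
    of a decent external single-model scorer.
    """
    if pool.true_scores is None:
        raise ValueError("pool has no true scores")
    rng = np.random.default_rng(seed)
    truth = np.array([pool.true_scores[m] for m in pool.model_ids])
    data = {}
    for c in range(n_columns):
        data[f"aux{c + 1}"] = np.clip(
            truth + rng.normal(scale=noise_sd, size=len(truth)), 0.0, 1.0)
    return pd.DataFrame(data, index=pd.Index(pool.model_ids, name="model_id"))


def make_msa(query_length: int, n_rows: int, mutation_rate: float,
             coverage_blocks: list[tuple[int, int]] | None = None,
             seed: int = 0) -> MSA:
    """Synthetic alignment: mutated, block-covered copies of a random query.

    Each non-query row covers one block drawn from *coverage_blocks*
    (1-based inclusive; full coverage when None) with gaps elsewhere, and
    carries per-column substitutions at *mutation_rate* inside its block.
    """
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    query = "".join(rng.choice(list(AMINO_ACIDS), size=query_length))
    rows = [query]
    for _ in range(n_rows - 1):
        chars = np.array(list(query))
        mutate = rng.random(query_length) < mutation_rate
        if mutate.any():
            chars[mutate] = rng.choice(list(AMINO_ACIDS), size=mutate.sum())
        if coverage_blocks:
            a, b = coverage_blocks[rng.integers(len(coverage_blocks))]
            mask = np.ones(query_length, dtype=bool)
            mask[a - 1: b] = False
            chars[mask] = "-"
        rows.append("".join(chars))
    return MSA(rows=rows)


def make_hit_table(L: int, segments: list[DomainSegment],
                   seed: int = 0) -> list[AlignmentHit]:
    """Hit table whose filtered union reproduces the planned TBM cover.

    *segments* must tile [1, L]; planned TBM segments must be longer than
    40 residues (shorter ones could not survive the aligned-length filter).
    Decoy hits violating each filtering rule — an insignificant E-value, an
    aligned length of exactly 40 and a low coverage — are added over FM
    regions so that a missing filter corrupts the segmentation visibly.
    """
    pos = 1
    for s in sorted(segments, key=lambda x: x.start):
        if s.start != pos:
            raise ValueError("segments must tile [1, L] without gaps")
        pos = s.end + 1
    if pos != L + 1:
        raise ValueError("segments must end at L")
    rng = np.random.default_rng(seed)
    hits = []
    for s in segments:
        if s.klass != "TBM":
            continue
        if s.length <= 40:
            raise ValueError("planned TBM segments must be > 40 residues")
        hits.append(AlignmentHit(
            template_id=f"t{rng.integers(1000, 9999)}",
            e_value=float(10.0 ** rng.uniform(-50, -5)),
            target_start=s.start,
            target_end=s.end,
            coverage=0.9,
            identity=float(rng.uniform(0.3, 0.9)),
        ))
        if s.length > 90:  # a redundant sub-hit inside the covered region
            mid = s.start + s.length // 2
            hits.append(AlignmentHit(
                template_id=f"t{rng.integers(1000, 9999)}",
                e_value=float(10.0 ** rng.uniform(-30, -5)),
                target_start=s.start + 5,
                target_end=min(mid + 20, s.end),
                coverage=0.9,
                identity=float(rng.uniform(0.3, 0.9)),
            ))
    fm = [s for s in segments if s.klass == "FM"]
    decoy_span = (fm[0].start, fm[0].end) if fm else (1, min(L, 120))
    a, b = decoy_span
    hits.append(AlignmentHit("bad_evalue", 2.0, a, b, 0.9, 0.4))
    hits.append(AlignmentHit("bad_length", 1e-10, a, min(a + 39, L), 0.9, 0.4))
    hits.append(AlignmentHit("bad_coverage", 1e-10, a, b, 0.3, 0.4))
    rng.shuffle(hits)
    return hits
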