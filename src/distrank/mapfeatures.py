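"""Distance-map and contact matching features.

Model quality features computed by comparing a *predicted* inter-residue
distance map (or predicted contact set) against the map *observed* in a
candidate 3D model.  Distance maps are rendered to [0, 1] images (distances
capped at 16 A) so that image-similarity metrics apply: SSIM, PSNR, a
GIST-style orientation-histogram descriptor, a 64-bit DCT perceptual hash
and ORB keypoint matching, alongside RMSE, Pearson correlation and
contact-cell recall/precision computed on the raw maps.

Contact matching scores are the precision of the top L/2 predicted contacts
per sequence-separation class (short/medium/long) against the contacts
realised in the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
from scipy.fft import dctn
from scipy.stats import pearsonr
from skimage.feature import ORB, match_descriptors
from skimage.metrics import peak_signal_noise_ratio, structural_similarity
from skimage.transform import resize

from .structio import SEPARATION_CLASSES, ContactSet, DistanceMap, contacts_from_map

__all__ = [
    "DistFeatureRecord",
    "ContactMatchRecord",
    "normalize_map",
    "map_match_scores",
    "topk_contacts",
    "contact_match",
    "contact_match_record",
]

#: distances above this are visually saturated; contacts live below 8 A so a
#: 16 A cap keeps contrast in the near-contact range
DISTANCE_CAP = 16.0
PSNR_CAP = 100.0
CONTACT_THRESHOLD = 8.0
#: near-diagonal band ignored by cell-level precision/recall/Pearson
MIN_SEPARATION = 6


@dataclass
class DistFeatureRecord:
    """The nine distance-map matching scores for one model."""

    ssim: float
    psnr: float
    gist: float
    rmse: float
    recall: float
    precision: float
    phash: float
    pearson: float
    orb: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class ContactMatchRecord:
    """Per-separation-class contact matching precision for one model."""

    short_score: float
    medium_score: float
    long_score: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def normalize_map(m: DistanceMap, cap: float = DISTANCE_CAP) -> np.ndarray:
    """Render a distance map as an L x L image in [0, 1], distances capped."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    return np.minimum(m.values, cap) / cap


def _offdiag_mask(n: int, min_sep: int = 1) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=min_sep)


def _gist_descriptor(img: np.ndarray, grid: int = 4, bins: int = 8) -> np.ndarray:
    """Orientation-histogram grid descriptor (GIST-style stand-in).

    Gradient orientations are histogrammed (weighted by gradient magnitude)
    in a ``grid x grid`` spatial partition; the concatenated histograms form
    the descriptor.
    """
    gy, gx = np.gradient(img)
    mag = np.hypot(gx, gy)
    ang = np.mod(np.arctan2(gy, gx), np.pi)  # orientation, not direction
    n = img.shape[0]
    edges = np.linspace(0, n, grid + 1).astype(int)
    desc = []
    for a in range(grid):
        for b in range(grid):
            sl = (slice(edges[a], edges[a + 1]), slice(edges[b], edges[b + 1]))
            h, _ = np.histogram(
                ang[sl], bins=bins, range=(0, np.pi), weights=mag[sl])
            desc.append(h)
    return np.concatenate(desc)


def _cosine01(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 and nv == 0:
        return 1.0
    if nu == 0 or nv == 0:
        return 0.0
    return float(np.clip(np.dot(u, v) / (nu * nv), 0.0, 1.0))


def _phash_bits(img: np.ndarray) -> np.ndarray:
    """64-bit DCT perceptual hash: 32x32 resample, top-left 8x8 DCT block,
    median-thresholded (DC term excluded from the median)."""
    small = resize(img, (32, 32), anti_aliasing=True)
    coeffs = dctn(small, norm="ortho")[:8, :8].ravel()
    med = np.median(coeffs[1:])
    return coeffs > med


def _orb_score(img_a: np.ndarray, img_b: np.ndarray) -> float:
    """Fraction of matched ORB keypoint descriptors between the two images."""
    out = []
    for img in (img_a, img_b):
        scaled = resize(img, (256, 256), anti_aliasing=True)
        orb = ORB(n_keypoints=100, fast_threshold=0.05)
        try:
            orb.detect_and_extract(scaled)
            out.append(orb.descriptors)
        except (RuntimeError, ValueError):
            out.append(None)
    da, db = out
    if da is None or db is None or len(da) == 0 or len(db) == 0:
        return 0.0
    matches = match_descriptors(da, db, cross_check=True)
    return float(len(matches) / max(len(da), len(db)))


def map_match_scores(predicted: DistanceMap, observed: DistanceMap) -> DistFeatureRecord:
    """The nine map-matching scores of a model map against a predicted map."""
    if predicted.size != observed.size:
        raise ValueError(
            f"size mismatch: predicted {predicted.size}, observed {observed.size}")
    n = predicted.size
    img_p = normalize_map(predicted)
    img_o = normalize_map(observed)

    identical = np.array_equal(predicted.values, observed.values)
    ssim = 1.0 if identical else float(structural_similarity(
        img_p, img_o, win_size=min(7, n if n % 2 else n - 1), data_range=1.0))
    psnr = PSNR_CAP if identical else float(
        min(peak_signal_noise_ratio(img_p, img_o, data_range=1.0), PSNR_CAP))
    gist = _cosine01(_gist_descriptor(img_p), _gist_descriptor(img_o))

    iu, ju = _offdiag_mask(n, 1)
    rmse = float(np.sqrt(np.mean(
        (predicted.values[iu, ju] - observed.values[iu, ju]) ** 2)))

    # cell-level contact recall/precision and Pearson, near-diagonal excluded
    iu6, ju6 = _offdiag_mask(n, MIN_SEPARATION)
    p_cells = predicted.values[iu6, ju6] <= CONTACT_THRESHOLD
    o_cells = observed.values[iu6, ju6] <= CONTACT_THRESHOLD
    both = np.sum(p_cells & o_cells)
    precision = float(both / p_cells.sum()) if p_cells.any() else 1.0
    recall = float(both / o_cells.sum()) if o_cells.any() else 1.0

    pv, ov = predicted.values[iu6, ju6], observed.values[iu6, ju6]
    if identical:
        pearson = 1.0
    elif np.std(pv) == 0 or np.std(ov) == 0:
        pearson = 0.0
    else:
        pearson = float(pearsonr(pv, ov)[0])

    phash = 1.0 - float(
        np.count_nonzero(_phash_bits(img_p) != _phash_bits(img_o))) / 64.0
    orb = 1.0 if identical else _orb_score(img_p, img_o)

    return DistFeatureRecord(
        ssim=ssim, psnr=psnr, gist=gist, rmse=rmse, recall=recall,
        precision=precision, phash=phash, pearson=pearson, orb=orb)


def topk_contacts(predicted: ContactSet, k: int,
                  separation_class: str = "any") -> ContactSet:
    """The k highest-scoring predicted pairs within a separation class.

    Ties are broken by (i, j) lexicographic order.  If fewer than k pairs
    qualify, all of them are returned with a warning.
    """
    if separation_class not in SEPARATION_CLASSES:
        raise ValueError(f"unknown separation class {separation_class!r}")
    lo, hi = SEPARATION_CLASSES[separation_class]
    eligible = [
        (i, j, s) for i, j, s in predicted.pairs
        if (j - i) >= lo and (hi is None or (j - i) <= hi)]
    eligible.sort(key=lambda t: (-t[2], t[0], t[1]))
    if len(eligible) < k:
        warnings.warn(
            f"only {len(eligible)} contacts available for top-{k} selection")
    return ContactSet(pairs=eligible[:k], separation_class=separation_class)


def contact_match(predicted_topk: ContactSet, model_contacts: ContactSet) -> float:
    """Precision of the predicted contacts against the model's contacts."""
    if len(predicted_topk) == 0:
        warnings.warn("empty predicted contact set; precision reported as 0")
        return 0.0
    hits = predicted_topk.keys() & model_contacts.keys()
    return len(hits) / len(predicted_topk)


def contact_match_record(predicted: ContactSet, model_map: DistanceMap,
                         L: int, threshold: float = CONTACT_THRESHOLD,
                         topk_fraction: float = 0.5) -> ContactMatchRecord:
    """Short/medium/long contact matching scores for one model.

    Per class, the precision of the top L/2 predicted contacts of that class
    against the contacts realised in the model's distance map (<= 8 A).
    """
    k = int(L * topk_fraction)
    scores = {}
    for klass in ("short", "medium", "long"):
        top = topk_contacts(predicted, k, klass)
        observed = contacts_from_map(model_map, threshold, klass)
        if len(top) == 0:
            scores[klass] = 0.0
        else:
            scores[klass] = contact_match(top, observed)
    return ContactMatchRecord(
        short_score=scores["short"],
        medium_score=scores["medium"],
        long_score=scores["long"],
    )
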