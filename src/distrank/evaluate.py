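"""Evaluation statistics for model pools and alignments.

Covers the standard currencies used to judge quality-assessment methods:
per-target ranking loss (true quality of the best model minus that of the
selected model), per-model Z-scores and summed positive Z-scores, sample
skewness of the pool's quality distribution, the fraction of good models
(TM-score > 0.5), the effective sequence count (Neff) of an MSA at 62%
identity, per-column alignment coverage, and plain/log-x Pearson
correlations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "MSA",
    "EvalReport",
    "read_msa",
    "ranking_loss",
    "z_scores",
    "skewness",
    "neff",
    "good_fraction",
    "coverage_profile",
    "correlate",
    "evaluate_pool",
]

NEFF_IDENTITY = 0.62
GOOD_TM = 0.5


@dataclass
class MSA:
    """Aligned sequences, query first, uniform length, '-' for gaps."""

    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty alignment")
        w = len(self.rows[0])
        if any(len(r) != w for r in self.rows):
            raise ValueError("alignment rows must have uniform length")
        self.rows = [r.upper() for r in self.rows]

    @property
    def query(self) -> str:
        return self.rows[0]

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def __len__(self) -> int:
        return len(self.rows)


def read_msa(path: str | Path) -> MSA:
    """Read an aligned FASTA / A3M-like file (query first).

    Lowercase insert states are uppercased; '.' gaps become '-'.  All rows
    must end up the same length.
    """
    rows, cur = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if cur:
                    rows.append("".join(cur))
                    cur = []
            else:
                cur.append(line.replace(".", "-"))
    if cur:
        rows.append("".join(cur))
    return MSA(rows=rows)


@dataclass
class EvalReport:
    """Per-target evaluation summary."""

    target_id: str
    loss: float
    z: dict[str, float]
    sum_positive_z: float
    skewness: float
    good_fraction: float

    def as_dict(self) -> dict:
        return {
            "target_id": self.target_id,
            "loss": self.loss,
            "z_scores": self.z,
            "sum_positive_z": self.sum_positive_z,
            "skewness": self.skewness,
            "good_fraction": self.good_fraction,
        }


def ranking_loss(true_scores: dict[str, float], selected_top1: str) -> float:
    """True score of the pool's best model minus that of the selected model."""
    if selected_top1 not in true_scores:
        raise KeyError(f"model {selected_top1!r} not in the score table")
    return abs(max(true_scores.values()) - true_scores[selected_top1])


def z_scores(scores: dict[str, float],
             population_sd: bool = True) -> tuple[dict[str, float], float]:
    """Standardised per-model scores and the sum of the positive ones.

    Uses the population SD (divide by n) by default, the CASP convention;
    set ``population_sd=False`` for the sample SD.  A zero-SD pool yields
    all-zero Z with a warning.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 models")
    vals = np.array(list(scores.values()), dtype=float)
    sd = vals.std(ddof=0 if population_sd else 1)
    if sd == 0:
        warnings.warn("zero standard deviation; all Z-scores set to 0")
        z = {m: 0.0 for m in scores}
        return z, 0.0
    mean = vals.mean()
    z = {m: float((s - mean) / sd) for m, s in scores.items()}
    return z, float(sum(max(v, 0.0) for v in z.values()))


def skewness(scores) -> float:
    """Sample skewness g1 = m3 / m2^(3/2) (moment estimator).

    Positive skew means the mean exceeds the median (mass at low scores
    with a thin tail of good models).  Zero-variance input yields 0 with a
    warning.
    """
    vals = np.asarray(list(scores), dtype=float)
    if len(vals) < 3:
        raise ValueError("need at least 3 values")
    if vals.std() == 0:
        warnings.warn("zero variance; skewness reported as 0")
        return 0.0
    return float(stats.skew(vals, bias=True))


def _row_identity(a: str, b: str, query_cols: np.ndarray, denom: int) -> float:
    aa = np.frombuffer(a.encode(), dtype="S1")[query_cols]
    bb = np.frombuffer(b.encode(), dtype="S1")[query_cols]
    same = (aa == bb) & (aa != b"-")
    return float(np.count_nonzero(same)) / denom


def neff(msa: MSA, identity_cut: float = NEFF_IDENTITY) -> int:
    """Effective sequence count: greedy clusters at > *identity_cut* identity.

    Rows are scanned in file order; a row joins the first cluster whose
    representative (founder) shares more than the cutoff identity, where
    identity counts identical non-gap residues over the query's non-gap
    columns divided by the query's non-gap length.  Neff is the number of
    clusters.
    """
    query_cols = np.flatnonzero(
        np.frombuffer(msa.query.encode(), dtype="S1") != b"-")
    denom = len(query_cols)
    if denom == 0:
        raise ValueError("query has no non-gap columns")
    reps: list[str] = []
    for row in msa.rows:
        for rep in reps:
            if _row_identity(row, rep, query_cols, denom) > identity_cut:
                break
        else:
            reps.append(row)
    return len(reps)


def good_fraction(scores, threshold: float = GOOD_TM) -> float:
    """Fraction of scores strictly above *threshold* (TM-score > 0.5)."""
    vals = np.asarray(list(scores), dtype=float)
    if len(vals) == 0:
        raise ValueError("empty score list")
    return float(np.mean(vals > threshold))


def coverage_profile(msa: MSA) -> np.ndarray:
    """Per query-column count of rows with a non-gap residue there."""
    arr = np.array([np.frombuffer(r.encode(), dtype="S1") for r in msa.rows])
    query_cols = arr[0] != b"-"
    return np.count_nonzero(arr[:, query_cols] != b"-", axis=0)


def correlate(x, y, log_x: bool = False) -> float:
    """Pearson correlation of y against x (optionally log x).

    Returns NaN with a warning when either side has zero variance.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with at least 3 points")
    if log_x:
        if np.any(x <= 0):
            raise ValueError("log_x requires positive x values")
        x = np.log(x)
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance; correlation undefined")
        return math.nan
    return float(stats.pearsonr(x, y)[0])


def evaluate_pool(target_id: str, true_scores: dict[str, float],
                  selected_top1: str) -> EvalReport:
    """Loss, Z-scores, skewness and good-model fraction for one target pool."""
    z, spz = z_scores(true_scores)
    return EvalReport(
        target_id=target_id,
        loss=ranking_loss(true_scores, selected_top1),
        z=z,
        sum_positive_z=spz,
        skewness=skewness(true_scores.values()),
        good_fraction=good_fraction(true_scores.values()),
    )
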