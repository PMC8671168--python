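"""Domain boundary detection from target-template alignment hits.

Template hits are filtered by significance (E-value <= 1), aligned length
(> 40 residues) and target coverage (> 0.5).  The union of the retained hit
intervals forms the template-based (TBM) cover of the target; every maximal
uncovered region longer than 40 residues becomes a template-free (FM)
domain, and shorter uncovered gaps are absorbed into the flanking
template-based regions.  A target with no retained hit is a single-domain
template-free target.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AlignmentHit",
    "DomainSegment",
    "filter_hits",
    "parse_domains",
    "classify_target",
    "read_hit_table",
    "write_hit_table",
    "write_segments_bed",
    "EVALUE_MAX",
    "MIN_ALIGNED_LENGTH",
    "MIN_COVERAGE",
    "FM_MIN_GAP",
]

EVALUE_MAX = 1.0
MIN_ALIGNED_LENGTH = 40   # hits of aligned length <= 40 are discarded
MIN_COVERAGE = 0.5
FM_MIN_GAP = 40           # uncovered regions > 40 residues become FM domains


@dataclass(frozen=True)
class AlignmentHit:
    """One target-template alignment hit (1-based inclusive target interval)."""

    template_id: str
    e_value: float
    target_start: int
    target_end: int
    coverage: float
    identity: float | None = None

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("E-value must be non-negative")
        if self.target_start > self.target_end:
            raise ValueError("target_start must be <= target_end")
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must lie in [0, 1]")

    @property
    def aligned_length(self) -> int:
        return self.target_end - self.target_start + 1


@dataclass(frozen=True)
class DomainSegment:
    """A 1-based inclusive target interval labelled FM or TBM."""

    start: int
    end: int
    klass: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must be <= end")
        if self.klass not in ("FM", "TBM"):
            raise ValueError(f"unknown domain class {self.klass!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def filter_hits(
    hits: list[AlignmentHit],
    evalue_max: float = EVALUE_MAX,
    min_aligned_length: int = MIN_ALIGNED_LENGTH,
    min_coverage: float = MIN_COVERAGE,
) -> list[AlignmentHit]:
    """Retain hits with E-value <= 1, aligned length > 40 and coverage > 0.5."""
    return [
        h for h in hits
        if h.e_value <= evalue_max
        and h.aligned_length > min_aligned_length
        and h.coverage > min_coverage
    ]


def parse_domains(L: int, retained: list[AlignmentHit],
                  fm_min_gap: int = FM_MIN_GAP) -> list[DomainSegment]:
    """Tile [1, L] into FM/TBM segments from the retained hits.

    The hit intervals' union is the TBM cover.  Uncovered runs longer than
    40 residues become FM segments; shorter runs join the adjacent TBM
    cover.  No retained hits at all yields a single FM segment over the
    whole target.
    """
    if L < 1:
        raise ValueError("target length must be >= 1")
    if not retained:
        return [DomainSegment(1, L, "FM")]
    covered = np.zeros(L, dtype=bool)
    for h in retained:
        a = max(h.target_start, 1)
        b = min(h.target_end, L)
        if a <= b:
            covered[a - 1: b] = True
    if not covered.any():
        return [DomainSegment(1, L, "FM")]

    # absorb short uncovered runs into the TBM cover
    runs = _runs(~covered)
    for a, b in runs:
        if b - a + 1 <= fm_min_gap:
            covered[a - 1: b] = True

    segments = []
    for a, b in _runs(covered):
        segments.append(DomainSegment(a, b, "TBM"))
    for a, b in _runs(~covered):
        segments.append(DomainSegment(a, b, "FM"))
    segments.sort(key=lambda s: s.start)
    return segments


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean mask as 1-based inclusive intervals."""
    out = []
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return out
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    for a, b in zip(starts, ends):
        out.append((int(a) + 1, int(b) + 1))
    return out


def classify_target(segments: list[DomainSegment]) -> str:
    """'FM', 'TBM' or 'FM_and_TBM' depending on the segment classes present."""
    if not segments:
        raise ValueError("no segments")
    klasses = {s.klass for s in segments}
    if klasses == {"FM"}:
        return "FM"
    if klasses == {"TBM"}:
        return "TBM"
    return "FM_and_TBM"


def read_hit_table(path: str | Path) -> list[AlignmentHit]:
    """Read a TSV of hits: template_id, e_value, target_start, target_end,
    coverage[, identity]."""
    df = pd.read_csv(path, sep="\t")
    hits = []
    for row in df.itertuples(index=False):
        hits.append(AlignmentHit(
            template_id=str(row.template_id),
            e_value=float(row.e_value),
            target_start=int(row.target_start),
            target_end=int(row.target_end),
            coverage=float(row.coverage),
            identity=float(row.identity) if hasattr(row, "identity") else None,
        ))
    return hits


def write_hit_table(hits: list[AlignmentHit], path: str | Path) -> None:
    rows = [{
        "template_id": h.template_id,
        "e_value": h.e_value,
        "target_start": h.target_start,
        "target_end": h.target_end,
        "coverage": h.coverage,
        "identity": h.identity,
    } for h in hits]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_segments_bed(segments: list[DomainSegment], target_id: str,
                       path: str | Path) -> None:
    """Write segments as BED-like lines (0-based half-open intervals)."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{target_id}\t{s.start - 1}\t{s.end}\t{s.klass}\n")
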