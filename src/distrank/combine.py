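"""Model combination: neighbour selection, consensus averaging, splicing.

Given a ranked model pool, a top-ranked *reference* model is combined with
structurally similar neighbours into a consensus candidate; the candidate
is accepted only if it stays close to the reference (GDT-TS >= 0.9),
otherwise the caller is expected to fall back to refining the reference.
Two neighbour-selection presets are provided: the "server" rule keeps
models with GDT-TS > 0.6 to the reference, while the "human" rule keeps
models ranked within the top 60 with GDT-TS > 0.7 or RMSD < 3 A.

The consensus engine is superpose-and-average at the Ca level: every
member is Kabsch-superposed onto the reference and the candidate trace is
the unweighted coordinate mean (reference included).  Region splicing
replaces a bad region of one model with the corresponding region of
another after a TM-score-optimal superposition computed on the residues
that are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import metrics
from .ranking import ModelPool, Ranking
from .structio import GeometryReport, Structure, geometry_check

__all__ = [
    "CombinationPlan",
    "PRESETS",
    "select_combination_set",
    "consensus_combine",
    "accept_candidate",
    "splice_regions",
    "combine_for_reference",
]

#: neighbour-selection presets: the automated-server rule and the human
#: protocol rule (top-60 rank window, GDT-TS/RMSD gate)
PRESETS = {
    "server": dict(gdt_min=0.6, rmsd_max=None, top_n=None, cap=20),
    "human": dict(gdt_min=0.7, rmsd_max=3.0, top_n=60, cap=20),
}
ACCEPTANCE_GDT = 0.9


@dataclass
class CombinationPlan:
    """Outcome of one combination attempt for a reference model."""

    reference_id: str
    member_ids: list[str]
    acceptance: str          # "accepted" | "rejected"
    candidate: Structure
    candidate_gdt: float
    geometry: GeometryReport | None = None

    def __post_init__(self) -> None:
        if len(self.member_ids) > 20:
            raise ValueError("at most 20 members may be combined")
        if self.reference_id in self.member_ids:
            raise ValueError("reference must not be among the members")


def select_combination_set(
    reference_id: str,
    pool: ModelPool,
    ranking: Ranking,
    gdt_min: float | None = 0.7,
    rmsd_max: float | None = 3.0,
    top_n: int | None = 60,
    cap: int = 20,
) -> list[str]:
    """Neighbour models eligible to be combined with the reference.

    A model qualifies when it is ranked within *top_n* (if set) and is
    similar to the reference: GDT-TS > *gdt_min* or RMSD < *rmsd_max*
    (whichever rules are enabled).  The list is truncated to *cap* members
    in rank order; it may legitimately be empty for hard targets.
    """
    reference = pool[reference_id]
    members = []
    for model_id in ranking.model_ids:
        if model_id == reference_id or model_id not in pool.model_ids:
            continue
        if top_n is not None and ranking.rank_of(model_id) > top_n:
            continue
        model = pool[model_id]
        ok = False
        if gdt_min is not None and metrics.gdt_ts(model, reference) > gdt_min:
            ok = True
        if not ok and rmsd_max is not None:
            if metrics.superpose(model, reference).rmsd < rmsd_max:
                ok = True
        if ok:
            members.append(model_id)
        if len(members) >= cap:
            break
    return members


def consensus_combine(reference: Structure, members: list[Structure]) -> Structure:
    """Superpose members onto the reference and average the Ca traces.

    All structures must share the reference's residue numbering.  With no
    members the reference is returned unchanged (with a warning).
    """
    if not members:
        warnings.warn("no members to combine; returning the reference model")
        return reference
    for m in members:
        if not np.array_equal(m.residue_index, reference.residue_index):
            raise ValueError("members must share the reference's residues")
    stack = [reference.ca_coords]
    for m in members:
        sp = metrics.superpose(m, reference)
        stack.append(sp.apply(m.ca_coords))
    mean_ca = np.mean(stack, axis=0)
    return Structure(
        target_id=reference.target_id,
        sequence=reference.sequence,
        residue_index=reference.residue_index.copy(),
        ca_coords=mean_ca,
    )


def accept_candidate(candidate: Structure, reference: Structure,
                     threshold: float = ACCEPTANCE_GDT) -> str:
    """'accepted' iff GDT-TS(candidate, reference) >= threshold.

    A rejection signals that the consensus drifted too far from the start
    model and the caller should refine the reference instead.
    """
    g = metrics.gdt_ts(candidate, reference)
    return "accepted" if g >= threshold else "rejected"


def splice_regions(keep: Structure, donor: Structure,
                   region: tuple[int, int]) -> tuple[Structure, GeometryReport]:
    """Replace *region* (1-based inclusive) of *keep* with the donor's copy.

    The donor is superposed onto *keep* with the TM-score-optimal
    superposition computed on the residues **outside** the region; the
    output trace is *keep* outside the region (bit-for-bit) and the
    superposed donor inside it.  The result's geometry report is returned
    alongside, since splicing can create junction breaks.
    """
    start, end = region
    if start > end:
        raise ValueError("region start must be <= end")
    for s in (keep, donor):
        if start < s.residue_index.min() or end > s.residue_index.max():
            raise ValueError("region outside structure residues")
    keep_mask = (keep.residue_index < start) | (keep.residue_index > end)
    if not keep_mask.any():
        raise ValueError("region covers the whole chain; nothing kept")
    donor_in = (donor.residue_index >= start) & (donor.residue_index <= end)
    if not donor_in.any():
        raise ValueError("donor has no residues in the region")

    sp = metrics.tm_superpose(donor.subset(~donor_in), keep.subset(keep_mask))
    donor_moved = sp.apply(donor.ca_coords)

    # assemble: keep's residues outside, donor's residues inside the region
    out_idx, out_seq, out_ca = [], [], []
    donor_pos = {int(r): k for k, r in enumerate(donor.residue_index)}
    for k, r in enumerate(keep.residue_index):
        r = int(r)
        if start <= r <= end:
            continue
        out_idx.append(r)
        out_seq.append(keep.sequence[k])
        out_ca.append(keep.ca_coords[k])
    for r in sorted(donor_pos):
        if start <= r <= end:
            out_idx.append(r)
            out_seq.append(donor.sequence[donor_pos[r]])
            out_ca.append(donor_moved[donor_pos[r]])
    order = np.argsort(out_idx)
    spliced = Structure(
        target_id=keep.target_id,
        sequence="".join(out_seq[i] for i in order),
        residue_index=np.array(out_idx)[order],
        ca_coords=np.array(out_ca)[order],
    )
    return spliced, geometry_check(spliced)


def combine_for_reference(
    reference_id: str,
    pool: ModelPool,
    ranking: Ranking,
    preset: str = "human",
    acceptance_threshold: float = ACCEPTANCE_GDT,
) -> CombinationPlan:
    """Full combination protocol for one reference model."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    member_ids = select_combination_set(
        reference_id, pool, ranking, **PRESETS[preset])
    reference = pool[reference_id]
    candidate = consensus_combine(reference, [pool[m] for m in member_ids])
    gdt = metrics.gdt_ts(candidate, reference)
    verdict = "accepted" if gdt >= acceptance_threshold else "rejected"
    return CombinationPlan(
        reference_id=reference_id,
        member_ids=member_ids,
        acceptance=verdict,
        candidate=candidate,
        candidate_gdt=gdt,
        geometry=geometry_check(candidate),
    )
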