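"""Structure I/O and derived geometric objects.

A :class:`Structure` is a single-chain Ca trace (optionally with Cb
coordinates) indexed by 1-based residue numbers.  From it we derive the
L x L inter-residue distance map, binary contact sets at a distance
threshold, and a geometry report flagging steric clashes and chain breaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "Structure",
    "DistanceMap",
    "ContactSet",
    "GeometryReport",
    "read_model",
    "write_model",
    "distance_map",
    "contacts_from_map",
    "geometry_check",
    "read_distance_map",
    "write_distance_map",
    "read_rr",
    "write_rr",
    "SEPARATION_CLASSES",
]

# CASP sequence-separation conventions: short 6-11, medium 12-23, long >= 24.
SEPARATION_CLASSES = {
    "short": (6, 11),
    "medium": (12, 23),
    "long": (24, None),
    "any": (1, None),
}

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_AA1TO3 = {v: k for k, v in _AA3TO1.items()}


@dataclass
class Structure:
    """Single-chain protein model reduced to per-residue coordinates.

    Parameters
    ----------
    target_id : str
        Identifier of the target (and optionally model) this chain belongs to.
    sequence : str
        One-letter amino-acid sequence of length L.
    residue_index : numpy.ndarray
        Strictly increasing 1-based residue numbers, shape (L,).
    ca_coords : numpy.ndarray
        Alpha-carbon coordinates in angstroms, shape (L, 3).
    cb_coords : numpy.ndarray, optional
        Beta-carbon coordinates (Ca reused for glycine); shape (L, 3).
    """

    target_id: str
    sequence: str
    residue_index: np.ndarray
    ca_coords: np.ndarray
    cb_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        if self.cb_coords is not None:
            self.cb_coords = np.asarray(self.cb_coords, dtype=float)
        L = len(self.sequence)
        if self.ca_coords.shape != (L, 3):
            raise ValueError(
                f"ca_coords shape {self.ca_coords.shape} != ({L}, 3)")
        if self.residue_index.shape != (L,):
            raise ValueError("residue_index length mismatch")
        if L and np.any(np.diff(self.residue_index) <= 0):
            raise ValueError("residue_index must be strictly increasing")
        if not np.all(np.isfinite(self.ca_coords)):
            raise ValueError("non-finite Ca coordinates")
        if self.cb_coords is not None and not np.all(np.isfinite(self.cb_coords)):
            raise ValueError("non-finite Cb coordinates")

    def __len__(self) -> int:
        return len(self.sequence)

    def coords(self, scheme: str = "ca") -> np.ndarray:
        """Coordinate matrix for *scheme* ('ca' or 'cb'; cb falls back to ca)."""
        if scheme == "ca":
            return self.ca_coords
        if scheme == "cb":
            return self.cb_coords if self.cb_coords is not None else self.ca_coords
        raise ValueError(f"unknown coordinate scheme {scheme!r}")

    def subset(self, mask: np.ndarray) -> "Structure":
        """New Structure restricted to the boolean/index *mask*."""
        seq = "".join(np.array(list(self.sequence))[mask])
        return Structure(
            target_id=self.target_id,
            sequence=seq,
            residue_index=self.residue_index[mask],
            ca_coords=self.ca_coords[mask],
            cb_coords=None if self.cb_coords is None else self.cb_coords[mask],
        )


@dataclass
class DistanceMap:
    """Symmetric L x L matrix of inter-residue distances in angstroms."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance map must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite distances")
        if np.any(v < 0):
            raise ValueError("negative distances")
        if not np.allclose(v, v.T):
            raise ValueError("distance map must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        self.values = v

    @property
    def size(self) -> int:
        return self.values.shape[0]


@dataclass
class ContactSet:
    """Residue pairs in contact, with per-pair scores.

    ``pairs`` is a list of ``(i, j, score)`` with 1-based ``i < j``; scores are
    probabilities for predicted contacts and 1.0 for observed ones.
    """

    pairs: list[tuple[int, int, float]]
    separation_class: str = "any"

    def __post_init__(self) -> None:
        if self.separation_class not in SEPARATION_CLASSES:
            raise ValueError(f"unknown separation class {self.separation_class!r}")
        lo, hi = SEPARATION_CLASSES[self.separation_class]
        seen = set()
        for i, j, _ in self.pairs:
            if not i < j:
                raise ValueError(f"pair ({i}, {j}) must have i < j")
            sep = j - i
            if sep < lo or (hi is not None and sep > hi):
                raise ValueError(
                    f"pair ({i}, {j}) violates class {self.separation_class}")
            if (i, j) in seen:
                raise ValueError(f"duplicate pair ({i}, {j})")
            seen.add((i, j))

    def __len__(self) -> int:
        return len(self.pairs)

    def keys(self) -> set[tuple[int, int]]:
        return {(i, j) for i, j, _ in self.pairs}


@dataclass
class GeometryReport:
    """Clash / chain-break diagnostics for a Ca trace."""

    clashes: list[tuple[int, int]] = field(default_factory=list)
    breaks: list[tuple[int, int]] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.clashes and not self.breaks


def read_model(path: str | Path, target_id: str | None = None) -> Structure:
    """Read the first chain of a PDB file into a :class:`Structure`.

    Keeps the first MODEL, first chain, and the highest-occupancy alternate
    location of each atom (the first on ties); hetero residues are skipped.
    Residues without a Ca atom are
    dropped with a warning (the index gap stays visible in
    ``residue_index``).  A file with no parseable residue raises
    ``ValueError``.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    parsed = PDBParser(QUIET=True).get_structure(path.stem, str(path))
    models = list(parsed)
    if not models:
        raise ValueError(f"no parseable ATOM records in {path}")
    chains = list(models[0])
    if not chains:
        raise ValueError(f"no parseable ATOM records in {path}")

    idx, seq, ca, cb, any_cb = [], [], [], [], False
    for res in chains[0]:
        if res.id[0] != " ":
            continue  # hetero/water
        resseq = res.id[1]
        if "CA" not in res:
            warnings.warn(
                f"residue {resseq} in {path.name} has no CA atom; dropped")
            continue
        idx.append(resseq)
        seq.append(_AA3TO1.get(res.get_resname().strip(), "X"))
        ca.append(res["CA"].get_coord())
        if "CB" in res:
            cb.append(res["CB"].get_coord())
            any_cb = True
        else:
            cb.append(res["CA"].get_coord())
    if not idx:
        raise ValueError(f"no residues with CA atoms in {path}")
    order = np.argsort(idx)
    idx = [idx[i] for i in order]
    seq = [seq[i] for i in order]
    ca = [ca[i] for i in order]
    cb = [cb[i] for i in order]
    return Structure(
        target_id=target_id or path.stem,
        sequence="".join(seq),
        residue_index=np.array(idx),
        ca_coords=np.array(ca),
        cb_coords=np.array(cb) if any_cb else None,
    )


def write_model(s: Structure, path: str | Path, remark: str | None = None) -> None:
    """Write a Structure as Ca (and Cb, if present) ATOM records."""
    lines = []
    if remark:
        lines.append(f"REMARK   1 {remark}")
    serial = 1
    for k in range(len(s)):
        resname = _AA1TO3.get(s.sequence[k], "UNK")
        for name, xyz in (("CA", s.ca_coords[k]),
                          ("CB", None if s.cb_coords is None else s.cb_coords[k])):
            if xyz is None:
                continue
            if name == "CB" and s.sequence[k] == "G":
                continue
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} {resname:>3s} "
                f"A{s.residue_index[k]:4d}"
                f"    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def distance_map(s: Structure, scheme: str = "ca") -> DistanceMap:
    """Euclidean inter-residue distance map under 'ca' or 'cb' coordinates."""
    xyz = s.coords(scheme)
    return DistanceMap(squareform(pdist(xyz)))


def contacts_from_map(
    m: DistanceMap,
    threshold: float = 8.0,
    separation_class: str = "any",
    residue_index: np.ndarray | None = None,
) -> ContactSet:
    """All residue pairs at distance <= *threshold* within the separation class.

    Separation is computed on residue numbering (``residue_index`` if given,
    else positional 1..L); scores are 1.0 since these are observed contacts.
    """
    if separation_class not in SEPARATION_CLASSES:
        raise ValueError(f"unknown separation class {separation_class!r}")
    lo, hi = SEPARATION_CLASSES[separation_class]
    L = m.size
    ridx = np.arange(1, L + 1) if residue_index is None else np.asarray(residue_index)
    pairs = []
    iu, ju = np.triu_indices(L, k=1)
    sep = ridx[ju] - ridx[iu]
    keep = (m.values[iu, ju] <= threshold) & (sep >= lo)
    if hi is not None:
        keep &= sep <= hi
    for a, b in zip(iu[keep], ju[keep]):
        pairs.append((int(ridx[a]), int(ridx[b]), 1.0))
    return ContactSet(pairs=pairs, separation_class=separation_class)


def geometry_check(
    s: Structure, clash_cut: float = 1.9, break_cut: float = 4.5
) -> GeometryReport:
    """Flag severe clashes and broken chains on the Ca trace.

    A clash is a non-adjacent Ca pair closer than *clash_cut* (default
    1.9 A); a break is a sequence-adjacent Ca pair farther than *break_cut*
    (default 4.5 A).  Adjacency means consecutive residue numbers.
    """
    d = squareform(pdist(s.ca_coords))
    idx = s.residue_index
    report = GeometryReport()
    L = len(s)
    for a in range(L - 1):
        if idx[a + 1] - idx[a] == 1 and d[a, a + 1] > break_cut:
            report.breaks.append((int(idx[a]), int(idx[a + 1])))
    iu, ju = np.triu_indices(L, k=1)
    adjacent = (idx[ju] - idx[iu]) == 1
    clash = (d[iu, ju] < clash_cut) & ~adjacent
    for a, b in zip(iu[clash], ju[clash]):
        report.clashes.append((int(idx[a]), int(idx[b])))
    return report


def read_distance_map(path: str | Path) -> DistanceMap:
    """Read a whitespace-delimited L x L distance matrix."""
    return DistanceMap(np.loadtxt(path))


def write_distance_map(m: DistanceMap, path: str | Path) -> None:
    np.savetxt(path, m.values, fmt="%.4f")


def read_rr(path: str | Path, separation_class: str = "any") -> ContactSet:
    """Read CASP RR-style contact records: ``i j [d1 d2] p`` per line.

    Header/sequence lines (non-numeric first token) are skipped.  Pairs are
    normalised to i < j; pairs outside the requested separation class are
    dropped.
    """
    lo, hi = SEPARATION_CLASSES[separation_class]
    pairs = []
    seen = set()
    with open(path) as fh:
        for line in fh:
            tok = line.split()
            if len(tok) < 2 or not tok[0].lstrip("-").isdigit():
                continue
            i, j = int(tok[0]), int(tok[1])
            if i > j:
                i, j = j, i
            if i == j or (i, j) in seen:
                continue
            sep = j - i
            if sep < lo or (hi is not None and sep > hi):
                continue
            p = float(tok[-1]) if len(tok) >= 3 else 1.0
            seen.add((i, j))
            pairs.append((i, j, p))
    return ContactSet(pairs=pairs, separation_class=separation_class)


def write_rr(c: ContactSet, path: str | Path) -> None:
    """Write contacts as CASP RR-style lines ``i j 0 8 p``."""
    with open(path, "w") as fh:
        for i, j, p in c.pairs:
            fh.write(f"{i} {j} 0 8 {p:.6f}\n")
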