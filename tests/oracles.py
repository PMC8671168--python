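"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own search/clustering code: the
superposition oracle uses scipy's rotation alignment, and the clustering
oracle operates directly on strings.
"""

from itertools import combinations

import numpy as np
from scipy.spatial.transform import Rotation


def scipy_transform(a_sel, b_sel):
    """Independent Kabsch (scipy align_vectors): rotation matrix + centres."""
    ac, bc = a_sel.mean(0), b_sel.mean(0)
    rot, _ = Rotation.align_vectors(b_sel - bc, a_sel - ac)
    return rot.as_matrix(), ac, bc


def oracle_gdt(model, reference) -> float:
    """GDT-TS by exhaustive subset superposition (sizes >= 3)."""
    a, b = model.ca_coords, reference.ca_coords
    n = len(a)
    best = {c: 0.0 for c in (1.0, 2.0, 4.0, 8.0)}
    for k in range(3, n + 1):
        for sel in combinations(range(n), k):
            sel = list(sel)
            rot, ac, bc = scipy_transform(a[sel], b[sel])
            d = np.linalg.norm((a - ac) @ rot.T + bc - b, axis=1)
            for c in best:
                best[c] = max(best[c], float(np.mean(d <= c)))
    return float(np.mean(list(best.values())))


def oracle_neff(rows, cut=0.62) -> int:
    """Greedy identity clustering written directly on strings."""
    query = rows[0]
    cols = [c for c, ch in enumerate(query) if ch != "-"]
    reps = []
    for row in rows:
        row = row.upper()
        for rep in reps:
            same = sum(1 for c in cols if row[c] == rep[c] and row[c] != "-")
            if same / len(cols) > cut:
                break
        else:
            reps.append(row)
    return len(reps)


def oracle_contacts(values, threshold, lo, hi):
    """Exhaustive double-loop contact enumeration on a distance matrix."""
    n = values.shape[0]
    out = set()
    for i in range(n):
        for j in range(i + 1, n):
            sep = j - i
            if values[i, j] <= threshold and sep >= lo and (
                    hi is None or sep <= hi):
                out.add((i + 1, j + 1))
    return out
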