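"""Independent oracles used by the test-suite.

These deliberately avoid the code paths they check: brute-force pair
scans, central finite differences, an exhaustive rotation-grid RMSD, and a
Gauss-code crossing-reduction unknot certifier.
"""

from __future__ import annotations

import numpy as np


def brute_force_contacts(positions, cutoff, min_seq_sep):
    """All-pairs distance scan."""
    n = len(positions)
    out = set()
    for i in range(n):
        for j in range(i + min_seq_sep, n):
            if np.linalg.norm(positions[i] - positions[j]) <= cutoff:
                out.add((i, j))
    return out


def finite_diff_force(energy_fn, x, h=1e-5):
    x = np.asarray(x, dtype=float)
    f = np.zeros_like(x)
    for i in range(x.shape[0]):
        for k in range(3):
            xp, xm = x.copy(), x.copy()
            xp[i, k] += h
            xm[i, k] -= h
            f[i, k] = -(energy_fn(xp) - energy_fn(xm)) / (2 * h)
    return f


def grid_search_rmsd(a, b, n_angles=40):
    """Exhaustive proper-rotation grid for small point sets."""
    from scipy.spatial.transform import Rotation

    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    best = np.inf
    angles = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
    betas = np.linspace(0, np.pi, n_angles // 2)
    for al in angles:
        for be in betas:
            for ga in angles:
                R = Rotation.from_euler("zyz", [al, be, ga]).as_matrix()
                r = np.sqrt(np.mean(np.sum((a - b @ R.T) ** 2, axis=1)))
                if r < best:
                    best = r
    return best


# ---------------------------------------------------------------------------
# Gauss-code crossing reduction
# ---------------------------------------------------------------------------

def gauss_code(crossings):
    """Cyclic Gauss code [(crossing_id, 'O'|'U'), ...] in traversal order."""
    events = []
    for cid, c in enumerate(crossings):
        events.append((c.s_under, cid, "U"))
        events.append((c.s_over, cid, "O"))
    events.sort()
    return [(cid, kind) for _, cid, kind in events]


def _apply_r1(code):
    m = len(code)
    for i in range(m):
        j = (i + 1) % m
        if code[i][0] == code[j][0]:
            keep = [code[k] for k in range(m) if k not in (i, j)]
            return keep, True
    return code, False


def _apply_r2(code):
    m = len(code)
    # find adjacent same-pass pairs (a,b); removable if (a,b) or (b,a)
    # also appears adjacently with the opposite pass for both
    pairs = {}
    for i in range(m):
        j = (i + 1) % m
        (a, ka), (b, kb) = code[i], code[j]
        if a != b and ka == kb:
            pairs.setdefault(frozenset((a, b)), set()).add(ka)
    for key, kinds in pairs.items():
        if kinds == {"O", "U"}:
            a, b = tuple(key)
            keep = [e for e in code if e[0] not in (a, b)]
            return keep, True
    return code, False


def reduce_gauss_code(crossings):
    """Reidemeister-I/II reduction of the Gauss code; an empty result
    certifies the unknot (the converse need not hold in general, but does
    for the simple diagrams these tests produce)."""
    code = gauss_code(crossings)
    changed = True
    while changed and code:
        code, changed = _apply_r1(code)
        if not changed:
            code, changed = _apply_r2(code)
    return code
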