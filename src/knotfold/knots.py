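"""Open-chain knot analysis.

A protein chain is open, so its topology is made well-defined by closing it
into a ring: both termini are extended radially away from the chain
centroid onto a large sphere and joined by an arc (a *physical knot*).
The closed curve is simplified by rigidity-preserving triangle elimination
(KMT), projected onto a generic plane, and typed by the Alexander
determinant |Δ(−1)| (1 = unknot, 3 = trefoil, 5 = figure-eight / 5-class).
Trefoil handedness comes from the summed crossing signs of the reduced
diagram.  On top of the per-conformation detector sit trajectory-level
tools: knotted-core localization, slipknot detection, first-knotting-event
search and knotting-mechanism classification (direct threading /
slipknotting / mousetrapping).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .samplers import Trajectory

logger = logging.getLogger(__name__)

_EPS = 1e-9


# ---------------------------------------------------------------------------
# Closure
# ---------------------------------------------------------------------------

def close_chain(open_curve: np.ndarray, radius_factor: float = 10.0,
                arc_segments: int = 12) -> np.ndarray:
    """Close an open curve through two radial extensions and a spherical arc.

    Each terminus is pushed radially away from the chain centroid onto a
    sphere of radius ``radius_factor`` × the radius of gyration; the two
    sphere points are joined by a discretized great-circle arc that stays
    far outside the chain.  Returns the closed polygon as a vertex array
    (closure edge last→first implicit).  An input whose first and last
    vertices coincide is already closed and is returned unchanged (minus
    the duplicate vertex).
    """
    pts = np.asarray(open_curve, dtype=float)
    if len(pts) < 4:
        raise ValueError("need >= 4 vertices")
    if np.linalg.norm(pts[0] - pts[-1]) < _EPS:
        return pts[:-1]

    centroid = pts.mean(axis=0)
    rg = math.sqrt(float(np.mean(np.sum((pts - centroid) ** 2, axis=1))))
    radius = max(radius_factor * rg, 1.0)

    ends = []
    for p in (pts[0], pts[-1]):
        v = p - centroid
        if np.linalg.norm(v) < _EPS:
            logger.warning("terminus coincides with centroid; jittering")
            v = np.array([1e-6, 0.0, 0.0])
        ends.append(v / np.linalg.norm(v))
    u0, u1 = ends

    dot = float(np.clip(np.dot(u0, u1), -1.0, 1.0))
    omega = math.acos(dot)
    arc = []
    if omega < 1e-6:
        arc = []
    else:
        if abs(omega - math.pi) < 1e-6:
            # antipodal: route through an arbitrary orthogonal waypoint
            w = np.cross(u0, np.array([1.0, 0.0, 0.0]))
            if np.linalg.norm(w) < 1e-6:
                w = np.cross(u0, np.array([0.0, 1.0, 0.0]))
            w /= np.linalg.norm(w)
            half1 = _slerp(u1, w, arc_segments // 2 + 1)
            half2 = _slerp(w, u0, arc_segments // 2 + 1)
            arc = half1[1:-1] + [w] + half2[1:-1]
        else:
            arc = _slerp(u1, u0, arc_segments + 1)[1:-1]
    closure = [centroid + radius * ends[1]]
    closure += [centroid + radius * a for a in arc]
    closure += [centroid + radius * ends[0]]
    return np.vstack([pts, closure])


def _slerp(a, b, n):
    dot = float(np.clip(np.dot(a, b), -1.0, 1.0))
    omega = math.acos(dot)
    if omega < 1e-9:
        return [a.copy() for _ in range(n)]
    return [
        (math.sin((1 - t) * omega) * a + math.sin(t * omega) * b)
        / math.sin(omega)
        for t in np.linspace(0.0, 1.0, n)
    ]


# ---------------------------------------------------------------------------
# KMT simplification
# ---------------------------------------------------------------------------

def _segment_hits_triangle(p, q, a, b, c) -> np.ndarray:
    """Vectorized: do segments p[i]->q[i] cross triangle (a,b,c)?
    Coplanar/degenerate cases count as hits (conservative)."""
    n = np.cross(b - a, c - a)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        return np.zeros(len(p), dtype=bool)  # degenerate triangle blocks nothing
    d = q - p
    denom = d @ n
    num = (a - p) @ n
    hits = np.zeros(len(p), dtype=bool)
    para = np.abs(denom) < 1e-12
    # parallel & in-plane: conservative hit if either endpoint near plane
    hits |= para & (np.abs(num) < 1e-9 * nn)
    ok = ~para
    t = np.full(len(p), -1.0)
    t[ok] = num[ok] / denom[ok]
    cand = ok & (t >= -1e-12) & (t <= 1 + 1e-12)
    if not np.any(cand):
        return hits
    x = p[cand] + t[cand, None] * d[cand]
    v0, v1 = c - a, b - a
    v2 = x - a
    d00, d01, d11 = v0 @ v0, v0 @ v1, v1 @ v1
    d02 = v2 @ v0
    d12 = v2 @ v1
    den = d00 * d11 - d01 * d01
    if abs(den) < 1e-15:
        hits[np.nonzero(cand)[0]] = True  # degenerate triangle frame: be safe
        return hits
    inv = 1.0 / den
    uu = (d11 * d02 - d01 * d12) * inv
    vv = (d00 * d12 - d01 * d02) * inv
    inside = (uu >= -1e-12) & (vv >= -1e-12) & (uu + vv <= 1 + 1e-12)
    hits[np.nonzero(cand)[0][inside]] = True
    return hits


def kmt_simplify(closed: np.ndarray, min_vertices: int = 3) -> np.ndarray:
    """Rigidity-preserving triangle elimination for a closed polygon.

    Vertex i is removable when the triangle (i−1, i, i+1) is not crossed
    by any non-adjacent polygon edge; removal preserves the knot type.
    Iterates to a fixed point.
    """
    pts = np.asarray(closed, dtype=float).copy()
    changed = True
    while changed and len(pts) > min_vertices:
        changed = False
        i = 0
        while i < len(pts) and len(pts) > min_vertices:
            m = len(pts)
            a, b, c = pts[(i - 1) % m], pts[i], pts[(i + 1) % m]
            seg_p = pts
            seg_q = np.roll(pts, -1, axis=0)
            mask = np.ones(m, dtype=bool)
            for k in ((i - 2) % m, (i - 1) % m, i, (i + 1) % m):
                mask[k] = False
            if not np.any(_segment_hits_triangle(seg_p[mask], seg_q[mask],
                                                 a, b, c)):
                pts = np.delete(pts, i, axis=0)
                changed = True
            else:
                i += 1
    return pts


# ---------------------------------------------------------------------------
# Diagram: crossings of a generic projection
# ---------------------------------------------------------------------------

@dataclass
class Crossing:
    s_under: float     # arc-length parameter (edge index + fraction) of understrand
    s_over: float
    sign: int


class ProjectionError(RuntimeError):
    pass


def _crossings_of_projection(pts: np.ndarray):
    """All transverse crossings of the xy-projection of a closed polygon.

    Raises ProjectionError on any near-degenerate geometry (parallel
    overlap, endpoint crossing, coincident depths).
    """
    m = len(pts)
    xy = pts[:, :2]
    z = pts[:, 2]
    nxt = np.roll(np.arange(m), -1)
    crossings = []
    for k in range(m):
        a, b = xy[k], xy[nxt[k]]
        za, zb = z[k], z[nxt[k]]
        e1 = b - a
        for l in range(k + 1, m):
            if l == k or nxt[l] == k or nxt[k] == l:
                continue
            c, d = xy[l], xy[nxt[l]]
            e2 = d - c
            denom = e1[0] * e2[1] - e1[1] * e2[0]
            rx, ry = c[0] - a[0], c[1] - a[1]
            if abs(denom) < 1e-12:
                continue
            t = (rx * e2[1] - ry * e2[0]) / denom
            u = (rx * e1[1] - ry * e1[0]) / denom
            if -1e-9 < t < 1e-9 or 1 - 1e-9 < t < 1 + 1e-9 or \
               -1e-9 < u < 1e-9 or 1 - 1e-9 < u < 1 + 1e-9:
                if -1e-9 < t < 1 + 1e-9 and -1e-9 < u < 1 + 1e-9:
                    raise ProjectionError("endpoint crossing")
                continue
            if not (0 < t < 1 and 0 < u < 1):
                continue
            z1 = za + t * (z[nxt[k]] - za)
            z2 = z[l] + u * (z[nxt[l]] - z[l])
            if abs(z1 - z2) < 1e-9:
                raise ProjectionError("coincident crossing depths")
            # sign: right-handed crossing = +1 (calibrated against the
            # Gauss writhe integral)
            if z1 > z2:
                e_over, e_under = e1, e2
            else:
                e_over, e_under = e2, e1
            sgn = 1 if (e_over[0] * e_under[1] - e_over[1] * e_under[0]) > 0 \
                else -1
            if z1 > z2:
                crossings.append(Crossing(s_under=l + u, s_over=k + t, sign=sgn))
            else:
                crossings.append(Crossing(s_under=k + t, s_over=l + u, sign=sgn))
    return crossings


_PERTURB_RNG_SEED = 961748927  # fixed: projections must be reproducible


def diagram_crossings(closed: np.ndarray, max_perturb: int = 100):
    """Crossings of a generic planar projection of the (KMT-reduced)
    closed polygon; the projection direction is perturbed deterministically
    until no degenerate crossings remain."""
    rng = np.random.default_rng(_PERTURB_RNG_SEED)
    pts0 = np.asarray(closed, dtype=float)
    scale = float(np.max(np.abs(pts0 - pts0.mean(axis=0)))) or 1.0
    for trial in range(max_perturb):
        if trial == 0:
            R = np.eye(3)
        else:
            R = Rotation.from_quat(rng.normal(size=4)).as_matrix()
        pts = pts0 @ R.T
        if trial >= 20:
            # rotations alone cannot resolve a singular polygon (a vertex
            # exactly on another edge); resolve with a tiny jitter
            pts = pts + rng.normal(scale=1e-7 * scale, size=pts.shape)
        try:
            return _crossings_of_projection(pts)
        except ProjectionError:
            continue
    raise ProjectionError(
        f"no generic projection found in {max_perturb} perturbations"
    )


# ---------------------------------------------------------------------------
# Alexander determinant at t = -1
# ---------------------------------------------------------------------------

def _bareiss_det(M: list[list[int]]) -> int:
    """Exact integer determinant (fraction-free Gaussian elimination)."""
    A = [row[:] for row in M]
    n = len(A)
    if n == 0:
        return 1
    sign = 1
    prev = 1
    for k in range(n - 1):
        if A[k][k] == 0:
            for r in range(k + 1, n):
                if A[r][k] != 0:
                    A[k], A[r] = A[r], A[k]
                    sign = -sign
                    break
            else:
                return 0
        for i in range(k + 1, n):
            for j in range(k + 1, n):
                A[i][j] = (A[i][j] * A[k][k] - A[i][k] * A[k][j]) // prev
        prev = A[k][k]
    return sign * A[-1][-1]


def alexander_det_from_crossings(crossings) -> int:
    """|Δ(−1)| from a crossing list (underpass-generator presentation)."""
    n = len(crossings)
    if n == 0:
        return 1
    order = sorted(range(n), key=lambda i: crossings[i].s_under)
    under_params = [crossings[i].s_under for i in order]

    def arc_of(s: float) -> int:
        """Generator index (0-based) of the arc containing parameter s:
        arc k runs from underpass k-1 to underpass k."""
        import bisect
        pos = bisect.bisect_left(under_params, s)
        return pos % n

    M = [[0] * n for _ in range(n)]
    for row, ci in enumerate(order):
        c = crossings[ci]
        k, k1 = row, (row + 1) % n
        i = arc_of(c.s_over)
        if i == (row + 1) % n or i == row:
            M[row][row] += -1
            M[row][(row + 1) % n] += 1
        else:
            M[row][row] += 1
            M[row][(row + 1) % n] += 1
            M[row][i] += -2
    minor = [r[: n - 1] for r in M[: n - 1]]
    return abs(_bareiss_det(minor))


def alexander_det(closed_polygon: np.ndarray, simplify: bool = True) -> int:
    """Alexander determinant |Δ(−1)| of a closed polygon."""
    pts = np.asarray(closed_polygon, dtype=float)
    if simplify:
        pts = kmt_simplify(pts)
    if len(pts) < 6:
        return 1
    return alexander_det_from_crossings(diagram_crossings(pts))


# ---------------------------------------------------------------------------
# Chain-level classification
# ---------------------------------------------------------------------------

@dataclass
class KnotAssignment:
    determinant: int
    label: str            # unknot | trefoil | det5 | other
    chirality: str        # right | left | n/a


@dataclass
class KnotCore:
    start: int            # 1-based inclusive
    end: int


@dataclass
class KnottingEvent:
    frame: int
    core_at_event: KnotCore
    mechanism: str = "unclassified"


_LABELS = {1: "unknot", 3: "trefoil", 5: "det5"}


def _as_points(trace_or_points) -> np.ndarray:
    if hasattr(trace_or_points, "positions"):
        return np.asarray(trace_or_points.positions, dtype=float)
    return np.asarray(trace_or_points, dtype=float)


def chain_is_knotted(trace_or_points) -> bool:
    pts = _as_points(trace_or_points)
    if len(pts) < 4:
        return False
    return alexander_det(close_chain(pts)) != 1


def classify_knot(trace_or_points, votes: int = 1) -> KnotAssignment:
    """Knot type and (for trefoils) handedness of an open chain.

    With ``votes > 1`` the chain is rotated into ``votes`` deterministic
    orientations, closed in each, and the majority determinant wins — a
    guard for shallow knots whose closure is direction-sensitive.
    """
    pts = _as_points(trace_or_points)
    if votes <= 1:
        det = alexander_det(close_chain(pts))
    else:
        rng = np.random.default_rng(20_220_117)
        dets = []
        for v in range(votes):
            R = (np.eye(3) if v == 0
                 else Rotation.from_quat(rng.normal(size=4)).as_matrix())
            dets.append(alexander_det(close_chain(pts @ R.T)))
        vals, counts = np.unique(dets, return_counts=True)
        det = int(vals[np.argmax(counts)])
    label = _LABELS.get(det, "other")
    chirality = "n/a"
    if label == "trefoil":
        reduced = kmt_simplify(close_chain(pts))
        s = sum(c.sign for c in diagram_crossings(reduced))
        chirality = "right" if s > 0 else "left"
    return KnotAssignment(determinant=det, label=label, chirality=chirality)


def writhe(closed: np.ndarray, n_sub: int | None = None) -> float:
    """Gauss double-integral writhe of a closed polygon (used to anchor
    the crossing-sign convention; positive for right-handed trefoils)."""
    pts = np.asarray(closed, dtype=float)
    m = len(pts)
    seg = np.roll(pts, -1, axis=0) - pts
    mid = pts + 0.5 * seg
    w = 0.0
    for i in range(m):
        for j in range(i + 1, m):
            if abs(i - j) in (0, 1, m - 1):
                continue
            r = mid[i] - mid[j]
            d = np.linalg.norm(r)
            if d < 1e-9:
                continue
            w += float(np.dot(np.cross(seg[i], seg[j]), r)) / d**3
    return w / (2 * math.pi)


def locate_core(trace_or_points) -> KnotCore:
    """Smallest knotted subchain, by alternating N/C terminal trimming
    with re-closure after every deletion."""
    pts = _as_points(trace_or_points)
    n = len(pts)
    if not chain_is_knotted(pts):
        raise ValueError("locate_core called on an unknotted chain")
    start, end = 0, n - 1
    blocked = {"N": False, "C": False}
    side = "N"
    while not (blocked["N"] and blocked["C"]):
        if blocked[side]:
            side = "C" if side == "N" else "N"
            continue
        if side == "N":
            s, e = start + 1, end
        else:
            s, e = start, end - 1
        if e - s + 1 >= 4 and chain_is_knotted(pts[s:e + 1]):
            start, end = s, e
        else:
            blocked[side] = True
        side = "C" if side == "N" else "N"
    return KnotCore(start=start + 1, end=end + 1)


def detect_slipknot(trace_or_points, grid: int = 12) -> tuple[int, int] | None:
    """Find a knotted subchain of an unknotted chain (a slipknot).

    Scans a coarse grid of intervals, then greedily refines the first hit.
    Returns 1-based inclusive (a, b) or None.  A whole-chain knot is not a
    slipknot by definition.
    """
    pts = _as_points(trace_or_points)
    n = len(pts)
    if n < 8 or chain_is_knotted(pts):
        return None
    step = max(2, n // grid)
    lengths = range(n - step, max(7, 2 * step) - 1, -step)
    for L in lengths:
        for a in range(0, n - L + 1, step):
            sub = pts[a:a + L]
            if chain_is_knotted(sub):
                core = locate_core(sub)
                return (a + core.start, a + core.end)
    return None


def first_knotting_event(trajectory: Trajectory,
                         persistence: int = 10) -> KnottingEvent | None:
    """Earliest frame from which the chain stays knotted for ``persistence``
    consecutive saved frames; records the knot core at that frame."""
    flags = trajectory.scalars.get("knotted")
    if flags is None:
        flags = np.asarray([chain_is_knotted(f) for f in trajectory.frames])
    flags = np.asarray(flags, dtype=bool)
    m = len(flags)
    for f in range(m - persistence + 1):
        if np.all(flags[f:f + persistence]):
            return KnottingEvent(
                frame=f, core_at_event=locate_core(trajectory.frames[f])
            )
    return None


# ---------------------------------------------------------------------------
# Mechanism classification
# ---------------------------------------------------------------------------

def _bend_angle(pts: np.ndarray, terminus: str, seg: int = 5,
                zone: int = 10) -> float:
    """Hook angle (deg) of a terminus: angle between the outward direction
    of the last ``seg`` beads and the chain direction just before the
    terminal ``zone``.  0 = straight terminus, 180 = fully doubled back."""
    n = len(pts)
    if n < zone + seg + 1:
        zone = max(seg, n // 2)
    if terminus == "C":
        v1 = pts[n - 1] - pts[n - seg]
        v2 = pts[n - zone - 1] - pts[max(n - zone - 1 - seg, 0)]
    else:
        v1 = pts[0] - pts[seg - 1]
        v2 = pts[zone] - pts[min(zone + seg, n - 1)]
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12)
    return math.degrees(math.acos(np.clip(c, -1, 1)))


def _threading_terminus(core: KnotCore, n: int) -> str:
    """The terminus nearer the knot core; ties go to C (protein knots are
    predominantly C-threaded)."""
    return "N" if (core.start - 1) < (n - core.end) else "C"


def classify_mechanism(
    trajectory: Trajectory,
    event: KnottingEvent,
    window: int = 10,
    *,
    bend_threshold_deg: float = 90.0,
    terminal_zone: int = 10,
    displacement_ratio: float = 2.0,
) -> str:
    """Label the knotting mechanism of a detected event.

    Decision rules, applied in order over the ``window`` frames preceding
    the event: (1) *slipknotting* — some pre-event frame holds a slipknot
    and the threading terminus is bent back (> ``bend_threshold_deg``);
    (2) *direct threading* — the knot core abuts a terminus (within
    ``terminal_zone`` residues) and that terminus stays straight
    throughout; (3) *mousetrapping* — the loop (core minus the terminal
    zone) moves more than ``displacement_ratio`` × the terminal residues;
    otherwise *unclassified*.  The thresholds operationalize qualitative
    descriptions and are configuration-exposed.
    """
    f = event.frame
    lo = f - window
    if lo < 0:
        logger.warning("mechanism window truncated at trajectory start")
        lo = 0
    pre = trajectory.frames[lo:f + 1]
    n = trajectory.n_beads
    core = event.core_at_event
    term = _threading_terminus(core, n)

    bends = np.array([_bend_angle(fr, term) for fr in pre])

    # rule 1: slipknotting
    if np.max(bends) > bend_threshold_deg:
        for fr in pre[:-1]:
            if detect_slipknot(fr) is not None:
                return "slipknotting"

    # rule 2: direct threading
    abuts = (core.start - 1 <= terminal_zone and term == "N") or \
            (n - core.end <= terminal_zone and term == "C")
    if abuts and np.all(bends < bend_threshold_deg):
        return "direct_threading"

    # rule 3: mousetrapping
    if len(pre) >= 2:
        disp = np.linalg.norm(np.diff(pre, axis=0), axis=2)  # (w, n)
        if term == "C":
            term_idx = np.arange(n - terminal_zone, n)
        else:
            term_idx = np.arange(0, terminal_zone)
        loop_idx = np.setdiff1d(
            np.arange(core.start - 1, core.end), term_idx
        )
        if len(loop_idx) and len(term_idx):
            loop_disp = float(np.mean(disp[:, loop_idx]))
            term_disp = float(np.mean(disp[:, term_idx]))
            if loop_disp > displacement_ratio * max(term_disp, 1e-12):
                return "mousetrapping"
    return "unclassified"


def knotting_probability_curve(trajectories, time_grid):
    """Fraction of trajectories knotted at each grid time, with binomial
    standard error.  Trajectories must share the same time unit (sweeps)."""
    if len(trajectories) == 0:
        raise ValueError("empty trajectory ensemble")
    time_grid = np.asarray(time_grid, dtype=float)
    ntr = len(trajectories)
    frac = np.zeros(len(time_grid))
    for traj in trajectories:
        flags = traj.scalars.get("knotted")
        if flags is None:
            flags = np.asarray([chain_is_knotted(fr) for fr in traj.frames])
        flags = np.asarray(flags, dtype=bool)
        times = traj.times()
        idx = np.searchsorted(times, time_grid, side="right") - 1
        idx = np.clip(idx, 0, len(flags) - 1)
        frac += flags[idx]
    frac /= ntr
    se = np.sqrt(frac * (1 - frac) / ntr)
    return frac, se
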