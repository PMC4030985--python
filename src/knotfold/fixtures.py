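"""Deterministic synthetic inputs: parametric knots, coils, toy native
folds and scripted knotting-mechanism trajectories.

Everything the test-suite and the examples need is generated here, so the
package exercises end-to-end without downloads.  All generators are pure
functions of their arguments (identical spec → identical output).

The scripted mechanism trajectories are *kinematic*, not dynamical: they
animate the geometry of each knotting mode (a straight terminus translated
through a fixed loop; a backward-bent terminus inserted and then
straightened; a loop rotated over a static terminus) to pin the decision
boundaries of the mechanism classifier.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np

from .samplers import Trajectory
from .structure import CaTrace, NativeContactMap, build_contact_map

logger = logging.getLogger(__name__)

CA_BOND = 3.8  # Å, canonical consecutive Cα spacing

# Phase/gap for open parametric knots, chosen away from the curves'
# symmetry planes so the radial closure is insensitive to the cut.
_TREFOIL_PHASE = 0.7
_TREFOIL_GAP = 0.45
_FIG8_PHASE = 0.4
_FIG8_GAP = 0.35


def _resample_arclength(curve: np.ndarray, n: int, spacing: float | None = None
                        ) -> np.ndarray:
    """Resample a polyline at n points equally spaced in arclength; if
    ``spacing`` is given the whole curve is rescaled to that bond length."""
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    grid = np.linspace(0.0, s[-1], n)
    out = np.stack([np.interp(grid, s, curve[:, k]) for k in range(3)], axis=1)
    if spacing is not None:
        cur = s[-1] / (n - 1)
        out *= spacing / cur
    return out


def _trefoil_curve(n: int, phase: float, span: float) -> np.ndarray:
    """Left-handed parametric trefoil (negative writhe)."""
    t = phase + np.linspace(0.0, span, n)
    return np.stack([
        np.sin(t) + 2 * np.sin(2 * t),
        np.cos(t) - 2 * np.cos(2 * t),
        -np.sin(3 * t),
    ], axis=1)


def _figure_eight_curve(n: int, phase: float, span: float) -> np.ndarray:
    t = phase + np.linspace(0.0, span, n)
    return np.stack([
        (2 + np.cos(2 * t)) * np.cos(3 * t),
        (2 + np.cos(2 * t)) * np.sin(3 * t),
        np.sin(4 * t),
    ], axis=1)


def _min_nonadjacent_gap(pts: np.ndarray) -> float:
    """Smallest distance between beads more than 2 apart in sequence."""
    n = len(pts)
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    ii, jj = np.triu_indices(n, k=3)
    return float(np.min(d[ii, jj])) if len(ii) else np.inf


def parametric_knot(knot_type: str, n_beads: int = 200, noise_A: float = 0.0,
                    seed: int = 0) -> np.ndarray:
    """Open curve of a given knot type, protein-like bond spacing.

    ``knot_type`` in {unknot, trefoil_right, trefoil_left, figure_eight}.
    Optional Gaussian vertex noise; if the noise makes non-adjacent beads
    approach within half a bond length (risking a topology change at
    polygon resolution), it is halved and the curve regenerated.
    """
    if n_beads < 4:
        raise ValueError("n_beads must be >= 4")
    if knot_type == "unknot":
        t = np.linspace(0.0, 1.8 * math.pi, n_beads)
        base = np.stack([np.cos(t), np.sin(t), 0.05 * np.sin(2 * t)], axis=1)
    elif knot_type in ("trefoil_right", "trefoil_left"):
        base = _trefoil_curve(max(4 * n_beads, 400), _TREFOIL_PHASE,
                              2 * math.pi - _TREFOIL_GAP)
        if knot_type == "trefoil_right":
            base = base * np.array([-1.0, 1.0, 1.0])
    elif knot_type == "figure_eight":
        base = _figure_eight_curve(max(4 * n_beads, 400), _FIG8_PHASE,
                                   2 * math.pi - _FIG8_GAP)
    else:
        raise ValueError(f"unknown knot type {knot_type!r}")
    pts = _resample_arclength(base, n_beads, spacing=CA_BOND)

    amp = noise_A
    while amp > 0:
        rng = np.random.default_rng(seed)
        cand = pts + rng.normal(scale=amp, size=pts.shape)
        if _min_nonadjacent_gap(cand) > 0.75 * CA_BOND:
            return cand
        warnings.warn(
            f"noise {amp:.3g} A risks self-intersection; halving"
        )
        amp *= 0.5
        if amp < 1e-3:
            break
    return pts


def extended_chain(n_beads: int, spacing: float = CA_BOND) -> np.ndarray:
    """Straight chain along x."""
    x = np.zeros((n_beads, 3))
    x[:, 0] = np.arange(n_beads) * spacing
    return x


def random_coil(n_beads: int, seed: int = 0, min_gap: float = 3.0
                ) -> np.ndarray:
    """Self-avoiding random walk with fixed bond length."""
    rng = np.random.default_rng(seed)
    pts = [np.zeros(3)]
    while len(pts) < n_beads:
        for _ in range(200):
            step = rng.standard_normal(3)
            step *= CA_BOND / np.linalg.norm(step)
            cand = pts[-1] + step
            prior = np.asarray(pts[:-1])
            if len(prior) == 0 or np.min(
                np.linalg.norm(prior - cand, axis=1)
            ) >= min_gap:
                pts.append(cand)
                break
        else:
            # restart the tail if boxed in
            pts = pts[: max(1, len(pts) // 2)]
    return np.asarray(pts)


def _ideal_helix(n: int, rise: float = 1.5, radius: float = 2.3,
                 twist_deg: float = 100.0) -> np.ndarray:
    t = np.arange(n) * math.radians(twist_deg)
    return np.stack([
        radius * np.cos(t), radius * np.sin(t), np.arange(n) * rise
    ], axis=1)


def _helix_hairpin(n: int) -> np.ndarray:
    """Two antiparallel ideal helices packed side by side, joined by a
    two-bead turn with near-canonical bond lengths."""
    n1 = (n - 2) // 2
    n2 = n - 2 - n1
    h1 = _ideal_helix(n1)
    h2 = _ideal_helix(n2)[::-1] * np.array([1.0, -1.0, 1.0])
    h2[:, 0] += 9.0
    # slide h2 vertically so the junction gap suits a two-bead turn
    g0 = h2[0] - h1[-1]
    dxy = math.hypot(g0[0], g0[1])
    dz_target = math.sqrt(max(9.5**2 - dxy**2, 0.25))
    h2[:, 2] += (h1[-1, 2] + dz_target) - h2[0, 2]
    g = h2[0] - h1[-1]
    perp = np.cross(g, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.array([1.0, 0.0, 0.0])
    perp /= np.linalg.norm(perp)
    third = np.linalg.norm(g) / 3.0
    bump = math.sqrt(max(CA_BOND**2 - third**2, 0.0))
    t1 = h1[-1] + g / 3.0 + bump * perp
    t2 = h1[-1] + 2.0 * g / 3.0 + bump * perp
    return np.vstack([h1, t1, t2, h2])


def _beta_hairpin_pair(n: int) -> np.ndarray:
    """Four-strand antiparallel sheet (two hairpins): pleated strands at
    4.8 Å lateral spacing with one-bead turns."""
    L = max(4, (n - 3) // 4)
    lengths = [L, L, L, n - 3 - 3 * L]
    pts: list[list[float]] = []
    direction = 1
    for si, Ls in enumerate(lengths):
        x = si * 4.8
        zs = np.arange(Ls) * 3.3
        if direction < 0:
            zs = zs[::-1] + (pts[-1][2] - 1.5 - zs[-1])
        for k, z in enumerate(zs):
            pts.append([x + 0.95 * (-1) ** k, 0.0, float(z)])
        if si < 3:
            zt = pts[-1][2]
            pts.append([x + 2.4, 2.6 * (-1) ** si, zt + direction * 1.5])
        direction *= -1
    return np.asarray(pts[:n])


def _shallow_trefoil(n: int, tail: int = 6) -> np.ndarray:
    """Compact open trefoil whose last ``tail`` beads protrude straight out
    of the knotted core (a shallow C-terminal knot)."""
    body = parametric_knot("trefoil_left", n - tail)
    d = body[-1] - body[-3]
    d /= np.linalg.norm(d)
    ext = body[-1] + np.outer(np.arange(1, tail + 1) * CA_BOND, d)
    return np.vstack([body, ext])


def _knot_sequence(pts: np.ndarray, tail: int = 10) -> list[str]:
    """Sequence design for the knotted mini-fold: hydrophobic threading
    tail and loop lining (residues spatially close to the tail), polar
    elsewhere — knotted proteins carry sequences that make the terminus
    stick to the threading loop, which is what lets the non-native
    quasi-chemical term matter for knotting."""
    n = len(pts)
    hydro = "ILVF"
    polar = "SQNKED"
    tail_idx = set(range(n - tail, n))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    near_tail = set()
    for i in range(n - tail):
        if np.min(d[i, n - tail:]) < 9.0:
            near_tail.add(i)
    seq = []
    for i in range(n):
        if i in tail_idx or i in near_tail:
            seq.append(hydro[i % len(hydro)])
        else:
            seq.append(polar[i % len(polar)])
    return seq


def _default_sequence(n: int, seed: int) -> list[str]:
    """Plausible mixed sequence, deterministic per (n, seed)."""
    rng = np.random.default_rng(seed + 7919)
    pool = list("ACDEFGHIKLMNPQRSTVWY")
    return [pool[i] for i in rng.integers(0, 20, size=n)]


def toy_native(n_beads: int = 20, motif: str = "helix_hairpin", seed: int = 0,
               cutoff_A: float = 7.5, min_seq_sep: int = 3
               ) -> tuple[CaTrace, NativeContactMap]:
    """Small designed native structures for folding experiments.

    Motifs: ``helix_hairpin`` (two packed helices), ``beta_hairpin_pair``
    (four-strand sheet), ``shallow_trefoil`` (knotted mini-fold whose core
    excludes the last ~6 beads).  Deterministic in (n_beads, motif, seed).
    """
    seq = None
    if motif == "helix_hairpin":
        pts = _helix_hairpin(n_beads)
        ss = ["helix"] * n_beads
    elif motif == "beta_hairpin_pair":
        pts = _beta_hairpin_pair(n_beads)
        ss = ["sheet"] * len(pts)
    elif motif == "shallow_trefoil":
        pts = _shallow_trefoil(n_beads)
        ss = ["coil"] * n_beads
        seq = _knot_sequence(pts)
    else:
        raise ValueError(f"unknown motif {motif!r}")
    pts = pts[:n_beads]
    trace = CaTrace(
        positions=pts,
        residue_type=seq or _default_sequence(len(pts), seed),
        ss_label=ss[: len(pts)],
    )
    cmap = build_contact_map(trace, cutoff_A=cutoff_A, min_seq_sep=min_seq_sep)
    return trace, cmap


# ---------------------------------------------------------------------------
# Scripted knotting-mechanism trajectories
# ---------------------------------------------------------------------------

def _mechanism_base(n: int = 56, tail: int = 8) -> np.ndarray:
    """Final (knotted) state shared by the mechanism scripts: an open
    trefoil with a straight threading tail of ``tail`` beads."""
    return _shallow_trefoil(n, tail=tail)


def _find_unthreading_offset(final: np.ndarray, m_tail: int,
                             dist: float = 60.0) -> np.ndarray:
    """A rigid translation of the last ``m_tail`` beads that unknots the
    chain (pulls the terminus out of the loop); deterministic search."""
    from .knots import chain_is_knotted

    candidates = []
    d_tail = final[-1] - final[-m_tail]
    d_tail /= np.linalg.norm(d_tail)
    centroid = final.mean(axis=0)
    d_out = final[-1] - centroid
    d_out /= np.linalg.norm(d_out)
    candidates = [-d_tail, d_out, d_tail,
                  np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, -1.0]),
                  np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])]
    for c in candidates:
        start = final.copy()
        start[-m_tail:] += dist * c
        if not chain_is_knotted(start):
            return dist * c
    raise RuntimeError("no unthreading direction found")


def scripted_mechanism_trajectory(label: str, seed: int = 0,
                                  n_post: int = 12) -> Trajectory:
    """Kinematic trajectory animating one knotting mechanism.

    ``label`` in {direct_threading, slipknotting, mousetrapping}; each
    script ends in a trefoil and holds the knotted state for ``n_post``
    frames so the first-knotting-event detector (persistence window)
    fires.  Marked kinematic in the trajectory metadata.
    """
    if label == "direct_threading":
        frames = _script_direct_threading()
    elif label == "slipknotting":
        frames = _script_slipknotting()
    elif label == "mousetrapping":
        frames = _script_mousetrapping()
    else:
        raise ValueError(f"unknown mechanism {label!r}")
    frames = np.concatenate(
        [frames, np.repeat(frames[-1][None], n_post, axis=0)], axis=0
    )
    traj = Trajectory(frames=frames, stride=1, seed=seed, temperature=0.0,
                      scalars={"kinematic": True, "label": label})
    return traj


def _script_direct_threading(n_pre: int = 16) -> np.ndarray:
    """Straight terminus rigidly translated through the fixed loop."""
    final = _mechanism_base()
    m = 10                                     # moving terminal beads
    offset = _find_unthreading_offset(final, m)
    frames = []
    for tau in np.linspace(0.0, 1.0, n_pre):
        fr = final.copy()
        fr[-m:] += (1.0 - tau) * offset
        frames.append(fr)
    return np.asarray(frames)


def _script_slipknotting(n_pre: int = 16) -> np.ndarray:
    """Backward-bent terminus inserted through the loop, then straightened.

    While the doubled-over tip sits beyond the loop the whole chain is
    unknotted but the subchain ending at the bend apex is knotted — the
    slipknot configuration; straightening the tip completes the knot.
    """
    from .knots import chain_is_knotted, detect_slipknot

    final = _mechanism_base()
    n = len(final)
    apex = n - 8                               # bend apex: deep enough that
    m_move = 12                                # the fold-back cancels threading
    axis = final[-1] - final[-10]
    axis /= np.linalg.norm(axis)
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)

    def bent_conf(straighten: float) -> np.ndarray:
        """straighten in [0,1]: 0 = fully doubled back, 1 = final straight."""
        fr = final.copy()
        for k in range(apex + 1, n):
            back = final[2 * apex - k] if 2 * apex - k >= 0 else final[0]
            folded = back + 1.5 * perp
            fr[k] = (1 - straighten) * folded + straighten * final[k]
        return fr

    bent0 = bent_conf(0.0)
    # withdrawal offset: bent tail pulled clear of the loop (no knot, no
    # slipknot), deterministic search
    centroid = final.mean(axis=0)
    d_out = final[-1] - centroid
    d_out /= np.linalg.norm(d_out)
    offset = None
    for c in (-axis, d_out, np.array([0.0, 0.0, 1.0]),
              np.array([0.0, 1.0, 0.0]), np.array([1.0, 0.0, 0.0])):
        start = bent0.copy()
        start[-m_move:] += 60.0 * c
        if not chain_is_knotted(start) and detect_slipknot(start) is None:
            offset = 60.0 * c
            break
    if offset is None:
        raise RuntimeError("no withdrawal direction found")

    frames = []
    half = n_pre // 2
    for tau in np.linspace(0.0, 1.0, half):   # phase A: insert bent terminus
        fr = bent0.copy()
        fr[-m_move:] += (1.0 - tau) * offset
        frames.append(fr)
    for s in np.linspace(0.0, 1.0, n_pre - half)[1:]:  # phase B: straighten
        frames.append(bent_conf(s))
    return np.asarray(frames)


def _script_mousetrapping(n_pre: int = 16) -> np.ndarray:
    """Loop region concertedly rotated over a quasi-static terminus.

    The final state carries long straight extensions on both ends so the
    resulting knot core is interior (the entrapped terminus protrudes well
    beyond it).  Only the loop segment moves.
    """
    base = _mechanism_base(n=56, tail=8)
    n0 = len(base)
    # extend both termini so the core is > 10 residues from either end
    dN = base[0] - base[2]
    dN /= np.linalg.norm(dN)
    extN = base[0] + np.outer(np.arange(12, 0, -1) * CA_BOND, dN)
    dC = base[-1] - base[-3]
    dC /= np.linalg.norm(dC)
    extC = base[-1] + np.outer(np.arange(1, 13) * CA_BOND, dC)
    final = np.vstack([extN, base, extC])
    n = len(final)
    from .knots import chain_is_knotted, locate_core
    core = locate_core(final)
    a, b = core.start - 1, core.end - 1        # 0-based
    loop = np.arange(a, min(b + 1, n - 16))    # loop region, away from C tail
    hinge = final[loop[0]]

    def rotated(angle: float, axis: np.ndarray) -> np.ndarray:
        fr = final.copy()
        c, s = math.cos(angle), math.sin(angle)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + s * K + (1 - c) * (K @ K)
        fr[loop] = (final[loop] - hinge) @ R.T + hinge
        return fr

    # deterministic search for a hinge axis/angle that unknots the chain
    chosen = None
    for ax in (np.array([1.0, 0, 0]), np.array([0, 1.0, 0]),
               np.array([0, 0, 1.0]),
               np.array([1.0, 1.0, 0]) / math.sqrt(2)):
        for ang in (math.pi / 2, 2 * math.pi / 3, math.pi / 3, math.pi):
            if not chain_is_knotted(rotated(ang, ax)):
                chosen = (ang, ax)
                break
        if chosen:
            break
    if chosen is None:
        raise RuntimeError("no unknotting rotation found")
    ang0, ax0 = chosen
    frames = [rotated((1.0 - tau) * ang0, ax0)
              for tau in np.linspace(0.0, 1.0, n_pre)]
    return np.asarray(frames)
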