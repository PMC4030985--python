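"""Geometric and thermodynamic trajectory analysis.

Optimal-superposition RMSD (whole chain or substructures), 2-D pathway
projections, free-energy surfaces from sampled densities, secondary-
structure-resolved native-contact statistics, terminus non-native
attraction, and two-pathway probabilities from barrier differences
(Kramers with equal prefactors).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .ratchet import native_fraction
from .structure import NativeContactMap

logger = logging.getLogger(__name__)


def kabsch_rmsd(conf_a, conf_b, subset=None) -> float:
    """RMSD after optimal proper-rotation superposition of a residue subset.

    ``subset``: iterable of 0-based bead indices (default: all beads).
    Raises on degenerate (collinear) subsets, whose superposition is
    ill-conditioned.
    """
    a = np.asarray(conf_a, dtype=float)
    b = np.asarray(conf_b, dtype=float)
    if subset is not None:
        subset = np.asarray(subset, dtype=int)
        a, b = a[subset], b[subset]
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("subsets must match and contain >= 3 points")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    def _collinear(pts):
        sv = np.linalg.svd(pts.T @ pts)[1]
        return sv[1] < 1e-9 * max(sv[0], 1e-300)

    # the optimal rotation is non-unique if either set is collinear, but
    # the minimum RMSD value is still unique unless both are
    if _collinear(a) and _collinear(b):
        raise ValueError(
            "degenerate (collinear) subset: RMSD superposition is "
            "ill-defined for this selection"
        )
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")   # rank-deficient sets warn in scipy
        rot, _ = Rotation.align_vectors(a, b)  # proper rotation only
    diff = a - rot.apply(b)
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def project_trajectory(trajectory, coord_a_def, coord_b_def, native,
                       knot_flags=None):
    """Project frames onto two RMSD-to-native coordinates.

    ``coord_*_def``: 0-based residue-index arrays defining each
    substructure; ``native``: reference coordinates.  Returns an (m, 2)
    array; knotting-event frames can be flagged via ``knot_flags``.
    """
    native = np.asarray(native, dtype=float)
    path = np.array([
        [kabsch_rmsd(fr, native, coord_a_def),
         kabsch_rmsd(fr, native, coord_b_def)]
        for fr in trajectory.frames
    ])
    if knot_flags is not None:
        return path, np.asarray(knot_flags, dtype=bool)
    return path


@dataclass
class FESGrid:
    """Two-coordinate free-energy surface, F = −kBT·ln(p), min-shifted to 0.

    Empty bins are masked (NaN), not zero-filled.  ``contour_interval``
    is cosmetic metadata for plotting."""

    edges_a: np.ndarray
    edges_b: np.ndarray
    free_energy: np.ndarray      # (na, nb), NaN where unsampled
    kBT: float
    contour_interval: float = 0.8


def fes_2d(samples, grid_spec, kBT: float = 1.0,
           contour_interval: float = 0.8) -> FESGrid:
    """Histogram-based 2-D free-energy surface.

    ``samples``: (m, 2) array of coordinate pairs; ``grid_spec``: number
    of bins (int) or (edges_a, edges_b).
    """
    s = np.asarray(samples, dtype=float).reshape(-1, 2)
    if len(s) < 1:
        raise ValueError("need at least one sample")
    if isinstance(grid_spec, int):
        H, ea, eb = np.histogram2d(s[:, 0], s[:, 1], bins=grid_spec)
    else:
        ea, eb = grid_spec
        H, ea, eb = np.histogram2d(s[:, 0], s[:, 1], bins=(ea, eb))
    if np.count_nonzero(H) == 1:
        logger.warning("all samples fall in a single bin")
    with np.errstate(divide="ignore"):
        F = -kBT * np.log(H / H.sum())
    F[H == 0] = np.nan
    F -= np.nanmin(F)
    return FESGrid(edges_a=ea, edges_b=eb, free_energy=F, kBT=kBT,
                   contour_interval=contour_interval)


@dataclass
class ContactStats:
    """Formed-fraction of native contacts, overall and per ss_class.

    Classes with no native pairs report ``None`` (undefined), never 0."""

    overall: float
    alpha: float | None
    beta: float | None
    other: float | None
    n_pairs: dict


def ss_contact_fractions(conformation, contact_map: NativeContactMap,
                         tolerance_factor: float = 1.2) -> ContactStats:
    """Per-secondary-structure-class native-contact formation, with the
    same contact criterion as the reaction coordinate Q."""
    x = np.asarray(conformation, dtype=float)
    p = contact_map.pairs
    r = np.linalg.norm(x[p[:, 0]] - x[p[:, 1]], axis=1)
    formed = r <= tolerance_factor * contact_map.native_distance
    out = {}
    counts = {}
    for cls in ("alpha", "beta", "other"):
        m = contact_map.class_mask(cls)
        counts[cls] = int(np.sum(m))
        out[cls] = float(np.mean(formed[m])) if counts[cls] else None
    return ContactStats(
        overall=float(np.mean(formed)),
        alpha=out["alpha"], beta=out["beta"], other=out["other"],
        n_pairs=counts,
    )


def terminus_attraction(conformation_ensemble, trace, qc_params,
                        terminus_length: int, min_seq_sep: int = 3,
                        terminus: str = "C"):
    """Mean non-native (quasi-chemical) interaction energy between the
    terminal segment and the rest of the chain, over an ensemble.

    All sampled structures enter the average irrespective of compactness.
    Returns (mean, standard_error).
    """
    from .forcefield import PotentialEnergyModel
    from .structure import build_contact_map

    n = trace.n_beads
    if terminus_length >= n:
        raise ValueError("terminus_length must be < chain length")
    cmap = build_contact_map(trace, min_seq_sep=min_seq_sep)
    model = PotentialEnergyModel(trace, cmap, qc_params=qc_params)
    if terminus == "C":
        tset = set(range(n - terminus_length, n))
    else:
        tset = set(range(terminus_length))
    pairs = model.nonnative_pairs
    in_t = np.array([(i in tset) != (j in tset) for i, j in pairs])
    sel = np.nonzero(in_t)[0]

    vals = []
    for x in conformation_ensemble:
        vals.append(model._qc_e(np.asarray(x, dtype=float), sel))
    vals = np.asarray(vals)
    se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return float(vals.mean()), se


def pathway_probability_from_barriers(delta_F_barrier_1: float,
                                      delta_F_barrier_2: float,
                                      kBT: float = 1.0):
    """Two-pathway splitting probabilities from transition-state barrier
    heights, assuming equal Kramers prefactors (logged: this neglects any
    difference in diffusive prefactor between the pathways)."""
    if not (np.isfinite(delta_F_barrier_1) and np.isfinite(delta_F_barrier_2)):
        raise ValueError("barriers must be finite")
    logger.info("pathway probabilities assume equal Kramers prefactors")
    r = np.exp(-(delta_F_barrier_1 - delta_F_barrier_2) / kBT)
    p1 = r / (1.0 + r)
    return float(p1), float(1.0 - p1)
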