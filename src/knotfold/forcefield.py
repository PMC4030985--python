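"""Coarse-grained Cα potential: native-centric (Gō) terms plus an optional
quasi-chemical non-native contact term.

The Gō part keeps the native structure at the energy minimum: stiff bonds,
angles and dihedrals restrained to their native values, a 12-10 well per
native contact, and excluded volume for everything else.  The non-native
term adds sequence-dependent contact energies (relative pairing
propensities) on the pairs that are *not* native, scaled by ``lambda_nn``;
``lambda_nn = 0`` recovers the pure native-centric model bitwise.

Reduced units: the native-contact well depth ε sets the energy scale
(temperatures are quoted in ε/k_B); lengths are Å.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .structure import AA1, CaTrace, NativeContactMap

_TWO_PI = 2.0 * math.pi


@dataclass
class GoModelParams:
    """Stiffnesses and well parameters of the native-centric terms.

    Defaults follow the common Cα Gō parameterization: V_bond = k_b(r−r0)²
    with k_b = 100 ε/Å², V_angle = k_a(θ−θ0)² with k_a = 20 ε/rad²,
    periodic dihedrals k1[1−cos(φ−φ0)] + k3[1−cos3(φ−φ0)] with (1, 0.5) ε,
    a 12-10 native well ε[5(r0/r)¹²−6(r0/r)¹⁰] and (σ/r)¹² repulsion with
    σ = 4 Å on non-native pairs.
    """

    bond_k: float = 100.0
    angle_k: float = 20.0
    dihedral_k1: float = 1.0
    dihedral_k3: float = 0.5
    epsilon_native: float = 1.0
    sigma_rep: float = 4.0
    epsilon_rep: float = 1.0

    def __post_init__(self) -> None:
        for name in ("bond_k", "angle_k", "dihedral_k1", "dihedral_k3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.epsilon_native <= 0 or self.sigma_rep <= 0:
            raise ValueError("epsilon_native and sigma_rep must be positive")


@dataclass
class QuasiChemicalParams:
    """Non-native contact term parameters.

    ``contact_energy`` is a symmetric 20×20 matrix of dimensionless pair
    propensities (alphabetical one-letter order), scaled by ``lambda_nn``.
    A cosine switching function takes the interaction smoothly to zero
    between ``nn_cutoff − switching_width`` and ``nn_cutoff``.
    ``attractive_only`` keeps only negative (attractive) entries, the
    default reading of the term as an overall residue attraction.
    """

    contact_energy: np.ndarray | None = None
    lambda_nn: float = 1.0
    nn_cutoff: float = 7.5
    switching_width: float = 1.5
    attractive_only: bool = True

    def __post_init__(self) -> None:
        if self.lambda_nn < 0:
            raise ValueError("lambda_nn must be >= 0")
        if self.contact_energy is None:
            self.contact_energy = load_contact_matrix()
        self.contact_energy = np.asarray(self.contact_energy, dtype=float)
        if self.contact_energy.shape != (20, 20):
            raise ValueError("contact_energy must be 20x20")
        if not np.allclose(self.contact_energy, self.contact_energy.T):
            raise ValueError("contact_energy must be symmetric")


def load_contact_matrix() -> np.ndarray:
    """Load the packaged contact-propensity matrix (see data file header
    for provenance; it is a synthetic hydropathy-derived surrogate)."""
    text = resources.files("knotfold.data").joinpath(
        "qc_contact_matrix.tsv"
    ).read_text()
    rows = []
    for line in text.splitlines():
        if line.startswith("#") or not line.strip():
            continue
        parts = line.split("\t")
        if parts[0] == "":
            order = parts[1:]
            continue
        rows.append([float(v) for v in parts[1:]])
    mat = np.asarray(rows)
    # reorder to canonical AA1 order if needed
    idx = [order.index(a) for a in AA1]
    return mat[np.ix_(idx, idx)]


def _angles(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    u = x[idx[:, 0]] - x[idx[:, 1]]
    v = x[idx[:, 2]] - x[idx[:, 1]]
    c = np.einsum("ij,ij->i", u, v) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    )
    return np.arccos(np.clip(c, -1.0, 1.0))


def _dihedrals(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    b1 = x[idx[:, 1]] - x[idx[:, 0]]
    b2 = x[idx[:, 2]] - x[idx[:, 1]]
    b3 = x[idx[:, 3]] - x[idx[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=1)[:, None]
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2n)
    c = np.einsum("ij,ij->i", n1, n2)
    return np.arctan2(y, c)


class PotentialEnergyModel:
    """Composable Cα potential with analytic forces.

    Built from a native :class:`CaTrace` and its contact map; evaluates
    total energy, the 3n-component force F = −∇V, and fast energy
    differences for Monte Carlo moves (only terms touching moved beads are
    recomputed).
    """

    def __init__(
        self,
        trace: CaTrace,
        contact_map: NativeContactMap,
        go_params: GoModelParams | None = None,
        qc_params: QuasiChemicalParams | None = None,
    ) -> None:
        self.trace = trace
        self.contact_map = contact_map
        self.go = go_params or GoModelParams()
        self.qc = qc_params  # None -> pure native-centric model
        x0 = trace.positions
        n = self.n_beads = len(x0)
        if n < 4:
            raise ValueError("need at least 4 beads")

        self.bond_idx = np.stack([np.arange(n - 1), np.arange(1, n)], axis=1)
        self.bond_r0 = np.linalg.norm(np.diff(x0, axis=0), axis=1)
        self.angle_idx = np.stack(
            [np.arange(n - 2), np.arange(1, n - 1), np.arange(2, n)], axis=1
        )
        self.angle_t0 = _angles(x0, self.angle_idx)
        self.dihedral_idx = np.stack(
            [np.arange(n - 3), np.arange(1, n - 2), np.arange(2, n - 1),
             np.arange(3, n)], axis=1
        )
        self.dihedral_p0 = _dihedrals(x0, self.dihedral_idx)

        self.native_pairs = contact_map.pairs
        self.native_r0 = contact_map.native_distance

        # non-native pair list: all j - i >= min_seq_sep not in the map
        sep = contact_map.min_seq_sep
        ii, jj = np.triu_indices(n, k=sep)
        native_set = set(map(tuple, self.native_pairs.tolist()))
        mask = np.array(
            [(i, j) not in native_set for i, j in zip(ii.tolist(), jj.tolist())]
        )
        self.nonnative_pairs = np.stack([ii[mask], jj[mask]], axis=1)

        if self.qc is not None:
            aa_idx = np.array([AA1.index(a) if a in AA1 else AA1.index("A")
                               for a in trace.residue_type])
            e = self.qc.contact_energy[
                aa_idx[self.nonnative_pairs[:, 0]], aa_idx[self.nonnative_pairs[:, 1]]
            ]
            if self.qc.attractive_only:
                e = np.minimum(e, 0.0)
            self.nn_e = e
        else:
            self.nn_e = None

        self._build_adjacency()

    # -- adjacency for incremental MC energies --------------------------------
    def _build_adjacency(self) -> None:
        n = self.n_beads
        self._touch = {}
        for name, idx in (
            ("bond", self.bond_idx),
            ("angle", self.angle_idx),
            ("dihedral", self.dihedral_idx),
            ("native", self.native_pairs),
            ("nonnative", self.nonnative_pairs),
        ):
            by_bead = [[] for _ in range(n)]
            for t, beads in enumerate(idx):
                for b in beads:
                    by_bead[b].append(t)
            self._touch[name] = [np.array(v, dtype=int) for v in by_bead]

    def _terms_touching(self, name: str, moved: np.ndarray) -> np.ndarray:
        lists = self._touch[name]
        parts = [lists[b] for b in moved]
        if not parts:
            return np.empty(0, dtype=int)
        return np.unique(np.concatenate(parts))

    # -- energy terms ---------------------------------------------------------
    def _bond_e(self, x, sel=slice(None)):
        idx, r0 = self.bond_idx[sel], self.bond_r0[sel]
        r = np.linalg.norm(x[idx[:, 0]] - x[idx[:, 1]], axis=1)
        return float(self.go.bond_k * np.sum((r - r0) ** 2))

    def _angle_e(self, x, sel=slice(None)):
        idx, t0 = self.angle_idx[sel], self.angle_t0[sel]
        if len(idx) == 0:
            return 0.0
        t = _angles(x, idx)
        return float(self.go.angle_k * np.sum((t - t0) ** 2))

    def _dihedral_e(self, x, sel=slice(None)):
        idx, p0 = self.dihedral_idx[sel], self.dihedral_p0[sel]
        if len(idx) == 0:
            return 0.0
        dp = _dihedrals(x, idx) - p0
        k1, k3 = self.go.dihedral_k1, self.go.dihedral_k3
        return float(np.sum(k1 * (1 - np.cos(dp)) + k3 * (1 - np.cos(3 * dp))))

    def _native_e(self, x, sel=slice(None)):
        idx, r0 = self.native_pairs[sel], self.native_r0[sel]
        if len(idx) == 0:
            return 0.0
        r = np.linalg.norm(x[idx[:, 0]] - x[idx[:, 1]], axis=1)
        q = r0 / r
        eps = self.go.epsilon_native
        return float(eps * np.sum(5 * q**12 - 6 * q**10))

    def _rep_e(self, x, sel=slice(None)):
        idx = self.nonnative_pairs[sel]
        if len(idx) == 0:
            return 0.0
        r = np.linalg.norm(x[idx[:, 0]] - x[idx[:, 1]], axis=1)
        s = self.go.sigma_rep / r
        return float(self.go.epsilon_rep * np.sum(s**12))

    def _switch(self, r):
        qc = self.qc
        r_on = qc.nn_cutoff - qc.switching_width
        s = np.zeros_like(r)
        s[r <= r_on] = 1.0
        mid = (r > r_on) & (r < qc.nn_cutoff)
        s[mid] = 0.5 * (1 + np.cos(math.pi * (r[mid] - r_on) / qc.switching_width))
        return s

    def _qc_e(self, x, sel=slice(None)):
        if self.qc is None or self.qc.lambda_nn == 0.0:
            return 0.0
        idx, e = self.nonnative_pairs[sel], self.nn_e[sel]
        if len(idx) == 0:
            return 0.0
        r = np.linalg.norm(x[idx[:, 0]] - x[idx[:, 1]], axis=1)
        return float(self.qc.lambda_nn * np.sum(e * self._switch(r)))

    # -- public API -----------------------------------------------------------
    def go_energy(self, x: np.ndarray) -> float:
        """Native-centric part only (bonded + native wells + repulsion)."""
        x = self._check(x)
        return (
            self._bond_e(x) + self._angle_e(x) + self._dihedral_e(x)
            + self._native_e(x) + self._rep_e(x)
        )

    def nonnative_energy(self, x: np.ndarray) -> float:
        """Quasi-chemical non-native term; exactly 0 when lambda_nn = 0."""
        x = self._check(x)
        return self._qc_e(x)

    def energy(self, x: np.ndarray) -> float:
        x = self._check(x)
        return self.go_energy(x) + self._qc_e(x)

    def delta_energy(self, x: np.ndarray, moved: np.ndarray,
                     x_new: np.ndarray) -> float:
        """Energy difference if beads ``moved`` take positions from
        ``x_new`` (full-size array); only affected terms are evaluated."""
        moved = np.asarray(moved, dtype=int)
        de = 0.0
        for name, fn in (
            ("bond", self._bond_e), ("angle", self._angle_e),
            ("dihedral", self._dihedral_e), ("native", self._native_e),
            ("nonnative", self._rep_e),
        ):
            sel = self._terms_touching(name, moved)
            if len(sel):
                de += fn(x_new, sel) - fn(x, sel)
        if self.qc is not None and self.qc.lambda_nn != 0.0:
            sel = self._terms_touching("nonnative", moved)
            if len(sel):
                de += self._qc_e(x_new, sel) - self._qc_e(x, sel)
        return de

    def energy_and_force(self, x: np.ndarray):
        """Total energy and the analytic force F = −∇V, shape (n, 3)."""
        x = self._check(x)
        f = np.zeros_like(x)
        e = 0.0

        # bonds
        idx, r0 = self.bond_idx, self.bond_r0
        d = x[idx[:, 0]] - x[idx[:, 1]]
        r = np.linalg.norm(d, axis=1)
        e += self.go.bond_k * np.sum((r - r0) ** 2)
        g = (2 * self.go.bond_k * (r - r0) / r)[:, None] * d  # dV/dx_i
        np.add.at(f, idx[:, 0], -g)
        np.add.at(f, idx[:, 1], g)

        # angles
        idx, t0 = self.angle_idx, self.angle_t0
        if len(idx):
            u = x[idx[:, 0]] - x[idx[:, 1]]
            v = x[idx[:, 2]] - x[idx[:, 1]]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            uh, vh = u / nu[:, None], v / nv[:, None]
            c = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
            t = np.arccos(c)
            s = np.sqrt(np.maximum(1 - c**2, 1e-12))
            e += self.go.angle_k * np.sum((t - t0) ** 2)
            dV = 2 * self.go.angle_k * (t - t0)
            gi = ((c[:, None] * uh - vh) / (nu * s)[:, None]) * dV[:, None]
            gk = ((c[:, None] * vh - uh) / (nv * s)[:, None]) * dV[:, None]
            np.add.at(f, idx[:, 0], -gi)
            np.add.at(f, idx[:, 2], -gk)
            np.add.at(f, idx[:, 1], gi + gk)

        # dihedrals
        idx, p0 = self.dihedral_idx, self.dihedral_p0
        if len(idx):
            b1 = x[idx[:, 1]] - x[idx[:, 0]]
            b2 = x[idx[:, 2]] - x[idx[:, 1]]
            b3 = x[idx[:, 3]] - x[idx[:, 2]]
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            nb2 = np.linalg.norm(b2, axis=1)
            y = np.einsum("ij,ij->i", np.cross(n1, n2), b2 / nb2[:, None])
            cphi = np.einsum("ij,ij->i", n1, n2)
            phi = np.arctan2(y, cphi)
            dp = phi - p0
            k1, k3 = self.go.dihedral_k1, self.go.dihedral_k3
            e += np.sum(k1 * (1 - np.cos(dp)) + k3 * (1 - np.cos(3 * dp)))
            dV = k1 * np.sin(dp) + 3 * k3 * np.sin(3 * dp)
            n1sq = np.einsum("ij,ij->i", n1, n1)
            n2sq = np.einsum("ij,ij->i", n2, n2)
            # collinear triples leave the dihedral undefined; its gradient
            # is taken as zero there
            bad = (n1sq < 1e-12) | (n2sq < 1e-12)
            dV = np.where(bad, 0.0, dV)
            n1sq = np.where(bad, 1.0, n1sq)
            n2sq = np.where(bad, 1.0, n2sq)
            dphi1 = -(nb2 / n1sq)[:, None] * n1
            dphi4 = (nb2 / n2sq)[:, None] * n2
            a1 = (np.einsum("ij,ij->i", b1, b2) / nb2**2)
            a3 = (np.einsum("ij,ij->i", b3, b2) / nb2**2)
            dphi2 = -(1 + a1)[:, None] * dphi1 + a3[:, None] * dphi4
            dphi3 = a1[:, None] * dphi1 - (1 + a3)[:, None] * dphi4
            np.add.at(f, idx[:, 0], -dV[:, None] * dphi1)
            np.add.at(f, idx[:, 1], -dV[:, None] * dphi2)
            np.add.at(f, idx[:, 2], -dV[:, None] * dphi3)
            np.add.at(f, idx[:, 3], -dV[:, None] * dphi4)

        # native 12-10 wells
        idx, r0 = self.native_pairs, self.native_r0
        if len(idx):
            d = x[idx[:, 0]] - x[idx[:, 1]]
            r = np.linalg.norm(d, axis=1)
            q = r0 / r
            eps = self.go.epsilon_native
            e += eps * np.sum(5 * q**12 - 6 * q**10)
            dVdr = (60 * eps / r) * (q**10 - q**12)
            g = (dVdr / r)[:, None] * d
            np.add.at(f, idx[:, 0], -g)
            np.add.at(f, idx[:, 1], g)

        # excluded volume + quasi-chemical on non-native pairs
        idx = self.nonnative_pairs
        if len(idx):
            d = x[idx[:, 0]] - x[idx[:, 1]]
            r = np.linalg.norm(d, axis=1)
            s = self.go.sigma_rep / r
            e += self.go.epsilon_rep * np.sum(s**12)
            dVdr = -12 * self.go.epsilon_rep * s**12 / r
            if self.qc is not None and self.qc.lambda_nn != 0.0:
                lam, w = self.qc.lambda_nn, self.qc.switching_width
                r_on = self.qc.nn_cutoff - w
                sw = self._switch(r)
                e += lam * np.sum(self.nn_e * sw)
                dsw = np.zeros_like(r)
                mid = (r > r_on) & (r < self.qc.nn_cutoff)
                dsw[mid] = -0.5 * math.pi / w * np.sin(
                    math.pi * (r[mid] - r_on) / w
                )
                dVdr = dVdr + lam * self.nn_e * dsw
            g = (dVdr / r)[:, None] * d
            np.add.at(f, idx[:, 0], -g)
            np.add.at(f, idx[:, 1], g)

        return float(e), f

    def force(self, x: np.ndarray) -> np.ndarray:
        return self.energy_and_force(x)[1]

    @staticmethod
    def _check(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite coordinates")
        return x


def go_energy(conformation, trace, contact_map, params=None) -> float:
    """Functional wrapper: native-centric energy of a conformation."""
    m = PotentialEnergyModel(trace, contact_map, go_params=params)
    if np.shape(conformation) != trace.positions.shape:
        raise ValueError("conformation bead count does not match trace")
    return m.go_energy(np.asarray(conformation, dtype=float))


def nonnative_energy(conformation, trace, contact_map, qc_params) -> float:
    """Functional wrapper: quasi-chemical non-native energy."""
    m = PotentialEnergyModel(trace, contact_map, qc_params=qc_params)
    if np.shape(conformation) != trace.positions.shape:
        raise ValueError("conformation bead count does not match trace")
    return m.nonnative_energy(np.asarray(conformation, dtype=float))


def total_energy_and_force(conformation, model: PotentialEnergyModel):
    """Energy and 3n-component force vector of the full model."""
    return model.energy_and_force(conformation)
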