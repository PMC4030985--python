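"""Ratchet-and-pawl biasing along the fraction of native contacts, the
Onsager–Machlup path action, and dominant-pathway selection.

The bias leaves the dynamics untouched whenever the fraction of native
contacts Q increases; when Q falls below its running maximum q_rec the
penalty ½·k·(q_rec − Q)² discourages regression, so thermal fluctuations
ratchet the chain toward the native state.  Trajectory probabilities are
ranked by the Onsager–Machlup action

    S_OM = Γ/(4·kBT·Δt) · Σ_i (x_{i+1} − x_i − F(x_i)·Δt/Γ)²

evaluated with the *unbiased* force only (Γ = m_eff·γ); within an ensemble
of trials sharing an initial state, the member with the lowest action is
the dominant (least-biased, most probable) pathway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .samplers import LangevinParams, MoveSet, Trajectory, run_sampler
from .structure import NativeContactMap

logger = logging.getLogger(__name__)


def native_fraction(conformation, contact_map: NativeContactMap,
                    tolerance_factor: float = 1.2) -> float:
    """Sharp-count Q: fraction of native pairs with current distance within
    tolerance_factor × native distance."""
    if contact_map.n_pairs == 0:
        raise ValueError("empty contact map: Q is undefined")
    x = np.asarray(conformation, dtype=float)
    p = contact_map.pairs
    r = np.linalg.norm(x[p[:, 0]] - x[p[:, 1]], axis=1)
    return float(np.mean(r <= tolerance_factor * contact_map.native_distance))


def smooth_native_fraction(conformation, contact_map: NativeContactMap,
                           tolerance_factor: float = 1.2,
                           alpha: float = 5.0):
    """Differentiable surrogate of Q (sigmoid contact counting) and its
    gradient wrt coordinates; used for the Langevin-engine bias force."""
    x = np.asarray(conformation, dtype=float)
    p = contact_map.pairs
    d = x[p[:, 0]] - x[p[:, 1]]
    r = np.linalg.norm(d, axis=1)
    t = alpha * (r - tolerance_factor * contact_map.native_distance)
    sig = 1.0 / (1.0 + np.exp(np.clip(t, -40, 40)))
    m = contact_map.n_pairs
    q = float(np.sum(sig) / m)
    dsig_dr = -alpha * sig * (1 - sig) / m
    g = np.zeros_like(x)
    gpair = (dsig_dr / r)[:, None] * d
    np.add.at(g, p[:, 0], gpair)
    np.add.at(g, p[:, 1], -gpair)
    return q, g


@dataclass
class RatchetState:
    """Pawl state: best Q reached so far and the bias stiffness."""

    q_record: float = 0.0
    k_ratchet: float = 0.0

    def __post_init__(self) -> None:
        if self.k_ratchet < 0:
            raise ValueError("k_ratchet must be >= 0")


def ratchet_bias(conformation, contact_map: NativeContactMap,
                 state: RatchetState, tolerance_factor: float = 1.2):
    """One bias evaluation: returns (bias_energy, bias_force, new_state).

    Energy uses the sharp Q exactly: 0 at or above the record (pawl
    engaged only on regression), ½·k·(q_rec − Q)² below it.  The force
    direction comes from the smoothed-Q gradient (the sharp count has a
    vanishing gradient almost everywhere).
    """
    q = native_fraction(conformation, contact_map, tolerance_factor)
    x = np.asarray(conformation, dtype=float)
    if q >= state.q_record:
        return 0.0, np.zeros_like(x), RatchetState(q, state.k_ratchet)
    delta = state.q_record - q
    energy = 0.5 * state.k_ratchet * delta**2
    _, gq = smooth_native_fraction(x, contact_map, tolerance_factor)
    force = state.k_ratchet * delta * gq
    return energy, force, RatchetState(state.q_record, state.k_ratchet)


class RatchetBias:
    """Stateful ratchet for the sampling engines.

    MC uses :meth:`delta_energy` per proposal; Langevin uses :meth:`force`.
    :meth:`commit` advances the pawl after an accepted/realized move.
    """

    def __init__(self, contact_map: NativeContactMap, k_ratchet: float,
                 tolerance_factor: float = 1.2, q_record: float = 0.0):
        self.contact_map = contact_map
        self.tolerance_factor = tolerance_factor
        self.state = RatchetState(q_record=q_record, k_ratchet=k_ratchet)

    def _energy_of_q(self, q: float) -> float:
        if q >= self.state.q_record:
            return 0.0
        return 0.5 * self.state.k_ratchet * (self.state.q_record - q) ** 2

    def q(self, x) -> float:
        return native_fraction(x, self.contact_map, self.tolerance_factor)

    def delta_energy(self, x, x_new) -> float:
        return self._energy_of_q(self.q(x_new)) - self._energy_of_q(self.q(x))

    def force(self, x) -> np.ndarray:
        e, f, _ = ratchet_bias(x, self.contact_map, self.state,
                               self.tolerance_factor)
        return f

    def commit(self, x) -> None:
        q = self.q(x)
        if q > self.state.q_record:
            self.state = RatchetState(q, self.state.k_ratchet)


def run_rmd(
    initial,
    model,
    contact_map: NativeContactMap,
    *,
    k_ratchet: float = 500.0,
    q_stop: float = 1.01,
    engine: str = "mc",
    n_steps: int = 2000,
    stride: int = 10,
    kBT: float = 1.0,
    tolerance_factor: float = 1.2,
    seed: int = 0,
    moveset: MoveSet | None = None,
    langevin_params: LangevinParams | None = None,
    knot_flags: bool = False,
) -> Trajectory:
    """Ratchet-and-pawl run: model dynamics plus the one-sided Q bias.

    The initial conformation's knotted state is checked and logged (the
    folding protocol requires unknotted starts).  Per-frame logs include
    Q, the running record q_record and the bias energy.
    """
    from .knots import chain_is_knotted

    x0 = np.asarray(initial, dtype=float)
    if chain_is_knotted(x0):
        logger.warning("run_rmd: initial conformation is knotted")
    bias = RatchetBias(contact_map, k_ratchet, tolerance_factor)
    bias.commit(x0)
    traj = run_sampler(
        x0, model, engine,
        n_steps=n_steps, stride=stride, kBT=kBT, seed=seed,
        moveset=moveset, langevin_params=langevin_params,
        contact_map=contact_map, bias=bias, q_stop=q_stop,
        knot_flags=knot_flags,
    )
    q = traj.scalars["Q"]
    traj.scalars["q_record"] = np.maximum.accumulate(q)
    traj.scalars["bias_energy"] = np.where(
        q >= traj.scalars["q_record"], 0.0,
        0.5 * k_ratchet * (traj.scalars["q_record"] - q) ** 2,
    )
    return traj


def om_action(trajectory: Trajectory, unbiased_force_fn,
              params: LangevinParams) -> float:
    """Onsager–Machlup action of a stride-1 trajectory under the unbiased
    force.  Refuses strides > 1: subsampled paths cannot be rescaled into
    the discrete action without changing its value."""
    if trajectory.stride != 1:
        raise ValueError(
            f"om_action requires stride-1 frames (got stride="
            f"{trajectory.stride}); re-run with stride=1 to rank this path"
        )
    dt, Gamma, kBT = params.dt, params.Gamma, params.kBT
    pref = Gamma / (4.0 * kBT * dt)
    s = 0.0
    frames = trajectory.frames
    for i in range(len(frames) - 1):
        f = np.asarray(unbiased_force_fn(frames[i]))
        resid = frames[i + 1] - frames[i] - f * dt / Gamma
        s += float(np.sum(resid**2))
    return pref * s


@dataclass
class PathEnsemble:
    """Trial trajectories sharing one initial condition, with their
    Onsager–Machlup actions and the selected dominant member."""

    group_key: str
    members: list[Trajectory]
    actions: np.ndarray | None = None
    dominant_index: int | None = None

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValueError("a path ensemble needs >= 1 member")
        if self.actions is not None:
            self.actions = np.asarray(self.actions, dtype=float)


def score_ensemble(ensemble: PathEnsemble, unbiased_force_fn,
                   params: LangevinParams) -> PathEnsemble:
    """Compute the unbiased-force action of every member."""
    ensemble.actions = np.asarray([
        om_action(t, unbiased_force_fn, params) for t in ensemble.members
    ])
    return ensemble


def select_dominant(ensemble: PathEnsemble) -> PathEnsemble:
    """Pick the lowest-action member; ties go to the lowest index."""
    if ensemble.actions is None:
        raise ValueError("ensemble has no actions; score it first")
    a = ensemble.actions
    best = int(np.argmin(a))  # argmin returns the first minimum on ties
    if np.sum(a == a[best]) > 1:
        logger.info("action tie in %s: keeping member %d",
                    ensemble.group_key, best)
    ensemble.dominant_index = best
    return ensemble
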