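"""Stochastic dynamics engines: overdamped Langevin and Metropolis Monte
Carlo with local moves (crankshaft rotations and single-bead displacements).

The Langevin propagator is the discrete overdamped update

    x_{i+1} = x_i + (Δt·D/k_BT)·F(x_i) + sqrt(2·D·Δt)·η_i

with η_i unit-variance Gaussian noise.  The MC engine uses local moves
only, so its sweep axis is a proxy for overdamped polymer dynamics; one
sweep is n proposals for an n-bead chain.  Both engines are bit
reproducible given (initial state, parameters, seed).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

ENERGY_DIVERGENCE_LIMIT = 1e8


class PropagationError(RuntimeError):
    pass


@dataclass
class LangevinParams:
    """Overdamped Langevin parameters in reduced units.

    The effective friction Γ = m_eff·gamma links the propagator to the
    path-action drift term F·Δt/Γ; consistency D = kBT/Γ is enforced at
    construction (supply any two of D / kBT / Γ-parts).
    """

    kBT: float = 1.0
    dt: float = 1e-3
    gamma: float = 1.0
    m_eff: float = 1.0
    D: float | None = None
    n_steps: int = 0

    def __post_init__(self) -> None:
        if min(self.kBT, self.dt, self.gamma, self.m_eff) <= 0:
            raise ValueError("kBT, dt, gamma, m_eff must be positive")
        Gamma = self.m_eff * self.gamma
        if self.D is None:
            self.D = self.kBT / Gamma
        elif abs(self.D * Gamma / self.kBT - 1.0) > 1e-9:
            raise ValueError(
                "inconsistent parameters: require D = kBT/(m_eff*gamma)"
            )

    @property
    def Gamma(self) -> float:
        return self.m_eff * self.gamma

    def check_stability(self, k_max: float) -> None:
        """Hard guard: dt·D·k_max/kBT must stay below 0.1."""
        if self.dt * self.D * k_max / self.kBT >= 0.1:
            raise ValueError(
                f"unstable time step: dt*D*k_max/kBT = "
                f"{self.dt * self.D * k_max / self.kBT:.3g} >= 0.1"
            )


@dataclass
class MoveSet:
    """MC move amplitudes: crankshaft rotations of 2–8 interior beads about
    the axis joining two anchor beads, and single-bead displacements."""

    crankshaft_max_angle: float = 0.3     # rad
    displacement_max: float = 0.10        # Å
    mix: float = 0.5                      # P(crankshaft)
    segment_range: tuple[int, int] = (2, 8)

    def __post_init__(self) -> None:
        if self.crankshaft_max_angle <= 0 or self.displacement_max <= 0:
            raise ValueError("move amplitudes must be positive")
        if not 0.0 <= self.mix <= 1.0:
            raise ValueError("mix must be in [0, 1]")


@dataclass
class Trajectory:
    """Time-ordered conformations with run metadata.

    ``frames`` has shape (m, n, 3); ``stride`` is the number of integration
    steps (or MC sweeps) between saved frames; per-frame scalar logs
    (energy, Q, ...) live in ``scalars``.
    """

    frames: np.ndarray
    stride: int
    seed: int | None
    temperature: float
    dt: float | None = None
    bias_record: np.ndarray | None = None
    scalars: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (m, n, 3)")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_beads(self) -> int:
        return self.frames.shape[1]

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError("a trajectory needs >= 2 frames")

    def times(self) -> np.ndarray:
        """Frame times in sweeps (MC) or steps (Langevin)."""
        return np.arange(self.n_frames) * self.stride


def langevin_step(x, force_fn, params: LangevinParams, rng) -> np.ndarray:
    """One overdamped Langevin update; deterministic given (x, rng state)."""
    x = np.asarray(x, dtype=float)
    f = np.asarray(force_fn(x), dtype=float)
    if f.shape != x.shape:
        raise PropagationError(
            f"force_fn returned shape {f.shape}, expected {x.shape}"
        )
    if not np.all(np.isfinite(f)):
        bad = np.nonzero(~np.isfinite(f))[0]
        raise PropagationError(f"non-finite force at component(s) {bad[:5]}")
    eta = rng.standard_normal(x.shape)
    return (
        x
        + (params.dt * params.D / params.kBT) * f
        + np.sqrt(2.0 * params.D * params.dt) * eta
    )


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def propose_move(x: np.ndarray, moveset: MoveSet, rng):
    """Generate one trial move; returns (x_new, moved_bead_indices)."""
    n = len(x)
    use_crank = rng.random() < moveset.mix
    if use_crank and n < 4:
        warnings.warn("chain too short for crankshaft; using single-bead move")
        use_crank = False
    x_new = x.copy()
    if use_crank:
        lo, hi = moveset.segment_range
        seg = int(rng.integers(lo, min(hi, n - 2) + 1))
        i = int(rng.integers(0, n - seg - 1))
        j = i + seg + 1
        axis = x[j] - x[i]
        if np.linalg.norm(axis) < 1e-9:
            axis = rng.standard_normal(3)
        angle = rng.uniform(-moveset.crankshaft_max_angle,
                            moveset.crankshaft_max_angle)
        R = _rotation_about_axis(axis, angle)
        moved = np.arange(i + 1, j)
        x_new[moved] = (x[moved] - x[i]) @ R.T + x[i]
    else:
        b = int(rng.integers(0, n))
        x_new[b] = x[b] + rng.uniform(
            -moveset.displacement_max, moveset.displacement_max, size=3
        )
        moved = np.array([b])
    return x_new, moved


def mc_step(conformation, energy_fn, moveset: MoveSet, kBT: float, rng):
    """One Metropolis step with a full-energy callable.

    ``energy_fn(x)`` must return the total energy.  Acceptance is
    min(1, exp(−ΔE/kBT)); a rejected proposal returns the input unchanged.
    """
    x = np.asarray(conformation, dtype=float)
    x_new, _ = propose_move(x, moveset, rng)
    de = energy_fn(x_new) - energy_fn(x)
    if _metropolis_accept(de, kBT, rng):
        return x_new, True
    return x, False


def _metropolis_accept(de: float, kBT: float, rng) -> bool:
    if de <= 0:
        rng.random()  # keep the RNG stream aligned across branches
        return True
    if kBT == 0:
        rng.random()
        return False
    return rng.random() < np.exp(-de / kBT)


class MCEngine:
    """Sweep-based Metropolis engine using incremental energies.

    ``model`` must expose ``delta_energy(x, moved, x_new)`` and ``energy``.
    An optional ``bias`` object (see :mod:`knotfold.ratchet`) contributes
    an extra energy difference per proposal.
    """

    def __init__(self, model, moveset: MoveSet | None = None,
                 kBT: float = 1.0, bias=None) -> None:
        self.model = model
        self.moveset = moveset or MoveSet()
        self.kBT = kBT
        self.bias = bias
        self.n_accepted = 0
        self.n_proposed = 0

    def sweep(self, x: np.ndarray, rng) -> np.ndarray:
        n = len(x)
        for _ in range(n):
            x_new, moved = propose_move(x, self.moveset, rng)
            de = self.model.delta_energy(x, moved, x_new)
            if self.bias is not None:
                de += self.bias.delta_energy(x, x_new)
            self.n_proposed += 1
            if _metropolis_accept(de, self.kBT, rng):
                if self.bias is not None:
                    self.bias.commit(x_new)
                x = x_new
                self.n_accepted += 1
        return x

    @property
    def acceptance(self) -> float:
        return self.n_accepted / max(self.n_proposed, 1)


def run_sampler(
    initial,
    model,
    engine_choice: str = "mc",
    *,
    n_steps: int = 1000,
    stride: int = 10,
    kBT: float = 1.0,
    seed: int = 0,
    moveset: MoveSet | None = None,
    langevin_params: LangevinParams | None = None,
    contact_map=None,
    bias=None,
    q_stop: float | None = None,
    knot_flags: bool = False,
) -> Trajectory:
    """Run MC (``n_steps`` sweeps) or Langevin (``n_steps`` steps) dynamics.

    Saves a frame every ``stride`` units (plus the final state), logging
    energy and — when ``contact_map`` is given — the fraction of native
    contacts Q.  Aborts on energy divergence, keeping the last good frame.
    """
    from .ratchet import native_fraction  # local import to avoid a cycle

    x = np.asarray(initial, dtype=float).copy()
    rng = np.random.default_rng(seed)
    frames, energies, qs, biases = [x.copy()], [], [], []

    if engine_choice == "mc":
        return _run_mc_fast(x, model, n_steps=n_steps, stride=stride,
                            kBT=kBT, seed=seed, moveset=moveset,
                            contact_map=contact_map, bias=bias,
                            q_stop=q_stop, knot_flags=knot_flags)
    if engine_choice == "mc_reference":
        engine = MCEngine(model, moveset=moveset, kBT=kBT, bias=bias)
        step_fn = lambda x: engine.sweep(x, rng)
    elif engine_choice == "langevin":
        lp = langevin_params or LangevinParams(kBT=kBT)
        if bias is not None:
            def step_fn(x):
                def total_force(y):
                    f = model.force(y)
                    fb = bias.force(y)
                    bias.commit(y)
                    return f + fb
                return langevin_step(x, total_force, lp, rng)
        else:
            step_fn = lambda x: langevin_step(x, model.force, lp, rng)
    else:
        raise ValueError(f"unknown engine {engine_choice!r}")

    def log_frame(x):
        e = model.energy(x)
        energies.append(e)
        if contact_map is not None:
            qs.append(native_fraction(x, contact_map))
        if bias is not None:
            biases.append(bias.state.q_record)
        return e

    e = log_frame(x)
    aborted = False
    for step in range(1, n_steps + 1):
        x = step_fn(x)
        if step % stride == 0 or step == n_steps:
            e = log_frame(x)
            if not np.isfinite(e) or abs(e) > ENERGY_DIVERGENCE_LIMIT:
                logger.error("energy divergence at step %d; aborting", step)
                aborted = True
                break
            frames.append(x.copy())
            if q_stop is not None and qs and qs[-1] >= q_stop:
                break

    traj = Trajectory(
        frames=np.asarray(frames),
        stride=stride,
        seed=seed,
        temperature=kBT,
        dt=(langevin_params.dt if engine_choice == "langevin"
            and langevin_params else None),
        bias_record=np.asarray(biases) if biases else None,
        scalars={"energy": np.asarray(energies[: len(frames)])},
    )
    if contact_map is not None:
        traj.scalars["Q"] = np.asarray(qs[: len(frames)])
    if knot_flags:
        from .knots import chain_is_knotted
        traj.scalars["knotted"] = np.asarray(
            [chain_is_knotted(f) for f in traj.frames]
        )
    traj.scalars["aborted"] = aborted
    return traj


def _run_mc_fast(x, model, *, n_steps, stride, kBT, seed, moveset,
                 contact_map, bias, q_stop, knot_flags) -> Trajectory:
    """Sweep-based MC through the compiled kernel (see _fastmc)."""
    from ._fastmc import kernel_args, mc_run

    moveset = moveset or MoveSet()
    if contact_map is not None and model.contact_map is not contact_map:
        raise ValueError("contact_map must be the model's own map")
    tol = bias.tolerance_factor if bias is not None else 1.2
    args = kernel_args(model, moveset, tol=tol)
    k_ratchet = bias.state.k_ratchet if bias is not None else 0.0
    q_rec0 = bias.state.q_record if bias is not None else 0.0
    frames, energies, qs, qrecs, nacc, nsaved = mc_run(
        np.ascontiguousarray(x, dtype=float),
        int(n_steps), int(max(stride, 1)), float(kBT),
        int(seed) % 2**31,
        q_stop=float(q_stop) if q_stop is not None else 2.0,
        k_ratchet=float(k_ratchet), q_record0=float(q_rec0), **args,
    )
    frames = frames[:nsaved]
    traj = Trajectory(
        frames=frames, stride=max(stride, 1), seed=seed, temperature=kBT,
        bias_record=qrecs[:nsaved] if bias is not None else None,
        scalars={
            "energy": energies[:nsaved],
            "acceptance": nacc / max(n_steps * model.n_beads, 1),
            "aborted": False,
        },
    )
    if contact_map is not None or bias is not None:
        traj.scalars["Q"] = qs[:nsaved]
    if bias is not None:
        from .ratchet import RatchetState
        bias.state = RatchetState(float(qrecs[nsaved - 1]), k_ratchet)
    if knot_flags:
        from .knots import chain_is_knotted
        traj.scalars["knotted"] = np.asarray(
            [chain_is_knotted(f) for f in traj.frames]
        )
    return traj
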