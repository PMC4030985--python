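"""Trajectory persistence: compact XYZ frames plus a JSON metadata sidecar
(seed, stride, temperature, per-frame scalars), and multi-model CA-only PDB
for visualization."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .samplers import Trajectory
from .structure import write_ca_pdb


def save_trajectory(traj: Trajectory, basepath) -> None:
    """Write ``basepath.xyz`` and ``basepath.json``."""
    base = Path(basepath)
    with open(base.with_suffix(".xyz"), "w") as fh:
        for i, fr in enumerate(traj.frames):
            fh.write(f"{traj.n_beads}\nframe {i}\n")
            for p in fr:
                fh.write(f"CA {p[0]:.4f} {p[1]:.4f} {p[2]:.4f}\n")
    meta = {
        "stride": traj.stride,
        "seed": traj.seed,
        "temperature": traj.temperature,
        "dt": traj.dt,
        "n_frames": traj.n_frames,
        "n_beads": traj.n_beads,
        "scalars": {
            k: (np.asarray(v).tolist() if isinstance(v, (np.ndarray, list))
                else v)
            for k, v in traj.scalars.items()
        },
    }
    if traj.bias_record is not None:
        meta["bias_record"] = np.asarray(traj.bias_record).tolist()
    with open(base.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def load_trajectory(basepath) -> Trajectory:
    base = Path(basepath)
    with open(base.with_suffix(".json")) as fh:
        meta = json.load(fh)
    frames = []
    with open(base.with_suffix(".xyz")) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        n = int(lines[i])
        frame = [
            [float(v) for v in lines[i + 2 + k].split()[1:4]]
            for k in range(n)
        ]
        frames.append(frame)
        i += 2 + n
    scalars = {
        k: (np.asarray(v) if isinstance(v, list) else v)
        for k, v in meta.get("scalars", {}).items()
    }
    return Trajectory(
        frames=np.asarray(frames),
        stride=meta["stride"],
        seed=meta["seed"],
        temperature=meta["temperature"],
        dt=meta.get("dt"),
        bias_record=(np.asarray(meta["bias_record"])
                     if "bias_record" in meta else None),
        scalars=scalars,
    )


def save_trajectory_pdb(traj: Trajectory, path, residue_type=None) -> None:
    write_ca_pdb(traj.frames[0], path, residue_type=residue_type,
                 models=traj.frames)
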