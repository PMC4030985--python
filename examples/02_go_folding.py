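"""Folding a toy native structure with the pure Gō model.

A 20-bead helix hairpin refolds from a fully extended chain under
Metropolis Monte Carlo (crankshaft + single-bead moves) at low
temperature.  Prints the fraction of native contacts Q and the RMSD to
the native structure along the run.
"""

from knotfold.fixtures import extended_chain, toy_native
from knotfold.forcefield import PotentialEnergyModel
from knotfold.observables import kabsch_rmsd
from knotfold.samplers import run_sampler

trace, cmap = toy_native(20, "helix_hairpin")
model = PotentialEnergyModel(trace, cmap)
print(f"native: {trace.n_beads} beads, {cmap.n_pairs} native contacts, "
      f"E = {model.energy(trace.positions):.1f} (reduced units)")

traj = run_sampler(extended_chain(20), model, "mc",
                   n_steps=100_000, stride=10_000, kBT=0.3, seed=1,
                   contact_map=cmap)
for t, q, e in zip(traj.times(), traj.scalars["Q"], traj.scalars["energy"]):
    print(f"sweep {t:7d}  Q = {q:.2f}  E = {e:7.1f}")
rmsd = kabsch_rmsd(traj.frames[-1], trace.positions)
print(f"final RMSD to native: {rmsd:.2f} A  "
      f"({'folded' if rmsd < 1 else 'not folded'})")
# Q climbing to ~1 and RMSD < 1 A means the chain found the native
# minimum of the native-centric potential from an unstructured start.
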