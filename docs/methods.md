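# Methods

`knotfold` implements a coarse-grained framework for studying how protein
chains fold into (and out of) knotted native states: a Cα-resolution
native-centric force field with an optional sequence-dependent non-native
term, overdamped Langevin and local-move Metropolis Monte Carlo engines, a
ratchet-and-pawl bias on the fraction of native contacts with
Onsager–Machlup dominant-pathway selection, and a complete open-chain knot
analysis layer.

## Structural model

Each residue is a single bead at its Cα position; coordinates are Å and
residue indices are 1-based throughout. A native input must have at least
4 residues and consecutive-bead distances in [2.5, 4.5] Å (gaps beyond
4.5 Å are annotated as chain breaks, not errors). Secondary structure
comes from HELIX/SHEET records when present; otherwise a geometric
fallback labels residues from Cα virtual bend angles and torsions (ideal
α geometry: bend ≈ 91°, |torsion| ≈ 50°; extended β: bend ≥ 105°,
|torsion| ≥ 120°). The fallback is a coarse CA-only classifier, not a
DSSP replacement.

Native contacts are all bead pairs with Cα–Cα distance ≤ 7.5 Å and
sequence separation ≥ 3 (both configurable; these are conventional Gō
choices, not values recovered from any particular study). Each pair
carries its native distance and a secondary-structure class: `alpha` when
both residues are helical, `beta` when both are strand, else `other`.

## Force field

Reduced units: the native-well depth ε sets the energy scale and
temperatures are quoted as k_BT/ε. The native-centric terms are

- bonds: k_b (r − r₀)², k_b = 100 ε/Å²;
- angles: k_θ (θ − θ₀)², k_θ = 20 ε/rad²;
- dihedrals: k₁[1 − cos(φ − φ₀)] + k₃[1 − cos 3(φ − φ₀)], (k₁, k₃) =
  (1, 0.5) ε;
- native contacts: ε[5(r₀/r)¹² − 6(r₀/r)¹⁰], minimized at the native
  distance with depth −ε;
- excluded volume on non-native pairs: ε_rep(σ/r)¹² with σ = 4 Å.

The optional non-native term adds λ_nn · e(aᵢ, aⱼ) · s(r) over the
non-native pairs, where e is a symmetric 20×20 contact-propensity matrix
and s(r) a cosine switch that turns the interaction off smoothly between
6 Å and 7.5 Å. The shipped matrix is a **synthetic surrogate** derived
from the Kyte–Doolittle hydropathy scale (e(a,b) ∝ −(h_a + h_b), shifted
to zero mean over the 210 unique pairs) so that it encodes *relative*
pairing propensities with hydrophobic–hydrophobic pairs most attractive;
it is not a published statistical-potential parameter set. By default
only attractive (negative) entries act, reading the term as an overall
residue attraction; a flag restores the repulsive entries. λ_nn = 0
recovers the pure native-centric model bitwise.

Forces are analytic and verified against central finite differences to
1e-4 relative; collinear triples (undefined dihedral) contribute zero
dihedral gradient.

## Dynamics

The Langevin engine uses the discrete overdamped update
x' = x + (Δt·D/k_BT)·F(x) + √(2DΔt)·η with unit Gaussian η. A single
effective friction Γ = m_eff·γ ties the propagator to the path action;
D = k_BT/Γ is enforced at construction, and Δt must satisfy
Δt·D·k_max/k_BT < 0.1 for the stiffest bonded constant (hard error
otherwise).

The MC engine proposes crankshaft rotations of 2–8 interior beads about
the axis joining two anchor beads (bond lengths inside the rotated
segment are preserved exactly) and single-bead displacements, accepted
with the Metropolis rule. One sweep is n proposals. Default amplitudes
(0.3 rad, 0.10 Å) give 35–45% acceptance near the toys' folding
temperatures. Because the moves are local, the sweep axis is a proxy for
overdamped polymer dynamics. A compiled (numba) kernel recomputes the
full potential per proposal — profitable at these chain lengths
(≤ ~50 beads) and immune to partial-update bookkeeping errors; the
NumPy implementation remains the reference and the two are pinned
against each other in the tests. Both engines are reproducible
bit-for-bit from (initial state, parameters, seed).

## Ratchet-and-pawl bias and dominant pathways

The reaction coordinate is the sharp-count fraction of native contacts
Q: a pair counts as formed when its distance is within 1.2× its native
distance. The pawl records the best Q reached (q_rec); the bias energy is
0 whenever Q ≥ q_rec and ½·k(q_rec − Q)² below it, so the chain evolves
freely while progressing and is discouraged from regressing. For the MC
engine only this energy is needed. For the Langevin engine the bias force
direction is taken from a sigmoid-smoothed Q (steepness 5 Å⁻¹), because
the sharp count has zero gradient almost everywhere; the energy bookkeeping
still uses the sharp Q. Because the penalty is one-sided, the sharp-count
MC ratchet acts purely as a no-regression pawl: it measurably accelerates
folding when spontaneous regression is the bottleneck (near or above the
folding temperature) and is neutral for downhill folding.

Path probabilities are ranked by the Onsager–Machlup action
S = Γ/(4k_BTΔt) Σᵢ (x_{i+1} − x_i − F(xᵢ)Δt/Γ)², always evaluated with
the **unbiased** force, so that among trial trajectories sharing an
initial state the lowest action marks the least-biased, most probable
pathway. Actions require stride-1 frames; subsampled trajectories are
refused rather than rescaled (the discrete action is not
stride-invariant). For an unbiased trajectory scored with its own force
each summand has expectation ½ per degree of freedom — a self-consistency
identity the tests assert within 5%.

## Knot analysis

Open chains are closed deterministically: both termini are extended
radially from the chain centroid to a sphere of radius 10× the radius of
gyration and joined by a discretized great-circle arc. Deterministic
closure was chosen over stochastic multi-closure voting for
reproducibility; a majority-vote mode over deterministic rotations exists
for shallow-knot edge cases. The closed polygon is simplified by
triangle elimination (KMT): a vertex is deleted when no other edge
crosses its triangle, which preserves the knot type and keeps crossing
counts small for 300+ residue chains.

Knot type is the Alexander determinant |Δ(−1)| computed from the
underpass-generator presentation of a generic planar projection
(projection directions are perturbed deterministically until no
degenerate crossings remain; after 20 failed rotations a 1e-7-scale
jitter resolves genuinely singular polygons). The determinant is
evaluated exactly with integer (Bareiss) elimination: 1 = unknot,
3 = trefoil, 5 = figure-eight class. Trefoil handedness is the sign of
the summed crossing signs of the reduced diagram; the sign convention is
anchored to the Gauss writhe double integral (right-handed trefoil :=
writhe ≈ +3.4), and mirroring a chain flips chirality but not the
determinant.

The knotted core is found by alternating N/C terminal trimming with
re-closure after every deletion; the minimal surviving interval is
knotted and both one-residue trims are not. Note a closure-sensitivity
caveat: trimming a tight knot can leave a subchain whose radial closure
re-completes the knot, so the minimal core can sit strictly inside the
visually knotted body. Slipknots (whole chain unknotted, some subchain
knotted) are found by a coarse interval scan with greedy refinement.

A knotting event is the earliest frame from which the chain stays
knotted for a persistence window (default 10 saved frames — knots in
these simulations can untie, so single-frame detections are not events).
Mechanisms are classified by ordered rules operationalizing the three
canonical modes: (1) *slipknotting* when a pre-event frame holds a
slipknot and the threading terminus is bent back by more than 90°;
(2) *direct threading* when the event core abuts a terminus (within 10
residues) and that terminus stays straight; (3) *mousetrapping* when the
loop (core minus terminal zone) moves more than twice as much as the
terminal residues. All thresholds are configuration-exposed heuristics.
The terminus bend angle compares the direction of the last 5 beads with
the chain direction just before the 10-bead terminal zone, so a deep
fold-back reads as ~180° rather than straight.

## Synthetic systems

The fixtures module generates every input the tests need: parametric
knots (unknot, both trefoil hands, figure-eight) resampled to the
canonical 3.8 Å Cα spacing with optional self-intersection-guarded
noise; self-avoiding random coils; and three designed native folds —
a two-helix hairpin (the folding-recovery workhorse), a four-strand
β sheet, and a *shallow trefoil* whose last ~6 beads protrude from the
knotted core, mimicking shallow C-terminal protein knots. The shallow
trefoil carries a designed sequence (hydrophobic threading tail and loop
lining, polar elsewhere) so that the quasi-chemical term attracts the
terminus toward the threading loop, as natural knotted-protein sequences
do. The scripted mechanism trajectories are kinematic animations — a
straight tail translated through the fixed loop, a doubled-back tail
inserted and then straightened, a loop rotated over a static terminus —
built to pin the classifier's decision boundaries, and are labelled
kinematic in their metadata.

What the toys do not emulate: real secondary-structure cooperativity,
sequence-transferable energetics, solvent and side-chain packing, and —
critically — chain lengths at which threading events occur at observable
rates (see limitations).

## Protocol and problem sizes

The end-to-end protocol generates unfolded starts by high-temperature
runs from the native state (default 5× the sampling temperature) until
Q < 0.1 and the chain is verified unknotted, evolves each start with
several independent biased trials, keeps the lowest-action productive
trajectory per start (productive = Q ≥ 0.9, RMSD ≤ 2 Å, correct knot
type), and emits knot/mechanism reports plus a resolved-config snapshot
that reproduces the run bit-for-bit. The default trial count per start
is 48, configurable.

Tests and the acceptance script run everything at desk scale: 14–40-bead
toys, 10⁴–10⁵ MC sweeps, ensembles of 8–20 runs. These sizes were chosen
so the whole suite completes on a single CPU while each check retains a
clear pass/fail margin.

## Known limitations

- **Knot-tying events are unobservably rare at this scale.** Refolding
  the 32-bead shallow trefoil from thermally unfolded, verified-unknotted
  starts reaches Q = 0.87–1.0 while remaining unknotted, in both force
  fields, across biased and unbiased runs up to 1.5×10⁵ sweeps and knot
  checks every 250 sweeps: the chain satisfies nearly all native
  distance constraints with the tail on the wrong side of the loop, and
  the threading step itself is never taken. This is the topological
  bottleneck of knotted-protein folding in miniature — studies at
  realistic scale likewise find only a few percent of biased trajectories
  reaching the knotted state, out of trajectory counts in the thousands.
  Consequently the directional experiment "non-native interactions
  increase knotting success" is implemented and run faithfully but does
  not resolve a nonzero rate in either arm at desk scale, and its
  acceptance test fails honestly (0 vs 0). Observing the contrast
  requires either much longer chains (where compact-phase entanglement is
  common) or orders of magnitude more sampling.
- The attractive-only non-native term stabilizes compact *unknotted*
  states as well as the knotted native, so near the untying temperature
  it does not uniformly protect the knot.
- The equal-prefactor Kramers assumption in the two-pathway probability
  is exactly that; it is logged whenever used.
- Closure sensitivity: shallow knots (~6-residue tails) sit near the
  detection boundary of any closure scheme; the majority-vote mode and
  the core-trim invariants are the provided diagnostics.
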