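# Methods

This note documents the model, its numerical choices, and what the
synthetic fixtures do and do not establish.

## Degrees of freedom and derived layers

The dynamical state is the backbone triad (N, Cα, C) per residue, with
momenta; coordinates are in Å, residue indices 0-based internally and
1-based in files and error messages.  Derived coordinates are rebuilt at
every force evaluation:

* **Carbonyl O**: in the peptide plane, 1.231 Å from C along the outward
  bisector of the Cα–C and N(i+1)–C bond directions.  The last residue has
  no following N; a pseudo-N is extrapolated 1.329 Å from C along the
  N→C direction so that every residue carries an O.
* **Amide H**: 1.010 Å from N along the outward bisector of the Cα–N and
  C(i−1)–N directions; the first residue has no H.
* **Cβ**: ideal tetrahedral position 1.530 Å from Cα, built from the
  residue frame (in-plane bisector e_x, plane normal e_z) with L-amino-acid
  chirality; glycine uses the same pseudo-Cβ so the burial and environment
  terms are defined for all residues.

Each placement stores its analytic Jacobian with respect to its parent
atoms.  Forces on derived sites (and on side-chain beads, through the
residue frame) are pulled back by the exact adjoint of the placement maps;
the test-suite verifies every composed gradient against central finite
differences at relative error below 1e−5 (individual terms below 1e−6).

## Energy terms and parameters

* **Oriented pair potential** `V = κ(V_r(r) + ang₁(−n̂₁·n̂₁₂)ang₂(n̂₂·n̂₁₂)V_a(r))`.
  Curves are uniform cubic B-spline sums, linear in their coefficients, so
  parameter gradients are exact basis evaluations.  Radial curves use
  spacing `cutoff/K`, which makes the value *and* slope identically zero at
  and beyond the cutoff with no clamping.  Side-chain pairs: 16+16 radial
  coefficients on [0, 10 Å] and 15+15 angular on [−1, 1] (62 per pair;
  210 unordered types → 13020).  Bead–backbone pairs: 14+14 on [0, 8 Å]
  and 13+13 (54 per pair; 5 sites × 20 types → 5400).  The assignment of
  the larger cutoff to side-chain pairs is a configuration default and can
  be overridden.  One scale κ per pair type (initialized 1.0) is trainable
  alongside the coefficients but counted separately in the bookkeeping.
  For unordered pair types the roles of ang₁/ang₂ follow the canonical
  (alphabetical) key order; role bookkeeping is handled by the graph
  construction so physical energies are well defined.
* **Environment (desolvation)**: smooth burial count
  `N_i = Σ_j σ_r(r_ij)·σ_a(cos θ_ij)` over the other residues' Cβ sites,
  with a logistic radial switch centered at 7.0 Å (width 1.0 Å) and a
  logistic hemisphere switch in cos θ about the Cα→Cβ axis (width 0.2).
  These constants are stand-ins exposed in `BurialConfig`.  Each residue
  type has a 10-coefficient curve on N_i ∈ [0, 12], clamped with zero slope
  outside.  By default burial is measured at the Cβ ("cbeta" mode);
  a "bead" mode moves the state-dependent burial inside the BP node
  energies, selectable on `EnergyModel`.
* **Ramachandran**: periodic bicubic tables (B-spline coefficients on a
  24×24 grid) keyed by context class — general, pre-proline, glycine —
  with the file format supporting arbitrary context keys.  The bundled
  table is synthetic (negative-log von Mises mixtures over the α, β and
  αL basins), a stand-in for statistical backbone libraries.  A single
  trainable scalar adds a smooth periodic bump centered at (−120°, +130°)
  with 40° width to stabilize β geometries.  Terminal residues, having
  only one defined dihedral, are skipped.
* **Hydrogen bonds**: donors are amide H (residues 2..N), acceptors
  carbonyl O, sequence separation ≥ 2.  Each pair contributes
  `magnitude · s_d(r_HO) · s_a(ĉ_donor) · s_a(ĉ_acceptor)` with C¹
  smoothstep switches: distance full below 2.0 Å and exactly zero beyond
  3.0 Å; angular switches rising on the alignment cosines from 0.5 to 1.0.
  The product of switches is the pair's score in [0, 1]; with these
  constants every i→i+4 pair of an ideal α-helix scores ≈0.9.  Only the
  magnitude is trainable; geometry constants are fixed.
* **Sterics**: `E = 10·(1 − r/3.2 Å)³` among backbone N, Cα, Cβ, C of
  residues separated by ≥ 2, zero beyond 3.2 Å (≈3 Å contact plus
  switching width); smooth and strictly decreasing inside.
* **Bonded terms** (fixed, never trained): stiff harmonic bonds
  (k = 100 E/Å²), angles (k = 50 E/rad²) and an ω-dihedral restraint at
  180° (k = 20 E/rad²) hold the three-atom backbone near ideal geometry.

The flattened trainable vector α has a documented stable ordering
(side-chain pairs, backbone pairs, environment curves, sheet bias, H-bond
magnitude; see `ParameterSet`), and round-trips through the JSON parameter
file bit-exactly (floats serialized via shortest round-trip repr).

## Side-chain belief propagation

The fixture rotamer library is synthetic: ALA/GLY have one state at the
(pseudo-)Cβ; every other type gets three staggered χ₁-like bead positions
at tetrahedral angles about the Cα→Cβ axis, at a per-type centroid
distance, with orientations along Cβ→bead and priors (0.5, 0.3, 0.2).
The file format supports up to six states per type and real libraries
load from JSON.

BP runs damped synchronous sum-product with prior weights kept separate
from physical energies (they enter as −T log w).  Defaults: damping 0.5,
tolerance 1e−8 on the maximum message change (probability scale), 50
iterations; the acceptance checks tighten the tolerance to 1e−13.
Damping mixes messages in **log space**: probability-space mixing can
stall on saturated messages at very low temperature, which log-space
mixing avoids while sharing the same fixed points.  Non-convergence is
reported on the returned beliefs, not raised — training uses the partial
result.

The Bethe free energy is computed from the converged node and edge
marginals and is exact (equals −T log Z) on trees; the suite verifies this
at 1e−10 on random tree graphs and ~1e−3 accuracy on weakly coupled
cycles.  Forces and parameter gradients are belief-weighted expectations
of the per-state energy gradients — the envelope argument, exact at the
Bethe stationary point, with no implicit-function correction.

## Sampling

BAOAB Langevin splitting (default dt = 0.01, γ = 1.0, unit masses),
chosen for its configurational accuracy at finite step size; at γ = 0,
T = 0 it reduces to velocity Verlet.  Pivot Monte Carlo rotates the chain
segment downstream of a random φ or ψ axis by a uniform angle and applies
Metropolis; bonded internal coordinates are preserved exactly by
construction.  Replica exchange attempts alternating even/odd neighbor
swaps with acceptance min(1, exp(Δβ·ΔE)); temperature ladders are
`T_k = T_min + k·Δ·(100/N_res)` — intervals scale as 1/N_res, normalized
so a 100-residue chain gets intervals of exactly the configured base.
Model units are used throughout; converters for display assume one energy
unit = 0.6 kcal/mol and T = 1 ↔ 300 K.

## Training

Contrastive divergence with the "model minus data" sign:
`Δα = (ε/M) Σ_a (⟨dV/dα⟩_free − ⟨dV/dα⟩_restrained)` — the descent
direction of the data negative log-likelihood when the free simulation
equilibrates, and a useful direction even when it does not.  The
restrained ensemble uses a flat-bottom harmonic on best-fit Cα-RMSD
(radius 1.0 Å, spring 50 E/Å² beyond the bottom); its gradient uses the
standard result that terms through the optimal rotation and centroid
vanish at the superposition optimum.  The restraint has no trainable
parameters, so recorded dV/dα never contains restraint contributions.
Minibatches are fixed consecutive subsets (no reshuffling by default);
the step size multiplies by 0.25 after every two full passes.  Parameter
derivatives are recorded from the coldest replica only.  Per-block
learning-rate multipliers are exposed (`CDConfig.block_lr`) because scalar
and spline blocks can prefer different step sizes.  Early stopping is by
step count; prolonged training is not automatically beneficial for this
kind of objective.  Per-step RNG streams derive from (seed, step), so a
run resumed from a checkpoint reproduces the uninterrupted run exactly.

## Analysis

Cα-RMSD uses Kabsch (SVD) superposition, excluding three residues at each
terminus by default to discount end fraying; the quaternion method serves
as an independent oracle in the tests.  Rg is Cα-only; the denatured-state
reference is `1.9·N_res^0.6` Å.  Heat capacity uses the fluctuation
relation `Cp = var(E)/T²` with the unbiased (n−1) variance.  H-bond
counting thresholds the switch-product score at 0.5; on an ideal
20-residue helix all 16 (i, i+4) donor/acceptor pairs exist (O is placed
on every residue, H from residue 2 on) and score ≈0.9.  Clustering is
greedy leader clustering on pairwise RMSD (default cutoff 3 Å),
deterministic in frame order, with centroids the members minimizing mean
intra-cluster RMSD.

## Synthetic data and what the tests show

All fixtures are generated programmatically: ideal-geometry chains built
by internal-coordinate construction realizing requested (φ, ψ) (helix
−57°/−47°, strand −120°/+130°, coil sampled from the bundled table),
random smooth parameter sets, the χ₁ fixture rotamer library, and a 1-D
double-well toy with quadrature-exact Boltzmann references.  These
fixtures exercise the machinery — geometry, gradients, samplers,
training updates — under controlled conditions; they do not demonstrate
folding accuracy on real proteins, which requires a trained parameter set
and far longer sampling than the test scales.  `ParameterSet.demo()` is a
physically flavored demonstration set, not a trained force field.

## Problem sizes used in validation

Chosen to keep the full suite and the acceptance script in minutes on one
core: gradient checks on 6–8-residue mixed-sequence fixtures (all 72
coordinates); BP exactness on 100 random trees of ≤ 6 nodes × ≤ 6 states;
sampler checks with 1.2–1.6 × 10⁵ Metropolis/Langevin steps with 20×
thinning (the pivot sampler is an independence sampler whose sticky
high-probability basins demand thinning before a χ² comparison);
restrained-ensemble runs of 2 replicas × 300 steps on a 10-residue helix;
CD recovery with 2000–4000 exact Gaussian samples per update for 200
updates.

## Known limitations

* The bundled Ramachandran table, rotamer library, and burial/H-bond
  geometry constants are synthetic stand-ins; file formats accept real
  statistical libraries.
* Loopy BP is approximate; accuracy is quantified only for weak couplings.
* No cis-proline, D-amino acids, explicit solvent, or all-atom side
  chains; no physical time-scale calibration.
* The bead-mode environment coupling treats neighbor burial against Cβ
  sites only (no bead–bead burial).
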