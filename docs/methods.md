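# Methods

## Scope and model

`aggfold` analyses the two coupled processes by which short cationic
antimicrobial peptides are thought to reach a membrane in a functional
fold: self-association of many chains into aggregates, and
aggregation-driven straightening of individual chains from a compact
helix-loop-helix conformation into the linear single helix.  The package
does not integrate equations of motion.  Its synthetic generator is a
*kinematic emulator*: it produces trajectories whose aggregation and
folding events are scripted, so that every detector in the analysis chain
can be validated against exact ground truth.  Real molecular-dynamics
output in the same multi-model PDB layout can be analysed with the
identical code path.

## Reduced representation

Each residue carries five atoms: backbone N, Cα, C, O plus one side-chain
pseudo-atom at the Cβ position.  The pseudo-atom carries the side chain's
mass (for the radius of gyration) and a residue-class-dependent radius
(for SASA).  This preserves every analysis surface — dihedrals, backbone
PCA on N/Cα/C, class-decomposed SASA, atom-level contacts — at a fraction
of full-atom cost.  Consequences: absolute SASA values are smaller than
full-atom CHARMM-radius values (the reference study's ≈230–260 nm² levels
are not reproduction targets); class *fractions* and time-series shapes
are the meaningful output.

## Conformer construction

The straight template is an ideal α-helix built from internal coordinates
(φ = −57°, ψ = −47°, ω = 180°; bond lengths N–Cα 1.458 Å, Cα–C 1.525 Å,
C–N 1.329 Å).  The N–Cα–C angle is set to the tetrahedral 109.5°, which
yields a rise of 1.505 Å per residue (Cα1→Cα20 extent 2.86 nm) and a
radius of gyration of 0.95 nm, inside the linear-state basin
(0.9–1.1 nm).

The helix-loop-helix template opens the four hinge torsions (φ/ψ of
residues 10 and 11, the Gly10–Ser11 hinge) by a common offset.  Because a
torsion change rotates everything downstream about its bond axis, the
angle between the two helical-segment axes has a closed form in the
offset; the offset matching a requested bend angle is found by
bracketing + Brent root finding, and the chain is rebuilt from internal
coordinates so all non-hinge residues keep exactly helical dihedrals.
Reachable bend angles with this one-parameter family span ≈0–158°; the
default bend of 120° gives Rg = 0.68 nm, inside the compact basin
(0.55–0.80 nm).  Opening only the central ψ10/φ11 pair — the narrowest
reading of "hinge" — cannot exceed ≈106° (the sum of the axis–bond
angles), which is why both hinge residues participate.

## Synthetic scenarios

A `Scenario` fixes the study conditions; the defaults are the reference
system: 27 chains of bombinin H2 (sequence `IIGPVLGLVGSALGGLLKKI`), cubic
15 nm periodic box, 3×3×3 grid at 5 nm spacing (13 mM), all chains
initially hinge-bent, frames every 1 ns.  Events are scripted:

* **Merge events** `(t, chain_a, chain_b)` — the aggregate containing
  `chain_b` is rigidly translated along the centre-of-mass line toward the
  aggregate containing `chain_a` until first atom contact (0.4 nm by
  default, safely below the 0.5 nm detection cutoff); thereafter the union
  diffuses as one rigid body.
* **Straightening events** `(t, chain)` — the chain's coordinates are
  replaced by the straight template superposed (Kabsch, all atoms) on its
  previous position, i.e. the transition is instantaneous between frames,
  matching the "snap" character of the observed transitions.  Because the
  conformational change moves atoms by up to ~1 nm, a re-cohesion step
  then restores the aggregate's internal contact graph (detached
  components are pulled back into contact), so scripted aggregates never
  split — mirroring the observed stability of the large aggregate.

Each aggregate performs a rigid-body random walk per frame (translation
σ = 0.01 nm, rotation σ = 0.5° about its centre of mass) and i.i.d.
Gaussian noise is added per atom per frame.  The default noise σ is
0.002 nm: unlike correlated thermal motion, *independent* per-atom noise
perturbs backbone torsions strongly (σ = 0.01 nm already produces ±35°
dihedral jitter and state flicker), and 0.002 nm keeps noisy conformers
classifiable while remaining visible in RMSF.  The generator returns the
applied event schedule as a ledger table; all randomness flows from one
`numpy` generator seeded by the scenario, so equal seeds give bitwise
identical trajectories.

What the generator does **not** emulate: forces, solvent, thermostats,
realistic diffusion coefficients, partially folded intermediates, chain
flexibility beyond the two templates, or aggregate shape change.  Tests
passing on these scenarios therefore validate the *analysis machinery*
(detection, classification, decomposition, fitting) — not any physical
prediction about real peptides.

## Analysis definitions and numerical choices

* **Helix assignment.** Residue *i* is helical iff φ ∈ [−100°, −30°] and
  ψ ∈ [−80°, −5°] and it belongs to ≥ 4 consecutive such residues; termini
  (undefined φ or ψ) are never helical.  This dihedral-window criterion
  stands in for hydrogen-bond-based assigners (STRIDE/DSSP): the state
  question here reduces to "is the Val5–Lys17 core continuously helical",
  which the dihedral test answers; a custom helix mask can be supplied to
  the state logic for other assigners.
* **State classification** over residues 5–17 (1-based): *single-helix*
  iff the whole span is helical; *helix-loop-helix* iff the span contains
  ≥ 2 helical segments of ≥ 3 in-span residues; else *disordered*.  The
  "all 13 residues" requirement for the single-helix call and the run
  lengths (4 for helix, 3 per segment) are configurable constants; they
  were chosen so the two noise-free templates classify unambiguously.
* **SASA.** Shrake–Rupley with probe 0.14 nm and 960 golden-spiral
  quadrature points per atom (deterministic; doubling the count changes
  totals by < 1 %).  Backbone radii: N 0.155, Cα/C 0.170, O 0.152 nm;
  side-chain pseudo-atom radii 0.20 (hydrophobic), 0.19 (polar), 0.20 nm
  (charged), 0.11 nm for glycine.  Per-residue areas sum backbone + Cβ of
  that residue; class totals sum residues by class, so the partition is
  exact by construction.  An optional quadrature orientation makes SASA
  exactly invariant under a rigid transform applied to both.
* **Residue classes.** charged = {K,R,D,E}, polar = {S,T,N,Q,C,Y,H,W},
  hydrophobic = {A,V,L,I,M,F,P,G}, user-overridable.  Gly and Pro sit in
  the hydrophobic class: in a Gly/Pro-rich peptide the hydrophobic-SASA
  curve should account for essentially the entire burial signal, which
  this partition preserves.  His is treated as neutral at physiological
  pH; formal charges only (Lys/Arg +1, Asp/Glu −1, termini +1/−1) — no
  pKa model.
* **Aggregates.** Chains are adjacent when any inter-chain atom pair is
  closer than 0.5 nm (the 5 Å neighbour criterion) under the minimum-image
  convention (KD-tree with periodic box); aggregates are connected
  components.  The same cutoff serves neighbour attribution and contact
  counting; contacts are counted at atom-pair level and attributed to both
  residues (a deduplicated residue-pair mode is provided, since either
  reading of "contacts per frame" is defensible).
* **Clustering.** GROMOS-style greedy neighbour counting at 0.3 nm RMSD
  with per-pair optimal superposition.  Ties on neighbour count go to the
  earlier frame index — determinism requires *some* rule and the
  algorithm's original description leaves it open.
* **PCA.** Cartesian, mass-unweighted, on N/Cα/C (60 atoms → 180
  coordinates per 20-residue chain).  All observations (chain-frames, for
  multi-chain input) are least-square fitted to the starting conformation;
  the covariance is centred on the trajectory mean.  Eigen-RMSF of mode
  *m* at atom *a* is √λ_m · ‖v_m(a)‖.
* **RMSF** superposes every frame onto the first frame (optionally the
  iterated mean structure) on all atoms, then takes per-residue Cα RMS
  deviations about the time-average positions.
* **Transitions.** A chain has transitioned at the first entry into
  single-helix whose occupancy over the following 50 ns window (clipped at
  the series end) is ≥ 0.8.  Both knobs are configurable; they encode the
  qualitative "once transitioned, it remains stable" observation as an
  operational rule and reject single-frame flickers.
* **Sigmoid fit.** Nonlinear least squares of
  h_max / (1 + exp(−k (t − t_1/2))) with k > 0.  As printed with a
  positive exponent the logistic form only increases for a negative shape
  parameter; we fit the monotone-increasing convention and report
  λ = −k alongside.  Initialisation: h_max ← terminal count, t_1/2 ← time
  of half-terminal count, k ← 4/(t90 − t10); three restarts.  The
  monotonicity precondition can be relaxed for noisy per-frame
  observations.

## Units and I/O

All internal coordinates are nm; PDB I/O converts to/from Å (coordinates
round-trip to the format's 10⁻³ Å precision).  Trajectories are
multi-model PDB with one MODEL per frame, CRYST1 for the box, and
`REMARK 250 FRAME k TIME_NS t` header lines that round-trip time stamps
exactly; the writer emits no wall-clock metadata, so output is
byte-reproducible.  Tables are TSV with a header comment carrying tool
version, seed and config hash.

## Problem sizes used in the test and acceptance runs

The bundled scenarios are sized for interactive turnaround: the kinetics
reconstruction uses the full 27 chains × 2001 frames (1 ns spacing) but
zero noise; aggregation scenarios use 20–30 ns staircase schedules; SASA
time series are computed on strided frame subsets (the per-frame cost is
~1 s for 2 700 atoms at 960 points); clustering fixtures use 40 frames.
The acceptance script regenerates its two scenarios from scratch in a few
seconds.

## Known limitations

* Absolute quantities of the reference study that depend on real dynamics —
  11.7 % single-helix occupancy of the monomer, cluster occupancies near
  57 %, absolute SASA levels, the 19 % contact excess of straight chains,
  and the specific fitted sigmoid parameters of the reference run — are
  not reproducible from a kinematic emulator and are deliberately not
  asserted anywhere; the corresponding machinery is validated on scripted
  analogues instead.
* Bend angles above ≈158° are outside the single-offset hinge family and
  raise an error.
* Boxes are orthorhombic (the study's box is cubic); no triclinic
  support.
* SASA is computed on coordinates as stored (chains are generated whole);
  an aggregate interacting with its own periodic image would be decomposed
  as if isolated.
* `fit_sigmoid` on a step function with very few steps constrains the
  rate k weakly; this is a property of the data, not the optimiser, and
  the residual sum in the diagnostics should be inspected.
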