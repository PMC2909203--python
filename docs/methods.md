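# Methods

## Coordinate model and geometry

Structures are single chains of canonical residues at backbone + Cβ
resolution (N, CA, C, O, CB; glycine has no CB), coordinates in Å,
residue numbering 1-based with closed intervals.  Chains are built from
internal coordinates (NeRF) with ideal covalent geometry: N–CA 1.458 Å,
CA–C 1.525 Å, C–N 1.329 Å, standard bond angles, ω fixed at 180°, CB
placed at the L-configuration improper (C–N–CA–CB ≈ −123°).  Torsion
changes on existing coordinates are applied as rigid rotations about the
N–CA (φ) or CA–C (ψ) bond, which preserves covalent geometry exactly;
this one mechanism drives both the synthetic ensemble perturbation and
the annealing moves.  Superposition is Kabsch with SVD sign correction
(proper rotations only); collinear point sets are rejected.

Secondary structure is assigned from torsions alone: a residue is helical
iff φ ∈ −57 ± 30°, ψ ∈ −47 ± 30° and it belongs to a run of ≥ 3 such
residues.  This is deterministic and self-contained; it is *not* a
hydrogen-bond (DSSP-style) assignment, and chain termini (undefined
torsions) count in the denominator of the helical fraction.

PDB I/O accepts ATOM records of one chain only (HETATM, insertion codes
and multi-chain files are rejected); altloc duplicates keep the
highest-occupancy copy.  Reading goes through gemmi; writing is a
fixed-column formatter (occupancy 1.00, B 0.00) with a hard error past
serial 99999.

## Synthetic study conditions

The generators define the conditions every test runs under:

* **Bundles** — n ideal helices (φ, ψ = −57, −47) with axes on a circle
  of configurable packing radius (default 7–9 Å), antiparallel by
  default, joined by extended loops laid along the inter-helix gap.
  Helix interiors are exact; loop junctions are approximate, which is
  invisible to every downstream consumer (all work from distances or
  torsions).  Sequences follow a heptad pattern (hydrophobic a/d
  positions) so compactness and RAPDF see realistic composition.
* **Server-model ensembles** — independent Gaussian torsion noise per
  member, with the common scale calibrated by bisection on a fixed noise
  draw so the mean CA RMSD to the source lands within ~2% of the
  requested target (default 2.0 Å, 5 models — the diversity regime of
  server ensembles).  Deterministic per seed; the ±25% calibration band
  is verified over many seeds in the tests.
* **RAPDF corpus** — a mix of 2/3/4-helix bundles and random-coil decoys
  (default 8–10 structures, 24–60 residues each); small, but enough that
  no distance bin in 3–20 Å is empty.
* **Planted amphipathic sequences** — inside the planted window the
  helical-wheel angle (100°/residue) decides the face (L/I/F one side,
  S/E/Q the other) and lysines are forced at chosen positions; the
  default fixtures use the relative offsets {0, 3, 10, 14, 17} of the
  PDCD10 α5 lysines so cluster detection is exercised on the published
  spacing.

What these fixtures do *not* emulate: real sidechains and rotamers,
sheets, heterogeneous per-region error profiles of real prediction
servers (noise here is isotropic in torsion space), and sequence-family
conservation.  Passing tests therefore demonstrate correctness of the
machinery and recoverability under idealized noise, not accuracy on real
server ensembles.

## RAPDF and filter terms

The RAPDF table bins atom-type-pair distances (1 Å bins, half-open
[lo, hi), range [3, 20) Å, residue separation ≥ 3) over a reduced typing:
N, CA, C, O shared across residues, CB typed by residue character class
(hydrophobic / polar / positive / negative) — 8 types, 36 unordered
pairs.  The full 167-type scheme of the original RAPDF literature is not
trainable from a desk-scale corpus; the typing is a configuration choice,
not a constraint of the code.  Probabilities use add-pseudocount
smoothing (default 1) for both the conditional and the background, and
`log_odds = −ln(P(bin|pair)/P(bin))`, so favorable distances are
negative.  Scores: `rapdf_raw` sums log-odds over qualifying pairs;
`rapdf_normalized = 100 · raw / n_contacts`.  The normalization constant
places scores on the order of magnitude of the −55 correct-topology
threshold exposed by `flag_correct_topology` (strictly better than −55);
nothing downstream depends on that absolute calibration.

The three auxiliary filter terms are declared stand-ins with standard
ranking semantics, not published functional forms:

* van der Waals: Σ max(0, 0.9·(rᵢ+rⱼ) − d)² over pairs with residue
  separation ≥ 2 (radii C 1.70, N 1.55, O 1.52 Å);
* hydrophobic compactness: Rg(hydrophobic Cβ) / Rg(all Cα), lower =
  better-buried core (undefined without hydrophobic residues);
* electrostatics: Σ qᵢqⱼ/(4 d²) with unit charges on Cβ of K/R (+1) and
  D/E (−1), i.e. a distance-dependent dielectric ε = 4d.

## Consensus constraints

For each qualifying atom pair the support is the maximal number of
models coverable by a sliding interval of width 0.5 Å (best placement,
not a fixed grid — a grid origin would be arbitrary and can split
agreeing values); the representative distance is the mean of the covered
values.  Weights multiply a support factor (1.0 at full support, 0.8 at
the quorum minimum, linear between for larger ensembles) by a rank factor
mapping the RAPDF-score rank linearly onto (0, 1] with ties sharing the
better rank — that keeps the documented 1.0 : 0.8 ratio exact for
equal-scoring constraints.  Compilation keeps, per residue pair and
cutoff (12/16/20 Å), the constraint with the most favorable RAPDF score
(ties: larger support, then shorter distance, then atom-name order).
"Most favorable" is interpreted as the lowest −ln ratio; a config switch
can flip this.  Batch-by-batch compilation is realized as this single
best-per-pair selection ordered by score, since no batching granularity
is stated anywhere authoritative.

## Model building

Each conformation starts from the fully extended chain, melts (every
residue's torsions replaced by prior draws at infinite temperature, which
decorrelates trajectories and their fold handedness), then runs
basin-hopping Metropolis annealing: a proposal replaces one residue's
(φ, ψ) — prior draw or small Gaussian tweak whose σ anneals with
temperature — and is relaxed by a short torsion-space FIRE minimization
before the acceptance test on the quenched energy
`U = Σ w (d − d₀)² + vdW`.  Restraints activate from short to full
sequence separation over the first 60% of the schedule (variable-target
ramp), and a deep FIRE quench of the best-visited state finishes the
trajectory, so the reported final energy never exceeds the initial one.

The FIRE quench uses an analytic torsion gradient computed with the
crossing-pair identity (only restraints split by a torsion's moving
suffix contribute; accumulated with force/torque difference arrays in a
kinematic atom ordering, O(n_restraints + n_atoms) per gradient).  Plain
steepest descent and plain Metropolis both stall far above the restraint
optimum on this landscape; FIRE plus basin hopping reaches it from a
near-native start and gets within a few Å from an extended start.  The
whole trajectory is one numba-compiled kernel, deterministic per
(seed, round, model).

Temperatures default to a geometric ladder 4.0 → 0.05 with 3 moves per
residue; these values (and the toy problem sizes below) were calibrated
against the fold-recovery behavior of the synthetic conditions, which is
the only calibration target available for a search schedule.

Cartesian relaxation (`relax`) is guarded steepest descent on the clash
term with harmonic bond-length restraints; a step is taken only if the
clash term does not increase.

The sequential filter keeps ⌈N/2⌉ models: the removals split equally
across RAPDF, vdW, compactness and electrostatics (remainder at the last
stage, e.g. 12/12/12/14 for N = 100), each stage dropping its count of
worst scorers with stable order on ties.

## Clustering

Density of a model = number of other models within the RMSD threshold
(default 2.0 Å for build ensembles; the scale parameter is shared with
single-linkage grouping so "neighborhood" and "cluster" mean the same
thing).  Iteration removes all models with density < 2 (a model must
have a neighbor besides itself) and recomputes until stable.  Clusters
rank by size, then lower mean intra-cluster RMSD, then lowest member
index; the centroid is the maximal-density member (ties: lowest mean
RMSD to the cluster, then lowest index).  Removing every model yields an
explicit empty result rather than an error.

## Pipeline

A consensus round chains consensus → weighting → constraint sets →
building (per set) → relaxation → sequential filter → clustering → top-5
centroid selection; round two restarts from the five centroids and
recomputes everything, including weights (the alternative — reusing
round-one weights — would contradict the premise that a new distance set
is derived from the new models).  When toy-scale clustering yields fewer
clusters than the next round's quorum needs, the remaining slots are
filled with the densest non-centroid survivors in cluster-rank order;
production-scale ensembles do not hit this path.  Any stage left with no
survivors aborts with a stage-named error.  All randomness derives from
one seed through spawned streams; a full run is deterministic end to end.

## What fold recovery can and cannot show

Two recovery properties characterize the builder under the default
synthetic conditions (5-model ensembles at 2 Å torsion noise):

* Restrained builds beat unconstrained (prior-only) builds in ~97% of
  seeds — the restraints carry real information and the search uses it.
* The final centroids do **not** reliably come closer to the source than
  the best input model, and cannot: the consensus distances, although
  individually accurate to ~0.2–0.3 Å, jointly encode the
  ensemble-consensus conformation.  Minimizing the restraint objective
  from the *source structure itself* drifts 1.0–1.8 Å away from it —
  about the mean input error, and about where the best-of-five input
  model already sits.  Beating the best input under isotropic noise
  would require information the consensus construction does not retain.
  With heterogeneous error profiles (real server ensembles agree where
  they are right), consensus can do better than any single input; the
  isotropic synthetic conditions are the worst case for it.

## Functional-site analyses

* Hydrophobic moment: Eisenberg consensus scale (packaged,
  configurable), μH = |Σ hₙ e^{i·100°·n}|/N; amphipathic segments are
  maximal merged runs of 18-residue windows with μH ≥ 0.25 (window and
  threshold chosen for robust planted-signal recovery at < 5% shuffle
  false-positive rate); the face assignment comes from the phase of the
  complex sum.
* Basic clusters: maximal groups of ≥ 4 K/R within a 20-residue span,
  anchored to an amphipathic segment and allowed to extend 5 residues
  past its end (a trailing flexible loop).
* Heptad registers: the a–g frame maximizing mean a/d hydrophobicity
  over the 7 frames; undefined for helices shorter than 14.
* SASA: own Shrake–Rupley (probe 1.4 Å, 240 antipodally-symmetric
  golden-spiral points — the symmetric point set makes mirror-symmetric
  arrangements exactly equal), cross-checked against an independent
  implementation in the tests.
* Desolvation patches: every surface atom (SASA > 1 Å²) seeds a patch of
  surface atoms within 10 Å; score = Σ ASP(class)·SASA over members with
  a packaged octanol/water-transfer-style ASP table (apolar carbon
  negative, polar/charged N/O positive).  This is a simplified
  re-parameterization with optimal-docking-area ranking semantics, not
  the published constants.  Patches rank ascending; greedy pruning drops
  candidates centered inside an already-kept patch.
* Masses: average-isotope residue masses + 18.02 Da per chain,
  multiplied by the copy number (no inter-chain bonds), so the dimer
  estimate is exactly twice the monomer.  No post-translational or
  purification-tag arithmetic is attempted.

## Problem sizes

The default test and acceptance workloads use 29-residue two-helix
hairpins (builds, clustering, recovery statistics), 38-residue
three-helix bundles (scoring fixtures) and a 145-residue six-helix fold
(sequence/surface analyses), with 8–10-structure training corpora,
5-model ensembles, and 30–100 seeded replicates per statistical
property.  These sizes were chosen so the full suite exercises every
stage of the protocol, including two complete consensus rounds, at desk
scale.

## Known limitations

Backbone + Cβ resolution throughout (no rotamers); torsion-window helix
assignment disagrees with DSSP near helix termini; the annealing kernel
is a stand-in for restrained torsion-angle molecular dynamics and its
schedule is calibrated, not derived; the ODA-style ASP constants are
package defaults, not fitted; single-chain PDB dialect only.
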