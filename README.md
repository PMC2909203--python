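# consfold

Consensus distance-restrained protein model refinement and helix
functional-site analysis.

## The problem

When a protein has no close structural template — PDCD10 (CCM3), the
212-residue cerebral-cavernous-malformation protein, is the motivating
case — individual comparative-modeling servers each produce plausible but
mutually inconsistent models.  The idea behind this package is that the
*agreeing parts* of such an ensemble are the trustworthy parts: an
interatomic distance observed within a 0.5 Å window in at least four of
five candidate models is treated as a restraint, and new conformations
are rebuilt from scratch under those restraints.  The consensus models
that result can then be mined for functional sites: amphipathic helices,
clusters of basic residues (candidate phosphoinositide-binding sites like
the K169/K172/K179/K183/K186 lysine cluster in PDCD10's α5 helix), heptad
repeats, and favorable-desolvation surface patches that mark candidate
dimer interfaces.

## The method

One consensus round consists of:

1. **Consensus distances** — for every atom pair (residue separation ≥ 3)
   the best placement of a sliding 0.5 Å window over the per-model
   distances; pairs covered in ≥ 4 of 5 models become restraints with the
   window mean as target.
2. **RAPDF weighting** — a residue-specific all-atom probability
   discriminatory function scores each restraint:
   `score(pair, bin) = −ln [P(bin | pair) / P(bin)]`, trained by Bayesian
   counting of atom-type-pair distances in a structure corpus (reduced
   8-type scheme: backbone N/CA/C/O plus CB by residue character class).
   Restraint weight = support factor (1.0 full support, 0.8 quorum) ×
   linear rank factor of the RAPDF score.
3. **Constraint sets** — one best restraint per residue pair, compiled at
   maximal-distance cutoffs of 12, 16 and 20 Å.
4. **Model building** — 50 rounds × 20 models per constraint set
   (3 × 50 × 20 = 3000 conformations per consensus round), each built
   from an extended chain by basin-hopping Metropolis annealing in
   (φ, ψ) space under `U = Σ w (d − d₀)² + vdW`, with a Ramachandran-like
   torsion prior as proposal distribution and an analytic-gradient FIRE
   quench after every proposal.
5. **Filtering** — half the conformations are removed by sequentially
   applying RAPDF, a soft-sphere van der Waals term, the hydrophobic
   compactness factor Rg(hydrophobic Cβ)/Rg(Cα), and a screened
   electrostatics term.
6. **Clustering** — iterative density clustering (cycle: count RMSD
   neighbors, drop low-density outliers) followed by single-linkage
   grouping; the centroids of the five largest clusters seed the second
   consensus round, whose centroids are the final models.

Everything runs on synthetic inputs generated by the package itself
(ideal helical bundles, torsion-noise "server model" ensembles, planted
amphipathic sequences), so the full protocol is testable offline.

## Worked example

```bash
python analysis/01_simulate_inputs.py
python analysis/02_train_scoring.py
python analysis/03_consensus_constraints.py
python analysis/04_refine_pipeline.py
python analysis/05_functional_sites.py
```

prints, among other lines:

```
six-helix fold: 145 residues, 75.2% helical
hairpin ensemble: 5 models, mean RMSD 2.02 A (target 2.0), best 1.42 A
1499 consensus distances (window 0.5 A, quorum 4 of 5)
mean |consensus - native| distance error: 0.251 A
cutoff 12 A: 103 constraints (one best atom pair per residue pair) -> constraints_12A.tsv
best input model:    1.42 A CA RMSD to source
best final centroid: 3.40 A CA RMSD to source
PDCD10: 212 residues, K=21, E=21
planted control: 5 lysines over a span of 18 residues (expected 5 over 18)
```

Reading these numbers: the six-helix fixture reproduces the target
topology class at 75% helicity; consensus extraction recovers individual
native distances to ~0.25 Å even from a 2 Å-noise ensemble; the rebuilt
centroids converge near the ensemble-consensus conformation (not closer
to the source than the noise level that produced the ensemble — see
`docs/methods.md` for why that is the information-theoretic behavior of
this restraint construction); and the sequence-level scans recover the
planted five-lysine amphipathic cluster with its exact 18-residue span.

The same stages are available as subcommands of the `consfold` console
script (`simulate`, `train-rapdf`, `consensus`, `build`, `filter`,
`cluster`, `sites`, `run`, `dry-run`).

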