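# Methods

## Model

The scoring function is a random-forest regression from ten per-mutation
features to the unfolding free-energy change ΔΔG (kcal/mol, positive =
destabilizing). Defaults follow the design the function was built around:
500 trees, 3 features considered per split, bootstrap sampling with
replacement. The minimum leaf size is not part of that design and defaults
to 5 (the classic regression-forest default); it is a constructor parameter
(`min_leaf`), as is the seed. Forest predictions are averages of training
targets, so predictions are always inside the training target range — a
model trained only on destabilizing mutations cannot predict strongly
stabilizing ones, which is the practical argument for symmetric training
sets (below).

Per-prediction feature contributions use tree-path attribution: walking
each tree's decision path, the change in node mean between parent and child
is credited to the feature tested at the parent, and credits are averaged
over trees. By construction `bias + Σ contributions = prediction` (checked
to 1e-6 in tests); the bias is the mean root value, i.e. the average
training ΔΔG. Feature importance is the standard impurity-decrease measure.

## Features

* **PSSM** — the quantity extracted from a PSI-BLAST position-specific
  scoring matrix is not uniquely determined by convention, so it is
  configurable (`diff` = score(mut) − score(wt), `wt`, `mut`) and the chosen
  convention is stored in model metadata. The default `diff` is
  anti-symmetric under mutation reversal when the same profile is reused,
  which supports the symmetric-training design.
* **ΔCS** — consumed from a tabular provider in PROVEAN-like layout
  (protein, pos, wt, mut, score); the package does not run conservation
  pipelines itself. A fallback default value can be configured for bulk
  scans where the table has gaps.
* **ΔOMH** — difference of Sweet–Eisenberg optimal matching hydrophobicity,
  mut − wt; exactly anti-symmetric. The scale is bundled
  (`foldstab.tables.OMH`) and overridable from a file.
* **SASA_pro / SASA_sol** — absolute solvent accessible surface area of the
  mutated residue in the folded structure, and of the wild-type residue in
  an extended Gly-X-Gly tripeptide (Miller et al. 1987 values, bundled and
  overridable).
* **P_FWY / P_RKDE / P_L** — fraction of all residues of the assigned
  chains that are aromatic / charged / leucine **and** buried (relative
  SASA < 0.2). Multi-chain selections are treated as one protein: the
  denominator is the total residue count over all assigned chains.
* **N_Hydro / N_Charg** — counts over a 23-residue window centered on the
  mutated site in the concatenated chain sequence, truncated at termini
  without renormalization.

## Solvent accessibility

SASA uses the Shrake–Rupley algorithm: heavy atoms only, water probe 1.4 Å,
Bondi-style van der Waals radii (C 1.70, N 1.55, O 1.52, S 1.80 Å; bundled,
overridable), and a deterministic Fibonacci-spiral point grid whose
resolution is the `sphere_points` parameter (default 960; discretization
error ~O(n^-1/2), within 2% of closed-form two-sphere oracles at 960
points). Because a fixed grid orientation would make results weakly
dependent on how the input happens to be oriented, the grid is expressed in
the structure's principal-axes frame (signs fixed by third moments) by
default, which makes SASA exactly invariant under rigid rotation and
translation; `canonical_frame=False` restores the plain fixed-orientation
algorithm, whose output is pointwise monotone under atom addition.

A residue is core (COR) when relative SASA — absolute SASA over the
tripeptide reference — is strictly below 0.2, otherwise surface (SUR); the
boundary value 0.2 itself is surface. DSSP-style providers can be
substituted upstream by constructing a `SasaProfile` directly; radius sets
and chain-break handling are provider-dependent choices and are therefore
parameters here rather than constants.

## Structures

PDB parsing (via Biopython) keeps ATOM records of the 20 standard amino
acids plus selenomethionine (normalized to MET), drops waters and other
heteroatoms, uses only the first NMR model, and for alternate locations
keeps the highest-occupancy conformer (first listed wins ties). Residues
are addressed by author numbering plus insertion code throughout, never by
sequential index. mmCIF, multi-model averaging and assembly generation are
out of scope (supply the assembly file).

The naive mutant builder relabels the residue and truncates its side chain
beyond Cβ (to Cα for a glycine target; a glycine origin simply has no Cβ to
keep). No repacking is attempted — externally modelled mutant structures
can be passed anywhere a structure is accepted. Forward mutations are
featurized on the wild-type structure and sequence; reverse mutations on
the mutant structure and mutant sequence, reusing the wild-type protein's
PSSM with the two residues' roles swapped (profiles for hypothetical mutant
proteins do not exist; the consistency check for a reverse record compares
the profile sequence against the record's *mut* residue, the original wild
type).

## Dataset curation

Reverse augmentation doubles a forward set, linking each pair through
`pair_id` and negating ΔΔG exactly. ΔΔG = 0 counts as destabilizing (the
`≥ 0` convention). When independent test sets are merged, a mutation with
several measurements keeps the mean only if max − min is strictly below
1.0 kcal/mol, otherwise all entries drop; mutations present in the training
set (either direction) are removed. Dedup keys deliberately exclude the
structure identifier, so one mutation mapped to two structures is one
record. Candidate structures for a protein are ranked by: not heteromer,
wild type, fewer ligands, crystal over NMR, better resolution, with
crystals worse than 3 Å sorted last.

Protein clustering uses global BLOSUM62 alignment (gap open −11, extend −1)
with single linkage: a pair is similar when identity (identical pairs over
aligned columns) exceeds 25% and the aligned region covers at least 50% of
both sequences. Optimal alignments of *unrelated* random sequences also
reach ~25% identity, so an additional significance guard requires a
positive alignment score (unrelated pairs score strongly negative). A
dedicated clustering tool's assignments can be imported from TSV instead.

## Cross-validation

Five protocols: CV1/CV2 are repeated random 80/20 and 50/50 splits (100
repeats by default); CV3 first subsamples up to 20 mutations per protein to
damp heavily measured proteins, then splits 80/20; CV4 leaves one protein
out per fold; CV5 leaves out a whole similarity cluster. In every protocol
the sampling unit is the forward/reverse pair (a pair counts two mutations
toward the CV3 cap; unpaired records count one), so no model ever trains on
the mirror image of a test mutation. All randomness in a run derives from a
single scheme seed via NumPy `SeedSequence` spawning, per-round model seeds
are logged, and reports include per-round and mean R/RMSE/slope, strata
breakdowns (destabilizing/stabilizing by experimental sign,
forward/reverse, COR/SUR), and the pooled R_FR over held-out pairs.

Statistical comparisons: Fisher z-transform test for correlations from
independent groups, and DeLong's covariance-based test for two correlated
ROC curves (midrank implementation; the AUC it computes is the Mann–Whitney
statistic, which equals the trapezoid AUC of the threshold-sweep ROC).
MCC returns 0 when any marginal of a non-empty confusion matrix is zero;
an all-zero matrix is an error. Dependent-correlation tests (same group,
overlapping variable) are out of scope.

## Synthetic data

The generator emulates every external input so the full pipeline runs
offline. Toy proteins are ideal α-helices (φ = −57°, ψ = −47°, trans
peptide) built by NeRF internal-coordinate construction; chains of ≥20
residues fold into an antiparallel two-helix hairpin packed at 10 Å so that
inner-facing residues are genuinely buried by the 0.2 relative-SASA
criterion (a lone helix buries nothing). Residues carry backbone, Cβ and
one or two pseudo side-chain carbons; coordinates get 0.02 Å of seeded
jitter to break exact symmetry. Synthetic PSSMs follow the PSI-BLAST ASCII
layout with integer scores around zero and the native residue raised by a
conservation-strength parameter (default 5).

The default study conditions are 12 proteins of 60 residues with 84 forward
mutations each (~2000 records after augmentation) and Gaussian noise of
sd 0.5 kcal/mol on forward ΔΔG — sized so the full generate → train →
cross-validate cycle stays within a few minutes on one CPU while leaving
enough data for stable forest fits. Forward ΔΔG is a fixed linear function
of the ten features; the default coefficients weight the anti-symmetric
features (PSSM, ΔCS, ΔOMH) most heavily, with signs following the
destabilizing-positive convention, and ΔCS is generated correlated with the
PSSM change so tests exercise a non-orthogonal design. Reverse ΔΔG is the
exact negation; reverse features are computed on mutated structures, never
copied.

What passing synthetic tests does and does not show: they verify that the
implementation recovers a known generating function, preserves
anti-symmetry, and keeps CV protocols leak-free — they do not establish
accuracy on experimental data, where features are noisier, the generating
function is unknown and non-linear, structures are real folds, and
stabilizing mutations are rare. Published experimental benchmarks require
external inputs (PDB structures, PSI-BLAST profiles against nr,
conservation runs, modelled mutant structures) that this package consumes
but does not fetch.

## Numerical choices and edge cases

* Pearson R on constant input, ROC on single-class labels, and an all-zero
  confusion matrix raise degenerate-input errors rather than returning
  NaN.
* ROC thresholds sweep the unique scores (positive iff score ≥ threshold);
  AUC is the trapezoid over the sweep and equals the concordant-pair
  fraction with ties counted half.
* Classification labels for extreme mutations are inclusive: ΔΔG ≥ +1.0 is
  highly destabilizing, ΔΔG ≤ −1.0 highly stabilizing.
* Model files are versioned joblib payloads with embedded parameters,
  feature order, PSSM convention and a training-set fingerprint; loading a
  foreign or corrupt file raises a format error.
* Principal-axes sign fixing falls back to the largest-magnitude projection
  when third moments vanish (near-symmetric atom clouds); for such inputs
  rotation invariance is only approximate, at the level of the grid
  discretization error.

## Limitations

The naive mutant builder ignores side-chain repacking, so reverse-mutation
SASA is systematically biased toward the truncated side chain; the toy
structures are not physically realistic folds; the conservation fallback is
a constant, not an alignment-based score; and the clustering significance
guard is a heuristic stand-in for a proper homology-search E-value.
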