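# foldstab

Prediction of protein stability changes (ΔΔG, kcal/mol) caused by single
missense mutations, for structural biologists and protein engineers who need
to rank candidate substitutions or audit a predictor's thermodynamic
consistency.

## The method

A mutation `wt → mut` at a site of a protein structure is described by ten
features in six groups:

| group | features | meaning |
|---|---|---|
| evolutionary | `PSSM` | change in PSI-BLAST log-odds at the site (mut − wt) |
| conservation | `ΔCS` | change of a PROVEAN-style conservation score |
| hydrophobicity | `ΔOMH` | OMH(mut) − OMH(wt), Sweet–Eisenberg scale |
| accessibility | `SASA_pro`, `SASA_sol` | SASA (Å²) of the mutated residue in the protein and in an extended tripeptide |
| global composition | `P_FWY`, `P_RKDE`, `P_L` | fractions of aromatic / charged / leucine residues buried in the core (relative SASA < 0.2) |
| local sequence | `N_Hydro`, `N_Charg` | hydrophobic (VILFMWYC) and charged (RKDE) residues in a 23-site window |

A random-forest regression (500 trees, 3 features per split) maps the
features to ΔΔG, with positive values destabilizing. Because ΔΔG is a state
function, a forward mutation and its reverse must satisfy
ΔΔG_F + ΔΔG_R = 0; training sets are therefore *reverse-augmented* — every
measured forward mutation contributes a mirrored record with swapped
residues and negated ΔΔG, featurized on a mutant structure and sequence.
The anti-symmetry of a trained model is audited through R_FR, the Pearson
correlation between predicted forward and reverse values over pairs (−1 is
perfect anti-symmetry).

Evaluation machinery includes Pearson R / RMSE / slope, ROC + maximal MCC
for classifying highly destabilizing (ΔΔG ≥ +1) and highly stabilizing
(ΔΔG ≤ −1) mutations, Fisher z comparison of independent correlations, the
DeLong test for correlated ROC curves, and five cross-validation protocols
(repeated 80/20 and 50/50, per-protein-capped subsampling,
leave-one-protein-out, leave-one-protein-cluster-out at >25% sequence
identity) — all of which keep each forward/reverse pair on one side of
every split.

Everything runs offline: a synthetic-data module generates toy α-helical
hairpin structures, PSI-BLAST-style profiles, conservation tables and ΔΔG
values from a known anti-symmetric generating function.

## Worked example

```sh
foldstab demo --out demo --seed 2
```

generates a 4-protein synthetic study (240 mutations after reverse
augmentation), trains a forest, runs an alanine scan on the first protein
and a 3-round 80/20 cross-validation. The CV summary it prints:

```json
{
  "scheme": "cv1",
  "repeats": 3,
  "mean_r": 0.9566,
  "mean_rmse": 0.8870,
  "r_fr": -0.9464,
  "antisymmetry_bias": 0.0085
}
```

Held-out predictions correlate at R ≈ 0.96 with the generated ΔΔG values
(RMSE 0.89 kcal/mol), and R_FR ≈ −0.95 shows the model predicts reverse
mutations as near-exact mirror images of forward ones. The alanine-scan
table (`demo/ala_scan.tsv`) has one row per non-alanine residue:

```
mutation  ddg_pred  location  pssm  delta_cs  delta_omh  sasa_pro ...  contrib_pssm ...
A:Y1A     1.990     SUR       -5.0  0.0       -2.07      172.384  ...  0.9532       ...
A:L2A     1.763     SUR       -4.0  0.0       -1.62      137.924  ...  0.8581       ...
```

`ddg_pred` is the predicted ΔΔG (positive = destabilizing), `location`
marks the site core (COR) or surface (SUR), and the `contrib_*` columns
decompose each prediction additively over the ten features
(bias + Σ contributions = prediction).

The same workflow is scriptable: `foldstab fixtures`, `foldstab train`,
`foldstab predict` (mutation list, inline `A:L104D` specs, or `--ala-scan`)
and `foldstab evaluate --scheme cv1..cv5`. The Python API mirrors it —
`make_training_bundle`, `StabilityForest(...).fit(X, y)`, `run_cv`,
`roc_analysis`, `antisymmetry_audit`.

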