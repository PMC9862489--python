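# morphobarcode

Dual-engine species identification for *Lutzia* mosquitoes (Diptera:
Culicidae) — and, more generally, for any congeneric insect groups where
damaged specimens defeat classical keys:

* **Wing geometric morphometrics.** Eighteen wing-vein landmarks per
  specimen are superimposed by Generalized Procrustes Analysis (GPA),
  re-expressed as partial-warp + uniform scores, and reduced to principal
  components ("final shape variables"). Canonical variate analysis
  separates species; pairwise **Mahalanobis distances** D between group
  means (pooled within-group covariance W):

      D_ij = sqrt( (m_i - m_j)' W⁻¹ (m_i - m_j) )

  are tested by label permutation with Bonferroni correction, summarized
  as a UPGMA tree with within-group bootstrap supports, and identification
  performance is measured by leave-one-out Mahalanobis reclassification.
  Digitizing **repeatability** is estimated from re-digitized wings via a
  one-way Procrustes-ANOVA variance decomposition, and **allometry** by
  regressing the first discriminant axis on centroid size (r²,
  permutation p).

* **COI DNA barcoding.** Aligned ~658 bp barcodes are screened for stop
  codons (invertebrate mitochondrial code), and pairwise **Kimura
  2-parameter** distances

      d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

  (P, Q = transition / transversion proportions, pairwise deletion) feed
  an intra-/interspecific divergence summary, a **barcoding-gap** report
  (gap present iff the smallest interspecific distance strictly exceeds
  the largest intraspecific distance of the pair), and a neighbor-joining
  tree with site-resampling bootstrap supports.

A first-class synthetic-data module generates landmark and barcode
datasets with the exact statistical structure these analyses assume
(calibrated Mahalanobis separations, digitizing error, allometry,
per-species divergence targets, an engineered gap-less species pair), so
the whole pipeline is testable without any downloads.

## Worked example

```bash
morphobarcode simulate --study-mirror --seed 7 --out sim
morphobarcode morpho  --landmarks sim/landmarks.tps --out morpho --seed 7
morphobarcode barcode --fasta sim/barcodes.fasta \
    --labels sim/barcode_labels.csv --out bc --seed 7
```

which prints

```
simulate: wrote 4 dataset files to sim
morpho: 157 specimens, LOO accuracy 96.18%, outputs in morpho
barcode: 40 sequences, overall intra 0.49% / inter 3.26%, gap absent for: fuscana-halifaxii; outputs in bc
```

The simulated study has 157 wings in four species groups (40/50/42/25):
the morphometric engine reclassifies 96% of them correctly (the most
distinct species at 100%), every species pair differs significantly in
shape, and the run bundle contains the Mahalanobis matrix, permutation
p-values, the confusion matrix, shape scores, a Newick clustering tree
and figures. The barcoding engine reports ~0.5% mean intraspecific vs
~3.3% mean interspecific K2P divergence but flags exactly one species
pair — the engineered *fuscana*/*halifaxii*-like pair — as having **no
barcoding gap**: genetic distances cannot separate those two species,
while wing shape can. That asymmetry between the two engines is the
package's central use case.

Python API equivalents live in `morphobarcode` (e.g. `gpa_align`,
`discriminant_analysis`, `loo_classification`, `k2p_matrix`,
`divergence_summary`, `barcoding_gap`, `bootstrap_nj`); see
`docs/methods.md` for the statistical details and design choices.

Real deposited barcodes (GenBank OP783906–OP783945) can be fetched for
analysis with the explicitly networked command
`morphobarcode fetch-accessions --accessions OP783906-OP783945 --out
data/lutzia_coi.fasta`; all other commands and all tests run fully
offline.

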