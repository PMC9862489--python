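# Methods

This note documents the statistical machinery, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and
the numerically delicate corners.

## Geometric-morphometric engine

**Superimposition.** `gpa_align` performs full Procrustes
superimposition: every configuration is centred, scaled to unit centroid
size, and rotated (determinant +1 only — all wings come from the same
body side, so reflections are disallowed) to the running consensus; the
consensus is the renormalized mean of the aligned shapes and is itself
re-rotated to the previous consensus so its orientation is stable across
iterations. Convergence is declared when the consensus moves less than
`tol = 1e-8` (Frobenius norm); non-convergence within `max_iter = 100`
sets a flag rather than raising, because a nearly converged
superimposition is still usable. The result is invariant (to numerical
precision) under arbitrary similarity transforms of the input and under
the choice of initial consensus; both properties are enforced by tests.

**Tangent space and shape variables.** Aligned shapes live close to the
consensus, so residuals are treated in the linear tangent space at the
consensus: the orthogonal complement, within centred coordinate space,
of the four similarity directions (two translations, rotation, scaling),
dimension 2·18 − 4 = 32. `compute_shape_variables` builds an orthonormal
basis of this space from the thin-plate-spline bending-energy
eigenvectors of the consensus (2·15 partial-warp directions) plus two
uniform (affine) components, projects the residuals onto it, and takes
principal components of the scores. Because the basis is an orthonormal
rotation of the tangent space, total variance is conserved exactly and
the retained PC space coincides with a PCA of raw tangent residuals —
a property the suite checks by canonical correlations. The
retained-variance threshold defaults to 0.99 and is configurable because
no single choice is canonical; with 157 specimens this typically retains
~31 components.

**Discrimination.** Canonical axes solve the generalized eigenproblem
B v = λ W v (between- vs pooled within-group covariance). Mahalanobis
distances are reported as D, not D², matching the magnitude convention
of standard morphometric software. Axis signs are fixed by making the
largest-magnitude loading positive; consequently the *sign* of the
allometric slope is a convention, while |r| and r² are stable.

Two numerical guards apply before any W⁻¹ is formed: scores are
projected onto the leading eigenspace of W with condition number below
1e8, and the dimension is capped at n − g − 1 so that every
leave-one-out refit keeps a full-rank pooled covariance. Both guards
only log; they never change well-posed inputs.

**Permutation test.** For each group pair, specimens are pooled and
labels permuted (default 1000 times); the statistic is the two-group
Mahalanobis D² recomputed per permutation (means *and* pooled covariance
refit — the permutation distribution must see the same estimator as the
observed value). p = (1 + #{D²_perm ≥ D²_obs}) / (n_perm + 1): the
add-one Monte-Carlo estimator never returns exactly zero. Bonferroni
multiplies by the number of pairs (6 for four groups). The permutation
loop is vectorized (batched solves over stacked scatter matrices), which
makes the 1000-dataset type-I calibration in the test suite cheap.

**Leave-one-out reclassification.** Each specimen is removed, group
means and the pooled covariance are refit on the remainder, and the
specimen is assigned to the group with the smallest Mahalanobis
distance. Refitting per fold (rather than reusing the global covariance)
gives honest, slightly conservative error rates; online morphometric
tools do not always document which variant they use, and this is the
stricter one.

**Repeatability.** All digitizations of specimens with ≥ 2 digitizations
are jointly superimposed; aligned coordinates enter a one-way variance
decomposition with specimen as the factor, pooled over all 36
coordinates. The among-specimen component is (MS_among − MS_within)/r₀
(r₀ the unbalanced-design replicate coefficient), clipped at zero;
repeatability is among/(among + within) in percent. This is the standard
Procrustes-ANOVA-style estimator.

**Clustering tree.** UPGMA (configurable: single/complete) on the D
matrix. Bootstrap supports resample specimens with replacement *within*
species — group sizes are part of the design and are preserved — then
recompute D and the tree, counting how often each internal cluster of
the full-data tree recurs.

## Barcoding engine

**K2P distances.** Transition/transversion proportions are counted over
sites where both sequences have an unambiguous base (pairwise deletion;
complete deletion by flag — the choice matters only when alignments
contain gaps, which in-frame culicid COI barcodes do not). A non-positive
log argument raises a `SaturationError` naming the pair, forcing the
user to notice data problems; summaries can opt into NaN propagation
instead. Matrices carry substitutions/site; summary tables are percent.

**Pseudogene screen.** Translation under the invertebrate mitochondrial
code (stops TAA/TAG); frame auto-detection accepts a sequence iff some
forward frame is stop-free, since the primer-relative frame of a barcode
need not be 0.

**Barcoding gap.** Per species pair: gap present iff the minimum
interspecific distance strictly exceeds the larger of the two species'
intraspecific maxima. Equality is "no gap": a gap is a positive hiatus.
Pairs involving a single-sequence species are indeterminate, never
silently zero.

**Neighbor joining and bootstrap.** NJ (Saitou–Nei, negative branches
clamped) is delegated to scikit-bio; on additive matrices the path
lengths reproduce the input exactly, which the suite verifies against an
exhaustive least-squares topology search. Bootstrap resamples alignment
columns, recomputes K2P + NJ, and annotates the bipartitions of the
*full-data* topology (not a consensus tree) with replicate percentages;
saturated replicates are skipped and counted.

## Synthetic generators

**Landmarks.** Species mean shapes are the wing template plus offsets
along fixed smooth tangent directions; individuals add isotropic
Gaussian noise per tangent coordinate (so the within-species tangent
variance is exactly 32·sd²) and an allometric term `a·(log CS − mean log
CS)` along a fixed direction; every digitization adds independent
digitizing noise, a random rigid motion and scaling by the specimen's
log-normal centroid size. With isotropic noise, true Mahalanobis
distances equal Euclidean offsets divided by the noise sd, which is what
makes the design calibratable.

The *study-mirror* specification places the four species at the exact
3-D classical-scaling embedding of the target D matrix (4.05–10.25),
uses group sizes 40/50/42/25 (157 wings, 10 re-digitized per species),
within-species shape sd 0.004 (tangent units) and log-size sd 0.06.
Digitizing error is solved by fixed point so it contributes 4% of the
among-specimen shape variance, and the species-size slope is solved
analytically so the expected r² of (first canonical axis ~ centroid
size) is 0.22 — both effect sizes are the study conditions being
mirrored, not free parameters. Realized D̂ on one dataset overshoots the
true values by the usual Wishart-inverse small-sample inflation (~15–25%
at k ≈ 31, n = 157); this is a property of the estimator, not the
generator, and the same inflation is baked into any empirical D table.

**Barcodes.** A stop-free ancestral sequence with COI-like composition
(A 30 : C 16 : G 15 : T 39) evolves down the species tree implied by the
interspecific target matrix (UPGMA heights), then each individual
evolves half its species' intraspecific target; every branch uses the
exact closed-form K2P transition probabilities (transition/transversion
rate ratio κ = 4). Two corrections keep targets honest: (i) species
separations are reduced by the intraspecific half-branches so the target
is the expected *individual-level* distance, and (ii) branch lengths are
pre-inflated by inverting — via exact 64×64 codon enumeration — the
slight substitution deficit introduced by re-rolling codons that mutate
into stops. After both corrections, realized divergences are unbiased to
within Monte-Carlo error.

The barcode study-mirror uses per-species intraspecific targets
(0.19/0.60/0.35/0.76%), a gap-less pair at 0.48% and the most divergent
species at ~4.9%. The third species sits 3.5% from the gap-less pair —
further than the real-data analogue — because single-dataset branch
realizations carry Poisson noise of ~0.5–0.9 percentage points, and the
design contract is that *exactly one* pair lacks a gap; a thinner margin
would make that contract a coin flip.

**What the generators do not emulate:** correlated landmark noise and
landmark-specific digitizing error, non-isotropic within-species shape
covariance, geographic population structure, rate variation across sites
(gamma), indels, and coalescent genealogies within species. Passing
tests therefore demonstrate correctness of the estimators under their
own model assumptions, plus calibrated behaviour at the study's effect
sizes — not robustness to every property of real data.

## Problem sizes used in validation

Replicate counts were chosen so Monte-Carlo standard errors sit well
inside the assertion tolerances: 5 datasets for repeatability (±2), 10
for allometric r² (±0.06; a single 157-specimen dataset has sampling sd
≈ 0.06 itself), 50 for divergence recovery (±0.15 percentage points),
1000 null datasets at 199 permutations each for the type-I rate
(±0.02), and 3 datasets for the single-gap-less-pair contract (the pair
must be gap-less in all three; at most one replicate may graze an extra
pair).

## Known limitations

* The landmark template is a plausible culicid wing layout, not a
  digitized specimen; only its role as a base configuration matters.
* Canonical-axis sign, and hence allometric slope direction, is a
  documented convention.
* `estimate_repeatability` assumes digitizing error is exchangeable
  across specimens (one-way model); operator or session effects would
  need a nested design.
* The NJ bootstrap annotates full-data bipartitions; clades absent from
  the full-data tree get no support value even if frequent among
  replicates.
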