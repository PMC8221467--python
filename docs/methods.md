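# Methods

This note documents the statistical model behind `craniomix`, the
conventions and tolerances its numerics use, what the synthetic-data
generator does and does not emulate, and the design choices that were
genuinely open.

## Shape model and superimposition

A specimen is a configuration of k labelled 3D landmarks (k = 34 in the
default basicranial scheme). Shape is what remains after removing
translation, size and orientation:

* **Centering** subtracts the landmark centroid.
* **Scale** is fixed by dividing by centroid size, CS = √Σᵢ‖xᵢ − x̄‖².
  Every configuration is held at CS = 1 throughout — there is no
  inverse-consensus rescaling step — which matches the convention of
  analysing "Procrustes coordinates" in the morphometrics packages this
  pipeline mirrors.
* **Orientation** is removed by the Kabsch solution: the proper rotation
  minimising the Frobenius residual, with the smallest singular direction
  sign-corrected so reflections are never introduced by superimposition
  (handedness is meaningful; mirror symmetry is handled explicitly, below).

Generalized Procrustes analysis iterates rotate-to-consensus /
update-consensus until the RMS change of the consensus falls below
`tol = 1e-10` (default; `max_iter = 100`, non-convergence is flagged,
never raised). The objective Σᵢ‖Xᵢ − C‖² is non-increasing across
iterations; convergence typically takes 3–5 iterations on realistic
noise levels. No tangent-space projection is applied before PCA: shape
variation in this application is small (Procrustes distances ≲ 0.1), so
the curvature correction is far below the noise floor.

The pairwise Procrustes distance (used by the observer-error protocol)
superimposes exactly two configurations — both at unit centroid size,
optimal rotation — independent of any joint GPA. This is the natural
reading of a protocol that compares distances between individual repeat
configurations, and it makes the distance a true metric (it is
2·sin(ρ/2) for geodesic distance ρ, so symmetry and the triangle
inequality hold; both are property-tested).

## Bilateral symmetry

The basicranium has object symmetry: paired left/right landmarks plus
unpaired midline landmarks within a single structure. The pairing for a
given landmark set is anatomical knowledge that must be supplied (a
small YAML block); the default scheme used by the generator has 6
midline landmarks and 14 bilateral pairs.

The symmetric component is computed in the standard way: reflect each
configuration across a fixed plane (first coordinate negated), swap
left/right labels, run one joint GPA over the 2n originals + mirror
images, and average each specimen's two aligned copies. Asymmetry —
directional and fluctuating alike — cancels in the average (the
asymmetric residual is not analysed further).

Because GPA fixes orientation only up to a global rotation, the averaged
shapes are mirror-symmetric about *some* plane, not necessarily the
x = 0 plane of the reflection operator. The symmetrized set is therefore
rotated into a canonical frame: the consensus satisfies
reflect(C) = C·Q for a rotation Q, the matrix G = Q·M (M = diag(−1,1,1))
is an orthogonal involution whose −1 eigenvector is the mirror normal,
and rotating by the eigenbasis of G puts the mirror plane at x = 0
exactly. This is a pure rotation — every downstream statistic is
unchanged — but it makes the symmetric subspace of the scheme contain
the data exactly, which is what the symmetry invariants (and any user
inspecting coordinates) expect.

A counting note: the symmetric subspace has 3 dimensions per pair and 2
per midline landmark (54 for the default scheme). Of the 7 similarity
degrees of freedom, only 4 act within it (two in-plane translations, the
rotation about the mirror normal, and scale); and because the average of
two unit-size configurations has size slightly below 1, scale is removed
only to first order. The symmetrized data therefore have numerical rank
dim(sym) − 3 (51 by default), which the PCA rank guard recovers.

## Ordination and rank handling

PCA is an SVD of the centered n × 3k coordinate matrix; components whose
singular value falls below 1e-9 × the largest are discarded as null
space. The threshold sits ~7 orders of magnitude below the smallest
structural singular value and ~3 above the round-off floor of the
superimposition, so the cut is unambiguous.

CVA is computed inside that non-null PCA subspace (the standard guard
for p ≫ n Procrustes data), then solves the symmetric-definite
generalized eigenproblem B·v = λ·W·v with W the pooled within-group
covariance (divisor n − g). Scores have unit pooled within-group
variance per axis; axes are ordered by eigenvalue, with variance shares
as eigenvalue fractions, and each axis is oriented so its
largest-magnitude loading is positive (a reproducible sign convention
for plots). If W is singular even inside the guard (n − g smaller than
the shape rank), the error says to reduce dimensionality first rather
than silently regularising.

## Stepwise PC reduction

For j = 1, 2, …, an LDA over all groups present is scored by
leave-one-out cross-validation on the first j PCs; the search stops at
the first strict drop below the running maximum (ties extend the
search), and the shortest prefix achieving the maximum is retained.
LOOCV is deterministic, so the cv-curve is exactly reproducible. The
scan is capped at j = n − g − 1 so the pooled covariance in every fold
remains invertible. The cross-validation uses uniform class priors; the
group entering it are all four study groups, since the retained PCs
must support both the four-group MANOVA and the two-source LDA.

## MANOVA

Wilks' Λ = det(W)/det(W + B) from the within/between SSCP matrices
(computed via slogdet for stability), Rao's F approximation

  s = √((p²q² − 4)/(p² + q² − 5)),  df₁ = pq,
  df₂ = s·[(n−1) − (p+q+1)/2] − pq/2 + 1,
  F = ((1 − Λ^{1/s})/Λ^{1/s}) · df₂/df₁,

with q = g − 1, and partial η² = 1 − Λ^{1/s}. For g = 2 or p ≤ 2 the
approximation is exact. The implementation is cross-checked against a
direct determinant-ratio oracle and against statsmodels' MANOVA to
1e-10, and its type-I error is verified to sit inside binomial 95%
bounds of the nominal 5% under a multivariate-normal null
(n = 60, m = 5, g = 3, 1,000 replicates). The six pairwise tests are
reported unadjusted by default, as is conventional in this literature;
Bonferroni/Holm corrections are available but off.

## Ancestry attribution

The two source groups train a pooled-covariance Gaussian LDA on the
retained PCs. Priors are equal (0.5/0.5), not proportional to source
sample sizes: source ns reflect collection effort, not prior ancestry
odds. Posteriors follow the linear discriminant closed form (softmax of
−½·Mahalanobis² + log prior), and are invariant under any invertible
linear transform applied consistently to training and test features
(property-tested, and matched against scikit-learn to 1e-8).

An individual is attributed to the arg-max source only when its
posterior reaches the threshold, default 0.55 — deliberately more
conservative than the 0.50 chance level for two classes. With two
complementary posteriors, "both below 55%" is equivalent to "the winner
is below 0.55", which is how the unattributable rule is implemented.
Group-level ancestry is summarised both as hard-attribution percentages
(assumes each individual is wholly local or wholly continental) and as
mean posteriors (allows within-individual admixture). The two agree
when the sources are well separated and diverge as separation shrinks —
the mean posterior shrinks toward 0.5 because individual posteriors
saturate less.

Target specimens are projected into the PCA fitted on all four groups
jointly (one PCA per sex stratum), not a source-only PCA, so sources
and targets share one feature space.

## Synthetic-data generator

The generator emulates the statistical structure the pipeline assumes,
with known ground truth:

* **Design**: four groups at the study's sample sizes — Early (27 F /
  20 M), Middle (13/29), British (45/56), Danish (14/32); 236 in all.
* **Mean shapes**: a deterministic pseudo-anatomical symmetric base
  (midline on the mirror plane, pairs mirrored; centroid size 1), with
  the two source means offset ± half a symmetric direction.
* **Separation** `source_separation = 3.0` (in units of `within_sd`):
  calibrated once so that the two sources' leave-one-out LDA accuracy
  lands at ≈ 0.90 — separable but overlapping populations, the regime
  the attribution method is designed for.
* **Admixture**: each target specimen is drawn wholly from one source
  (Bernoulli with π_danish = 0.65 for the Early group, 0.35 for the
  Middle group — a majority-continental early period reversing to
  majority-local later). A `blended_admixture` option instead places
  each target's mean at the convex combination, matching the
  mean-posterior reading of ancestry.
* **Noise** (per-coordinate SDs at centroid size 1): symmetric
  within-group variation 0.015 (isotropic in the symmetric subspace;
  real craniometric covariance is anisotropic, which this default does
  not attempt), bilateral asymmetry 0.005 (isotropic in the
  antisymmetric subspace), digitization noise 0.002 on all coordinates.
  These give total within-group Procrustes scatter of the order seen in
  human cranial samples (pairwise distances ~0.03–0.1) and an
  observer-error ratio of ~2–4, the "repeats clearly tighter than
  distinct individuals" regime the error protocol expects.
* **Nuisance transforms**: every specimen is finally rotated uniformly
  at random, translated, and scaled to a ~100 mm working scale, so the
  Procrustes stage is doing real work.
* **Sexual dimorphism**: ± half of `dimorphism_scale = 0.04` along one
  common symmetric direction — large enough that pooling sexes without
  care would distort the discriminant, which is what the per-sex design
  guards against.

Everything is driven by one integer seed (independent substreams for
means, dimorphism direction and specimen noise) and reproduces
bit-for-bit.

What passing tests on this generator do **not** show: robustness to
anisotropic or group-specific covariance, to allometry or age
structure, to missing landmarks, or to digitization error that varies
by landmark type — real-data properties outside the generator's scope.
One visible consequence of the isotropic default is that the
between-source signal concentrates in very few PCs, so the stepwise
reduction typically retains 1–2 PCs on synthetic data, whereas
empirical cranial datasets (anisotropic, many weak directions of group
difference) retain on the order of 10–20.

## Problem sizes used in validation

The shipped validation experiments use the study-scale design above:
one full per-sex + mixed-sex fit (n = 236); mixture recovery over 20
seeds (per-sex pipeline each, no mixed run); MANOVA size calibration at
n = 60, m = 5, g = 3 with 1,000 replicates; 10 repeat digitizations for
the observer-error protocol. Recovery is judged on the seed-averaged
estimates: mean-posterior bias for the Early group within ±0.10 of
π = 0.65, hard-attribution percentage within ±15 points, and the
Early-Danish/Middle-British majority reversal in ≥ 18 of 20 seeds
(majority meaning more individuals attributed to one source than the
other; unattributables counted separately).

## Known limitations

* The anatomical left/right pairing of a landmark set must be supplied;
  there is no automatic pairing detection.
* No missing-landmark estimation: specimens with incomplete
  configurations are rejected at input.
* Wilks' Λ only (no Pillai/Hotelling–Lawley variants); no permutation
  MANOVA or permutation tests on CVA distances.
* The LDA is linear with a pooled covariance; no quadratic or
  regularised discriminants.
* The observer-error verdict follows the max-repeat vs min-between rule;
  no Procrustes-ANOVA decomposition of error variance.
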