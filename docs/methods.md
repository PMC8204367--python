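# Methods

This note documents the statistical procedures implemented in `strokemap`,
the design choices made where several defensible options existed, what the
synthetic cohort generator does and does not emulate, and the numerical
conventions that matter for reproducing results.

## Behavioural reduction

Raw subtest scores are converted to deficits `d = 1 − score/max` (0 intact,
1 worst), so every variable points the same way regardless of whether the
instrument counts successes or symptoms. Deficits are z-scored per subtest
(denominator n − 1); subtests with zero variance — typically those at
ceiling for every subject — are dropped with a warning rather than
jittered, since a constant carries no information and imputing noise would
contaminate the correlation matrix.

PCA is an eigendecomposition of the p × p subtest correlation matrix;
loadings are eigenvectors scaled by the square root of their eigenvalue,
and variance proportions are eigenvalue/p. Variance explained is always
reported from the unrotated eigenvalues: after an oblique rotation the
per-component variance is not uniquely attributable, so the unrotated
figures are the only well-defined ones. The component count defaults to 3
and is configurable.

Rotation is PROMAX with power 4: varimax first (pairwise planar rotations
with Kaiser row normalization, closed-form optimal angle per pair,
criterion-ascent guaranteed, convergence at criterion gain < 1e−8), then
the sign-preserving power target `sign(λ)|λ|⁴` fitted by oblique
Procrustes, with the transformation rescaled so the factor correlation
matrix Φ has a unit diagonal. These are the conventional defaults; the
implementation reproduces R's `stats::promax(x, m = 4)` to ~1e−5 (a frozen
cross-check lives in the test suite). Structure loadings are pattern · Φ.

Per-subject component scores are Thurstone regression scores `Z R⁻¹ S`
(R the subtest correlation matrix, S the structure loadings), chosen
because they are standard, deterministic, and well-suited for reuse as
regression targets downstream; a near-singular R is ridge-stabilized by
1e−8 on the diagonal with a log message. Components are sign-oriented so
the sum of each component's loadings on deficit variables is positive:
higher scores always mean more impairment.

The ordered correlation matrix assigns each subtest to its
largest-|pattern-loading| component and sorts by (component, loading
magnitude), which lines the correlated blocks up along the diagonal for
inspection.

## Ridge lesion–symptom mapping

Analysis voxels are those lesioned in at least `min_lesion_count` subjects
(default 2): a voxel seen in a single lesion cannot be distinguished from
that subject's idiosyncrasy. Subjects with empty masks are excluded from
the feature matrix (their rows are all zeros and only shift the intercept)
but retained in behaviour-only outputs.

The solver computes `(XᵀX + λI)w = Xᵀy` on column-centered X and centered
y; with many more voxels than subjects it switches to the dual form
`w = Xᵀ(XXᵀ + λI)⁻¹y`, which is algebraically identical (tested to 1e−10).
Columns are scaled by their cohort standard deviation as a fixed feature
definition, so the λ grid — 20 log-spaced values in [1e−2, 1e4] — has a
consistent meaning across cohorts; centering is recomputed exactly within
every training fold through the Gram-matrix algebra, so no fold ever sees
a held-out subject's lesion pattern in its centering.

λ is selected by inner 5-fold cross-validation (deterministic striped
folds, ties resolved to the larger penalty), nested inside leave-one-out
CV: each held-out subject's prediction uses a λ chosen only on the
remaining n − 1. Explained variance is the squared Pearson correlation of
the LOOCV predictions with the observations, **set to zero when that
correlation is negative**. The clamp matters: when cross-validation
selects heavy shrinkage (as it does under the null), each LOO prediction
approaches the mean of the training fold, which is exactly anti-correlated
with the held-out value (slope −1/(n−1)); because Pearson correlation is
scale-free, the raw r² would credit this artifact with substantial
"explained variance" where the model has none. An anti-correlated
predictor explains nothing, so it scores zero; the signed correlation is
retained in the outputs. In-sample R² is reported alongside as secondary
metadata; the cross-validated figure is the headline.

Weight maps place each voxel's coefficient at its coordinate (zero
elsewhere), are smoothed with an isotropic Gaussian of variance 1 voxel²
(kernel truncated at 4 sd and renormalized), and scaled by the maximum
absolute value into [−1, 1]. Values below 0.05 in magnitude are zeroed only
in the display/export layer; the full processed map is always retained.
Lateralization summaries (the share of positive weight mass per
hemisphere) are computed on the display-thresholded map — that is the map
a reader sees, and the sub-threshold noise weights are precisely what the
threshold exists to suppress.

Cross-cohort comparison correlates two maps over the union of their
supports after resampling to a common grid (nearest-neighbour for masks and
labels, trilinear optionally for continuous maps). The permutation null
translates one map by uniform random 3D circular shifts: unlike voxel
shuffling, translation preserves the map's spatial autocorrelation, making
the p-value meaningful for smoothed maps. p = (1 + #{|r_perm| ≥ |r|}) /
(1 + n_perm), with 10,000 permutations by default.

## Vascular-territory control

Territory overlap vectors give the percentage of each lesion inside the
deep, anterior-superior and posterior-inferior MCA territories, pooled
across hemispheres (the clustering question — does branch territory shape
the deficit profile — is hemisphere-agnostic). Lesions with no overlap at
all are excluded with a logged count: a (0, 0, 0) vector says nothing
about branch territory.

Clustering is k-means (Euclidean, 50 restarts per candidate k, best
inertia) for k in 2..6; the chosen k maximizes the silhouette index, with
Davies–Bouldin breaking ties (lower wins). Both indices are computed from
their definitions: silhouette `(b − a)/max(a, b)` averaged over points with
singletons contributing 0 (this convention also covers the two-singleton
edge case, where the index is 0 by definition); Davies–Bouldin as the mean
over clusters of the worst `(s_i + s_j)/d(c_i, c_j)` ratio, with an
infinite sentinel when centroids coincide. Note that because `a` excludes
the point itself, duplicating every point changes the index by O(1/cluster
size) — the invariance is asymptotic, not exact.

The split-plot ANOVA decomposes the n × 3 score matrix (components within
subjects, lesion cluster between subjects) by cell means:

SS_total = SS_between + SS_subjects(cluster) + SS_within + SS_interaction
+ SS_residual,

a decomposition that is exact for unbalanced group sizes (all cross terms
cancel algebraically; a property test asserts exactness on arbitrary
inputs). The between effect is tested against the subjects-within-clusters
mean square; within and interaction against the component × subject
residual. Greenhouse–Geisser epsilon is estimated from the pooled
within-cluster covariance (the classical split-plot choice; some packages
use the raw covariance, which differs when cluster means differ) and
reported alongside the uncorrected p-values. Pairwise post-hoc contrasts
refit a 2 × 3 mixed ANOVA per cluster pair and Bonferroni-multiply the
interaction p by C(k, 2) — 6 contrasts at k = 4.

## The synthetic cohort generator

The generator exists so that every downstream stage can be validated
against known ground truth. It emulates the statistical shape of an
acute-stroke bedside battery and its lesions, not their anatomy:

* **Geometry.** The brain is the ellipsoid inscribed in the grid (default
  40×48×40 voxels at 2 mm, RAS affine centred so world x < 0 is left). Per
  hemisphere, a deep central core (radius 0.55 in normalized coordinates,
  the subcortical compartment) is surrounded by a cortical shell split into
  anterior-superior and posterior-inferior territories — six labels in all,
  a deterministic function of the grid.
* **Lesions.** One connected region per subject, grown by uniform random
  frontier expansion (6-connectivity) from a random seed voxel, confined to
  one territory of one hemisphere; volumes are log-normal (median 500
  voxels, log-sd 0.8 — the empirical distribution is not published, so this
  is a modelling choice exposed in the configuration). Hemisphere follows
  `left_fraction` (default 0.5), territory is uniform within hemisphere.
* **Planted anatomy.** Three positive weight maps with the canonical
  lateralization: component 1 on the left cortical shell, component 2 over
  the right hemisphere, component 3 in the left deep territory, each a
  Gaussian bump over its support.
* **Severities.** A subject's latent severity per component is the overlap
  of their lesion with the planted map, rescaled by the cohort's 90th
  percentile of nonzero overlaps and clipped to [0, 1]. The rescale is
  deliberately saturating: destroying most of a planted region produces a
  near-maximal deficit, and severities spread over the unit interval
  instead of bunching near zero under the long-tailed volume distribution
  (rescaling by the cohort *maximum* was tried and leaves so little dynamic
  range that integer rounding of coarse subtests erases most of the planted
  signal — measurably degrading component-score determinacy and map
  recovery).
* **Scores.** Noiseless deficit = planted loading row · severity vector,
  shifted down by its `ceiling_fraction` cohort quantile (so at least that
  fraction of subjects sits exactly at ceiling — with the default 0.4 this
  reproduces the zero-inflated, long-tailed deficit distributions of real
  batteries), plus Gaussian noise (sd 0.1 by default), clipped to [0, 1],
  converted to the subtest's integer scale and rounded half away from zero.
  The default battery has 25 subtests (10 OCS-like, 15 NIHSS-like) with a
  three-block loading matrix: a 12-subtest cognitive block on component 1,
  an 8-subtest left-motor/neglect block on component 2, a 4-subtest
  right-motor block on component 3, plus weak cross-loadings.
* **Reproducibility.** Each subject's lesion draws from an independent
  substream seeded by (cohort seed, subject index), and battery noise from
  (cohort seed, 10⁶), so outputs are byte-identical across runs and
  independent of generation order.

What the generator does **not** emulate: real vascular anatomy or white
matter, multifocal or bilateral lesions, scanner/modality differences,
missing data, recovery dynamics, or correlated measurement error between
subtests. Passing recovery tests therefore demonstrates that the pipeline
is correct and well-calibrated under its own assumptions — three latent
factors, monotone lesion-load/deficit coupling, independent noise — not
that three factors exist in any particular patient population.

## Default study conditions and problem sizes

End-to-end validation runs at n = 200 subjects on the 40×48×40 grid with
noise sd 0.1 (~29,000 analysis voxels); under these conditions the pipeline
recovers planted loadings at Tucker congruence ≥ 0.94, weight-map vs
planted-map correlations ≈ 0.78–0.84, and ≥ 95% correctly lateralized
displayed positive weight mass. Calibration checks use 1000 null ANOVA
simulations (n = 40, k = 4), 50 null LOOCV replicates (n = 100), and 200
permutation-null map comparisons on 16³ grids, sizes at which the Monte
Carlo error of the checked rates is well below the asserted margins.

## Known limitations

* The λ grid is fixed rather than data-adaptive; targets whose CV curve is
  flat near the interpolation end can select extreme penalties (the
  explained variance is unaffected, but raw — unsmoothed — weight maps at
  tiny λ are noisy).
* Regression factor scores are correlated even for orthogonal factors
  (score correlations approximate Φ only to ~0.1 at n = 2000).
* k-means with Euclidean distance treats the three overlap percentages as
  an unconstrained vector; compositional structure (the simplex constraint)
  is ignored, as is hemisphere.
* The split-plot F tests assume sphericity; Greenhouse–Geisser epsilon is
  reported but the headline p-values are uncorrected, matching the
  classical procedure.
* Empty-lesion subjects are excluded from mapping and territory analyses
  and reported separately; no imputation is attempted.
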