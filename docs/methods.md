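# Methods

## The statistical problem and the estimator

Two clinical groups (CFS, n = 38; GWI, n = 80) are compared through
per-subject activation features: the number of voxels whose 2-back >
0-back t-statistic strictly exceeds 3.17, counted inside each of 117
atlas regions.  "Exceeding" is read strictly (a voxel at exactly 3.17 is
excluded); missing t-values never enter a mask and are logged.  The
classifier of interest is not any single model but the *consensus* of
nine heterogeneous classifiers trained on identical features: a subject
is assigned to the positive class (CFS) at agreement level k if at least
k of the models vote CFS.  Precision within the selected segment equals
1 − FDR by construction and is the segment's "accuracy".  Specificity is
computed as 1 − FP/N but flagged in the API docs as inflated at high k:
subjects not selected by any model count as negatives regardless of why.

## Pipeline stages and their parameters

**Split.** Stratified 50:50 train/test (`split_ratio=0.5`), seeded.  With
118 subjects this yields 59/59 with 19 CFS + 40 GWI on each side.

**Covariate control.** Age (years), sex, BMI (kg/m²) are removed from
every feature by OLS with coefficients estimated on the training half
only.  The covariate slopes are estimated with the group label included
in the design (ANCOVA-style) and only the intercept + covariate
contribution is subtracted.  Rationale: sex is strongly imbalanced
between the cohorts (74% male vs 26% male), so a pooled regression of
feature on covariates would attribute genuine group differences to sex
and strip them from the data; in a diagnostic run pooled residualization
cut the training CV accuracy of the screened feature set from 0.98 to
0.81 and eliminated most planted regions.  With no group labels supplied
the function performs plain pooled residualization.  Constant covariates
are dropped; a rank-deficient design after dropping is an error.

**Collinearity screen.** Pearson matrices on train, test and combined
data; a pair is flagged when |r| >= 0.9 in *any* of the three (ties at
the threshold are flagged — only features strictly below pass).
Flagged connected components are merged by summing member counts (counts
are additive) and the screen repeats until no pair is flagged, so the
output is a fixed point.  Correlations undefined because of a constant
column are reported but not flagged: a constant column carries no
collinearity risk and is removed later by importance pruning.

**Recursive feature elimination.** Explicit backward loop (one feature
per step, ranked by |coefficient| of a standardized L2 logistic
regression), scored by stratified 5-fold CV accuracy on the training
half; the returned subset maximizes the CV score with ties resolved
toward the *larger* subset.  Written by hand rather than delegated to a
library RFE because the tie-break and the CV objective are part of the
contract.

**The bucket.** Nine scikit-learn estimators with pinned
hyperparameters: k-NN (k = 3), linear-kernel SVM (C = 1), decision tree
(unlimited depth, seeded), random forest (100 trees), AdaBoost (50
rounds over depth-1 trees), Gaussian naive Bayes, QDA, L2 logistic
regression, and a one-hidden-layer MLP (100 units, max 500 epochs).
Scale-sensitive models (k-NN, SVM, logistic, MLP) are wrapped with a
training-half standardizer.  QDA uses `solver="eigen"` with Ledoit–Wolf
shrinkage (`shrinkage="auto"`): with ~19 training subjects per class and
30–100 features an unshrunk class covariance is singular (the default
solver raises) and weak fixed shrinkage degenerates to constant
majority-class prediction, which silently starves the high-agreement
consensus segments.  Predictions use the positive-class probability with
ties at 0.5 (or decision value 0) breaking toward CFS.  A model that
raises during fit/predict is logged, marked failed, and excluded from
the floor check rather than aborting the run.

**Iterative pruning.** Each round drops features with random-forest
importance exactly 0, then features whose importance standard error
(per-tree SD / sqrt(trees)) exceeds the importance.  The loop terminates
when (a) every non-failed model clears the accuracy floor (0.69), (b) an
iteration prunes nothing, or (c) `max_iterations` (20) is reached; only
(c) is flagged non-converged.  Feature sets are monotone non-increasing
across iterations.  If pruning would empty the feature list the single
top-importance feature is kept, with a warning.

**Floor evaluation.** By default the floor is assessed by stratified
5-fold CV on the *training* half (`floor_eval="train_cv"`).  Assessing
it on held-out accuracy while iterating — rebuild until the validation
score clears 69% — leaks the test set into feature selection; that mode
is provided (`floor_eval="test"`) for fidelity to the original
procedure but is not the default.

**Permutation test.** Each replicate permutes the group labels uniformly
and re-runs the entire build (split, covariate control, elimination,
bucket refits).  Statistic: minimum per-model final test accuracy
(operationalizing "a similar score across all models"); mean accuracy
is available by configuration.  p-values use the add-one rule, which
cannot return 0 and is conservative under ties.  Default replicates are
200 at desk scale; 1000 reproduces the original setting.

## The synthetic cohort generator

The study's subject-level scans are not deposited, so the generator
emulates their statistical structure; its defaults are the package's
stated assumptions, not claims about the original data.

- **Counts.**  Per subject and region, negative binomial with mean 20
  and shape (dispersion) 8, i.e. SD ≈ 8.4 — overdispersed non-negative
  integers, the natural choice for voxel counts.  In the GWI group the
  mean of each planted effect region is shifted by `effect_size` x the
  baseline-group SD; the planted effect is therefore a Glass's delta
  relative to the CFS-group SD (the shifted group's own variance grows
  with its mean, so a pooled-SD standardized difference would be
  smaller).  Defaults: 5 effect regions (ids 10, 33, 56, 79, 102),
  effect size 1.5.
- **Maps mode.**  Each region of a subject's t-volume receives exactly
  the latent count of voxels drawn uniform in (3.2, 8.0); all other
  voxels are uniform in (−2, 3.0).  Since the two supports straddle the
  3.17 threshold with a gap, extraction is exact by construction and the
  round trip is tested for bit-exact equality.  Latent counts above a
  region's voxel capacity are clipped and the clipped value recorded.
- **Atlas.**  An ellipsoidal "brain" mask on a configurable grid
  (default 24³ with 2 mm voxels for desk-scale speed; the original
  analysis grid would be MNI-sized), partitioned into near-equal
  contiguous blocks in scan order; the seed permutes label assignment.
  Region centers of mass are computed in world mm through the affine.
- **Demographics.**  Age, BMI and sex drawn per group from the study's
  cohort table (CFS: age 47.7 ± 16.5, BMI 26.2 ± 4.5, 26% male; GWI:
  46.9 ± 7.8, 29.6 ± 5.6, 74% male).  Covariates are generated
  independently of the counts, so covariate adjustment should be
  signal-neutral.
- **Symptoms.**  Nine severity items (0–4 scale, from the study's
  symptom list).  Raw score = linear coupling of z-scored counts +
  Gaussian noise (SD 0.5), affinely mapped into [0, 4] around the
  midpoint by scaling with the largest absolute raw score.  The map
  preserves ranks exactly (the clip never bites), which makes the
  coupling testable by rank correlation; the cost is that the symptom
  SD is set by the mapping rather than the noise level.

What the generator does **not** emulate: spatial autocorrelation of
BOLD maps, scanner/session effects, within-subject day-1/day-2
correlation, missing data, or any coupling between demographics and
activation.  Passing tests therefore demonstrate the pipeline's
correctness and its behavior under a known signal model — not
performance on real scans.

## Problem sizes used by the tests and the acceptance script

Chosen as the package's desk-scale defaults: the full synthetic cohort
(118 subjects, 117 regions, 24³ grid) for the round trip, build and
recovery checks; 20 seeded cohorts for planted-region recovery (≥ 4/5
regions retained and full-agreement precision above any-agreement
precision, each in ≥ 18/20 runs); and 100 seeded null cohorts x 100
permutations for shuffle-test calibration, run with a reduced
three-model bucket (decision tree, naive Bayes, logistic regression,
single iteration, no RFE) — the calibration of a permutation p-value
under an exchangeable null does not depend on the classifier set, and
the small discrete null makes the check conservative.  The acceptance
script runs the full nine-model pipeline once with 49 shuffle
replicates (p resolution 0.02).

## Known limitations

- The consensus specificity is structurally optimistic at high k (see
  above); read precision/FDR instead.
- With 19 positive training subjects per split, per-model accuracies
  have binomial noise of ±6 percentage points; single-seed accuracy
  values should not be over-interpreted.
- Random-forest importances are mean-decrease-in-impurity and
  non-negative by definition; their standard errors come from per-tree
  dispersion and shrink with tree count, so the SE-based pruning rule
  interacts with `n_estimators`.
- `iterate_build` under `floor_eval="test"` reproduces the original
  rebuild-until-valid procedure and inherits its optimism; accuracies
  reported from that mode are not unbiased estimates.
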