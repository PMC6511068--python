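# Methods

## Problem

In mild cognitive impairment (MCI), only about a third of patients receive a
dementia diagnosis within three years. A screening rule for clinical-trial
enrichment must therefore favour *specificity* over sensitivity: a false
positive enrols a patient who would never have declined, while a missed
progressor merely shrinks the candidate pool. `hpsig` implements a two-stage
procedure that deliberately operates in a high-specificity, low-sensitivity
regime, together with the surrounding machinery: grey-matter atrophy
subtyping, prevalence-adjusted evaluation, Monte-Carlo tests, subgroup
enrichment, and a parametric cohort simulator so the whole pipeline runs
without access-restricted patient data.

## Atrophy subtyping

Individual modulated grey-matter maps (post-VBM; image preprocessing is out
of scope) are residualized voxel-wise against age, sex, mean grey-matter
volume and total intracranial volume by ordinary least squares. A spatial
Pearson correlation between every pair of residual maps gives an n × n
similarity matrix; Ward's hierarchical clustering, applied to the
dissimilarity d = 1 − r, is cut at exactly k clusters (default k = 7, a
configuration parameter since the original choice was made by visual
inspection). Each subtype is the average residual map of one cluster, and a
participant's *subtype weights* are the spatial correlations between their
residual map and each subtype average — continuous affinity measures, used
as modelling features.

Design choices that were genuinely open:

- **Ward on correlations.** Ward linkage requires dissimilarities; d = 1 − r
  is the common convention for correlation matrices and is the default.
- **Held-out participants** are residualized with the *stored*
  training-sample confound coefficients, never refit, so the projection is a
  fixed function of the trained model.
- **Label order.** Clusters are renumbered by descending size (ties: lowest
  member index) so labellings are reproducible across runs and platforms.

## The two-stage signature

Stage 1 fits a linear SVM (inverse-frequency class weights) to dementia (AD)
vs cognitively normal (CN) participants. Its cost parameter C is selected by
mean accuracy over a stratified shuffle split (50 splits, 20% test) from 15
log₁₀-spaced values in [10⁻², 10¹], ties resolved toward the smaller C; an
outer stratified 10-fold loop reports cross-validated performance. The
selected C is then reused in a subsampling ensemble: for each of
`n_subsamples` replications, a class-stratified subsample of the chosen
fraction trains a fresh SVM that predicts the held-out complement. A
participant's **hit probability** is the fraction of their held-out
appearances that were classified correctly. Dementia patients with a perfect
hit record (threshold 1.0, configurable) are **high-confidence** cases — the
ensemble filters out every patient whose classification depends on the
training subsample.

Stage 2 fits an L1-regularized logistic regression on the full training
sample to predict high-confidence status from the same standardized
features; C is selected on a stratified shuffle split (500 splits, 50% test)
over the same grid, ties again toward the smaller (sparser) C. The sparse
coefficient vector is the interpretable *signature*; because features are
z-scored with training-sample parameters the coefficients read as pseudo
z-scores.

Prediction on new (MCI) participants is three-way: **high confidence** when
the stage-2 probability reaches 0.5, otherwise **low confidence** when the
full-sample stage-1 SVM predicts the dementia class, otherwise **negative**.
The two thresholds are independent, so a stage-2 positive that is stage-1
negative is possible; it is rare but not negligible at small sample sizes
(0–3 participants per simulated validation cohort of ~115), and the risk
grouping counts such cases explicitly.

The ensemble size and subsample fraction are tuned on a validation MCI
cohort over the 3 × 4 grid {100, 500, 1000} × {10%, 20%, 30%, 50%}: cells
with progressor-detection sensitivity below 30% are discarded, survivors are
ranked lexicographically by (PPV, specificity), ties toward fewer subsamples
then a larger fraction, and the full audit table is returned.

Further open-choice resolutions: the same SVM C is used for every ensemble
replication (selected once on the full sample); subsamples are
class-stratified with at least one row per class, so a single-class
subsample cannot occur; model selection inside both grids is mean accuracy;
the stage-2 decision threshold is fixed at probability 0.5. All randomness
derives from one master seed — the subsample of replication r comes from
`default_rng([seed, r])`, and scikit-learn splitters get integer seeds
derived per component via `SeedSequence` with fixed tags — so a fit is
bit-reproducible and a replay oracle can reconstruct the exact subsample
sequence.

## Evaluation

Sensitivity, specificity, PPV and accuracy come from the confusion matrix,
with zero denominators yielding NaN rather than 0. The
**prevalence-adjusted PPV** recomputes PPV at a stated baseline progression
rate p by Bayes' rule,

    PPV(adj) = sens · p / (sens · p + (1 − spec) · (1 − p)),

with p = 0.336 as the default (the meta-analytic three-year progression rate
in MCI). The formula is verified against four published worked examples
(80.4%, 87.8%, 85.1%, 68.2%) in the test suite.

Two Monte-Carlo tests are provided. The **performance-difference test**
takes model A's observed sensitivity and specificity as a parametric null,
replicates TP ~ Bin(n₊, sens) and FP ~ Bin(n₋, 1 − spec) (default 100,000
replications), derives the induced metric distributions, and reports
one-sided p-values of the form (1 + count) / (reps + 1) — never exactly
zero. Replications with an undefined PPV are excluded from that metric's
tail count and the exclusion count reported. Directions default to the
high-specificity hypothesis: greater accuracy/specificity/PPV, lower
sensitivity. The **baseline-rate test** is the exact one-sided binomial tail
for observing at least the flagged progressor count at the cohort's baseline
rate. ROC/AUC comparison fits four standard classifiers (RBF-kernel SVM,
k-nearest neighbours, random forest, Gaussian naive Bayes) plus the linear
SVM and the two-stage model, with documented default hyperparameters.

## Enrichment

The MCI cohort is partitioned into the three risk classes, and the
high-confidence subgroup is tested for enrichment of binary traits
(progression, APOE4 carriage, female sex, CSF amyloid/tau positivity at the
standard cut-offs: amyloid-beta 1-42 < 192 pg/mL, total tau > 93 pg/mL, both
strict). The null draws 100,000 random subgroups of the same size from the
cohort *without replacement* (a subgroup is a subset); the one-sided p-value
is (1 + #{null proportion ≥ observed}) / (reps + 1), which converges to the
hypergeometric tail. Rows with a missing trait are dropped pairwise from
both subgroup and pool, with counts reported. Raw p-values are emitted;
no multiplicity correction is imposed, since the appropriate correction
depends on the user's trait family.

Group-level age comparisons and longitudinal mixed-effects trajectory models
are deliberately not reimplemented — they are routine fits for a dedicated
statistics package; the module exports per-group visit tables instead.

## The cohort simulator

The simulator draws participants subgroup-by-subgroup from 16-variable
multivariate normals — 12 subgroups = 4 clinical labels (CN, sMCI, pMCI, AD)
× 3 prognostic subclasses (negative, low confidence, high confidence) — then
clips each variable to its stated range and binarizes sex to the nearest of
{0, 1} (exact ties to 1), in that order. `fit_subgroup_moments` closes the
loop: it estimates subgroup means and unbiased covariances from any cohort
table, so moments fitted on one cohort can parameterize the next.

The bundled default specification is hand-crafted to be *plausible*, not
estimated from patient data: diagnosis-level means for age, sex and ADAS13
follow published ADNI demographic tables; the remaining means are realistic
values ordered CN < sMCI < pMCI < AD in severity; subclasses are shifted
along a single "severity" direction so that prognosis is learnable; and the
shared correlation structure is a rank-one severity factor (R = λλᵀ off the
diagonal), positive semidefinite by construction. Subgroup sizes sum to
N = 1,115. Non-PSD covariances (possible when users supply their own
moments) are rejected, or repaired by flooring negative eigenvalues at zero
when explicitly requested.

What the generator does *not* emulate: scanner/site effects, non-Gaussian
tails and floor/ceiling effects beyond range clipping, missing-data
mechanisms, and the empirical covariances of any real cohort. Tests passing
on this generator show the pipeline's logic and its expected qualitative
behaviour (e.g. the specificity/sensitivity trade-off), not clinical
performance on real data.

Voxel maps are simulated as affinity × subtype template + confound effects +
i.i.d. Gaussian noise, with ground-truth labels and affinities returned for
recovery testing. Two regimes matter: at low noise, clustering recovery is
essentially perfect (adjusted Rand index 1.0), while the link between
planted affinity and recovered weight is best probed in a *noise-dominated*
regime, where the spatial correlation is approximately linear in affinity
(at low noise the correlation saturates near 1 for every participant, since
Pearson correlation is scale-invariant). The recovery checks therefore train
on 100 low-noise maps per subtype and project 80 noisy held-out maps per
subtype (noise SD 2 × template SD, affinity ~ N(0.5, 0.4²), 2,000 voxels), a
regime in which both checks hold with margin.

Longitudinal ADAS13 trajectories use group baselines and slopes (points per
year) with per-subject random slope deviations and visit noise; the default
high-confidence excess slope is 1.8 points/year over the low-confidence and
negative groups, matching the reported cognitive-decline gap that motivates
the signature.

## Numerical choices and problem sizes

- C-grid ties break toward the smaller C; cluster-label ties toward the
  lowest member index; tuning ties toward fewer subsamples then larger
  fractions. All are documented in the relevant docstrings.
- Monte-Carlo p-values use the (1 + count)/(1 + reps) estimator.
- Similarity matrices are symmetrized and clipped to [−1, 1] against
  floating-point drift; the diagonal is set to exactly 1.
- The test suite runs reduced problem sizes chosen once as the package's own
  defaults for fast feedback: quarter-scale cohorts (~280 participants),
  5-point C grids, 10–25 model-selection splits and 30–100 subsample
  replications for pipeline-level checks; full-scale settings (15-point
  grids, 500/1000-replication ensembles, 100,000-replication Monte-Carlo)
  remain the library defaults. The directional high-specificity check runs
  20 quarter-scale cohorts with a 100-subsample, 20%-fraction ensemble; the
  generator moment-recovery check uses 100,000 draws per subgroup.

## Known limitations

- The strict-subset relation between high-confidence and stage-1 positive
  sets is a tendency, not a guarantee, because the two decision rules have
  independent thresholds (see above).
- The simulator's default parameters are synthetic; no quantitative claim
  about real ADNI performance follows from tests that use them.
- Probability calibration of the stage-2 logistic output is not attempted;
  the 0.5 threshold is a convention, not a calibrated operating point.
- Comparison classifiers use library defaults; exact replication of any
  particular published comparison would require aligning their settings.
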