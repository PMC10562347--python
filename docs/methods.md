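# Methods

This note documents the statistical model behind `remodelscore`, the
design choices made where the method was genuinely open, the synthetic
cohort the package is validated on, and the limits of what those
validations show.

## Scoring model

**Contrast.** Let X be the standardized subjects × features matrix,
and let C_h and C_n be the covariance matrices of the hypertensive
(SBP ≥ 160 mmHg) and normotensive (SBP < 120 mmHg, off medication)
strata. The enriched subspace is spanned by the leading eigenvectors of
the contrast matrix C_h − α·C_n. Directions of shared physiological
variance have similar variance in both strata and are cancelled (or
driven negative) as α grows, while directions expressing
disease-enriched variance survive. Group covariances use Ledoit–Wolf
shrinkage toward a scaled identity because the stratum sizes (~100) are
close to the feature count (68); the shrinkage target preserves
eigenvectors, so α = 0 still reproduces PCA of the target covariance.

**Component count.** Components are retained until the cumulative
positive-eigenvalue mass reaches 80% (capped at 10). Negative contrast
eigenvalues mark directions *depleted* in the target and carry no
enriched mass.

**Contrast-parameter selection.** For each α on a grid (0 plus 40
log-spaced values in [10⁻², 10³]), the hypertensive subjects are
projected onto the subspace and a clustering-tendency statistic is
computed. Two numerical realities shaped the estimator:

* The raw Hopkins statistic is not comparable across dimensions — its
  no-structure level rises from ≈0.55 in one dimension to ≈0.6+ in ten,
  so maximizing it naively favours high-dimensional subspaces
  regardless of structure. We therefore score each α by the Hopkins
  statistic's *excess* over its Monte-Carlo expectation under a
  variance-matched Gaussian null of the same sample size and dimension
  (25 null draws; the data statistic itself is averaged over 20 seeded
  subsamples at sampling fraction 0.25).
* On data whose enriched structure is a continuous trajectory rather
  than discrete clusters, the tendency profile over α is flat to within
  its own Monte-Carlo noise. Excess values within one null standard
  deviation of the maximum are treated as tied, and ties resolve toward
  the **larger** α — the conservative default of maximal background
  suppression while enriched structure remains (at least one positive
  eigenvalue). When the target genuinely contains revealed clusters the
  tendency peak stands above the tolerance and wins outright.

**Trajectory and score.** All subjects (intermediates included) are
projected onto the enriched subspace. A pseudo-node is placed at the
mean of the normotensive projections (mean rather than medoid; the
construction is not otherwise pinned down), a minimum spanning tree is
built over the complete Euclidean graph, and each subject's raw value
is the unique tree-path length to the centroid node. Min–max
normalization over the fitting cohort maps raw distances onto [0, 1],
guaranteeing both endpoints exactly. Zero-weight edges (coincident
subjects) are legal; the sparse MST computation runs on weights shifted
by +1 (a strictly monotone transform leaves the tree unchanged) so such
edges are not dropped by the sparse representation.

**Held-out scoring.** New subjects are adjusted, standardized and
imputed with training parameters, projected with training loadings,
attached to the tree by an edge to their nearest node, normalized with
the training bounds and clipped to [0, 1]. Attachment (rather than a
tree refit) keeps training scores frozen, which is what makes the
cross-validated RMSD a meaningful stability measure. Because the score
is a distance from the healthy centroid, projection noise folds near
the centroid: subjects in the immediate vicinity of the healthy anchor
have a noise-floored score, and movements across the centroid register
as increases. This is inherent to centroid-distance pseudotime scoring
and is visible in the flattened low end of the score–pseudotime curve.

## Preprocessing

* Exclusion is strict (>30% missing): a subject or feature at exactly
  30% is retained. Subjects are filtered before features.
* Trimmed scores regression is implemented as iterative PCA-model
  regression: missing cells start at column means and are repeatedly
  replaced by their rank-k PCA reconstruction until the largest cell
  change is below 10⁻⁶ (cap 500 iterations; non-convergence warns and
  returns the last iterate). The matrix is z-scored internally so
  large-scale variables do not dominate the PCA model; observed cells
  are never altered. The rank is the smallest k explaining ≥90% of the
  variance of complete rows, capped at 10.
* Held-out subjects with missing cells are imputed by the conditional
  mean under the training PCA basis: component scores are fit by least
  squares on the observed coordinates and the missing coordinates are
  reconstructed. This is the out-of-sample analogue of the fit-time
  imputation; a plain column-mean fill was measurably noisier for
  factor-structured data and degraded follow-up score precision.
* Sex adjustment replaces each feature by its least-squares residual on
  the sex indicator plus the feature's grand mean; with sex as the only
  adjustment covariate the pairwise-interaction model reduces to this
  additive term. Training slopes are reused for held-out data.
* Standardization is z-scoring with training moments; zero-variance
  features are dropped with a warning.

## Validation procedures

* **Stability:** stratified five-fold cross-validation over the
  normotensive + hypertensive subjects only (each held out exactly
  once; intermediates remain in every training set, mirroring their
  role of providing variance without driving the contrast). Per fold,
  the pipeline is refit from raw data and held-out subjects are scored
  through the attachment path; RMSD is computed against the full-data
  model's scores, with mean RMSD < 0.2 the acceptability bound.
* **Separation:** two-sided Welch t-test (the unequal-variance form is
  the safer default when group spreads differ) plus ROC over all score
  thresholds, trapezoid AUC, and the Youden-optimal threshold (ties to
  the lower threshold).
* **Comparison model:** the pipeline refit after excluding a named
  feature list (default use case: the nine left atrial strain
  indices), reported side by side with the full model's ROC.
* **Clinical patterns:** variables min–max rescaled to [0, 1] and
  smoothed against the score with LOWESS (local linear, span 0.5);
  score bins for the heat map follow the fixed rule — score ≤ 0.25 is
  Group 1, then consecutive groups of 20 subjects by ascending score up
  to group 10, residual subjects merging into the last group.
* **Intervention analysis:** ordinary least squares of the score change
  on the ventilatory-threshold change, Pearson correlation with gym
  attendance, Welch t-test of compliant (≥80% of 48 planned sessions)
  versus non-compliant subjects, and the group-level paired pre/post
  test. Follow-up visits are scored against the baseline-fitted model
  so both visits share one scale.

## Synthetic cohort

The generator emulates a ~400-subject young-adult cohort spanning
optimal to severely elevated blood pressure. Per subject it draws a
latent remodelling pseudotime t ∈ [0, 1] from the mixture 40%
Beta(2, 8) + 40% Uniform + 20% Beta(8, 2), chosen so the SBP thresholds
carve out normotensive/intermediate/hypertensive strata of realistic
size (roughly 25/50/25% at the defaults). Standardized features are

X = B·z + s·D·r(t) + sex shift + ε,

with six unit-norm background factor loadings B (factor scores
z ~ N(0, 1)), three unit-norm disease loadings D planted on clinically
signed variable groups (left atrial structure/function, LV volumes,
Doppler/diastolic indices — e.g. LA strain falls, E/e′ rises), a
monotone response r(t) ∝ g(t) = (t² + t)/2 (nonlinear remodelling; a
linear response is available), and ε ~ N(0, 0.3²). Features are then
mapped to clinical scales using published cohort means/SDs where
available, and 3% of cells are deleted completely at random.

Two calibration choices matter and are deliberate:

* **Disease amplitude is expressed in units of its cohort SD**, so the
  default `disease_effect_scale = 1.5` means the disease factors carry
  1.5× the standard deviation of a background factor. Without this
  normalization the enriched variance inside the hypertensive stratum
  sits far below the covariance-estimation noise floor at p ≈ n and no
  contrast parameter can recover it — a regime in which the method (or
  any method) is uninformative.
* **SBP is a noisy marker of severity**: SBP = 108 + 70·t + N(0, 12²)
  mmHg. The sizeable noise term makes each blood-pressure stratum span
  a range of true severity, which is what gives the hypertensive group
  internal disease-enriched variance for the contrast to find — and
  matches the broad within-stratum score distributions seen in real
  cohorts. Medication probability is 0.05 + 0.5·t (≈30% of the cohort
  on treatment).

The optional follow-up visit reduces pseudotime by
`exercise_effect · compliance` (floored at 0), regenerates features
with the subject's own background factor scores and fresh measurement
noise, and emits surrogate fitness columns: gym attendance
(≈ compliance × 48 sessions) and ventilatory-threshold change
(3·compliance − 0.5 ± 0.6 ml/kg/min). Compliance is bimodal — half the
participants near full attendance (Uniform(0.8, 1)), half disengaged
(Uniform(0, 0.6)) — as exercise-trial attendance tends to be. The
intervention sub-study enrols 60 subjects with baseline SBP in
[140, 160) mmHg: a hypertension-prevention exercise trial targets
elevated/stage-1 blood pressure below the established-hypertension
threshold, and this range also keeps compliant subjects from being
pushed into the centroid's noise-floor zone where score changes fold.

**What the generator does not emulate:** measurement-device and
inter-vendor differences, informative missingness, multi-site batch
effects, non-Gaussian measurement error, and any joint distribution
features of real echo variables beyond a low-rank factor structure —
the true joint distribution of these variables is unknown, and the
factor construction is an assumption. Passing tests therefore show the
pipeline recovers the structure it assumes at realistic noise levels,
not that real cohorts satisfy those assumptions.

## Problem sizes used in the test suite

Simulation-based checks run at the cohort sizes the science dictates,
kept modest deliberately: parameter recovery and cross-validation on
n = 400 cohorts (20 seeds / 5 folds), intervention power at the
60-subject sub-study size nested in n = 400 (20 seeds per arm), the
feature-exclusion comparison at n = 300 (20 seeds), and the relevance
precision check on a 40-feature equal-magnitude planted design at
n = 500. Monte-Carlo property checks (Hopkins null behaviour, follow-up
ordering) use 200–500 replicates.

## Known limitations

* With strong background suppression the retained subspace is often
  one-dimensional; branch detection or multiple trajectories are out of
  scope.
* The score floor near the healthy centroid compresses genuine change
  among the healthiest subjects (see held-out scoring above); analyses
  of change should focus on subjects away from the floor.
* The α selector assumes the grid brackets the feasible range; if no
  grid point retains a positive eigenvalue the fit fails loudly.
* Cross-validated stability treats the full-data model as the
  reference; it measures reproducibility of the score, not external
  validity.
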