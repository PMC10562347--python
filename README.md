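# remodelscore

Contrastive trajectory inference for echocardiographic assessment of
hypertensive cardiac remodelling in young adults.

## The problem

Early hypertension-related cardiac remodelling is spread across many
echocardiographic parameters — left atrial strain and volumes, left
ventricular volumes, Doppler and tissue-Doppler indices — long before
overt left ventricular hypertrophy appears. Clinicians and trialists
need a single quantitative summary of where an individual sits on the
remodelling spectrum, derivable from one cross-sectional scan.
`remodelscore` builds that summary: a per-subject **cardiac remodelling
score** in [0, 1], where 0 marks the healthy state and 1 the most
advanced disease state in the fitting cohort.

## The method

Given a subjects × variables table (68 variables: age, body mass index
and 66 echocardiography measurements) with sex, resting systolic blood
pressure (SBP) and anti-hypertensive medication status:

1. **Cleaning.** Subjects, then variables, with more than 30% missing
   data are excluded; remaining gaps are imputed by trimmed scores
   regression (iterative PCA-model regression). Features are adjusted
   for sex with additive linear models and standardized.
2. **Strata.** Subjects are classed as *normotensive* (SBP < 120 mmHg,
   off medication), *hypertensive* (SBP ≥ 160 mmHg) or *intermediate*.
3. **Contrastive PCA.** The subspace enriched in the hypertensive group
   is found by eigendecomposition of

   C<sub>hyper</sub> − α · C<sub>normo</sub>

   with Ledoit–Wolf-shrunk group covariances. The contrast parameter α
   is selected automatically as the subspace maximizing the clustering
   tendency of the projected hypertensive subjects (Hopkins statistic
   in excess of a dimension-matched Gaussian null). Components are kept
   until 80% of the positive contrast-eigenvalue mass is covered.
   Intermediate subjects are projected but never enter the contrast.
4. **Trajectory score.** A minimum spanning tree is built over all
   projected subjects plus a pseudo-node at the normotensive centroid.
   Each subject's raw score is the path distance along the tree to the
   centroid; min–max normalization over the fitting cohort maps this to
   [0, 1]. Held-out subjects attach by an edge to their nearest tree
   node and are normalized with the training bounds.
5. **Relevance.** Each variable's contribution to the enriched subspace
   is Σ<sub>k</sub> |w<sub>fk</sub>| λ<sub>k</sub><sup>+</sup>,
   normalized to sum to one.

Validation utilities cover five-fold cross-validated score stability
(RMSD between held-out and full-model scores, acceptable below 0.2),
normotensive/hypertensive separation (Welch t-test, ROC with
Youden-optimal threshold), a reduced-model comparison (e.g. without the
nine left atrial strain indices), score-bin heat-map tables, LOWESS
variable trajectories along the score, and the exercise-intervention
change analysis.

A calibrated synthetic cohort generator with full ground truth
(`simulate_cohort`, `simulate_followup`) drives all tests: it plants a
latent remodelling pseudotime on clinically signed feature groups over
shared background variance, links SBP and medication use to the
pseudotime, and can produce a post-intervention visit whose pseudotime
is reduced in proportion to exercise compliance.

## Worked example

```python
import remodelscore as rs

cohort, truth = rs.simulate_cohort(rs.SimConfig(n_subjects=400, seed=42))
model = rs.fit_pipeline(cohort, seed=1)
cv = rs.crossval_stability(cohort, n_folds=5, seed=1)
roc = rs.separation_test(model.scores["score"].to_numpy(),
                         model.scores["group"].to_numpy())
```

Running `python examples/02_fit_and_score.py` and
`python examples/03_validate_stability.py` prints:

```
selected contrast parameter alpha = 6.61
retained components: 1
score by blood-pressure group (mean +/- SD):
   hypertensive: 0.65 +/- 0.21  (n=98)
   intermediate: 0.24 +/- 0.21  (n=203)
   normotensive: 0.04 +/- 0.04  (n=99)
Spearman rho(score, planted pseudotime) = 0.897

mean RMSD = 0.0375 +/- 0.0058 (acceptable, bound 0.2)
AUC = 0.996
optimal threshold (Youden) = 0.190: sensitivity 98.0%, specificity 99.0%
```

The score orders the blood-pressure strata as expected, recovers the
planted disease pseudotime (ρ = 0.90), is stable under cross-validation
(mean RMSD well below the 0.2 acceptability bound), and separates the
contrast groups almost perfectly on this synthetic cohort. The
remaining examples cover simulation (`01`), clinical pattern tables
(`04`) and the exercise-intervention analysis (`05`).

A thin CLI mirrors the library:

```bash
remodelscore simulate --seed 42 --out cohort.csv --truth truth.csv
remodelscore fit      --cohort cohort.csv --out-dir results/ --seed 1
remodelscore validate --cohort cohort.csv --out-dir results/ --seed 1
remodelscore run-all  --seed 42 --out-dir results/
```

The cohort CSV schema is one row per (subject, visit):
`subject_id, visit, sex, sbp, on_medication, group`, optional
`active_days, vt_change` at follow-up, then the feature columns;
empty cells are missing values.

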