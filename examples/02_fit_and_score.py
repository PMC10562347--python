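"""Fit the remodelling-score model end to end and inspect the result.

The pipeline cleans the table (missingness exclusion, TSR imputation,
sex adjustment, standardization), contrasts hypertensive against
normotensive covariance (cPCA, automatic contrast parameter), builds
the minimum spanning tree anchored at the normotensive centroid, and
normalizes the per-subject path distances into a [0, 1] score.
"""

import warnings

from scipy.stats import spearmanr

import remodelscore as rs

warnings.filterwarnings("ignore", category=RuntimeWarning)

cohort, truth = rs.simulate_cohort(rs.SimConfig(n_subjects=400, seed=42))
model = rs.fit_pipeline(cohort, seed=1)

print(f"selected contrast parameter alpha = {model.subspace.alpha:.2f}")
print(f"retained components: {model.subspace.n_components}")
print("score by blood-pressure group (mean +/- SD):")
for group, block in model.scores.groupby("group"):
    print(f"  {group:>13}: {block['score'].mean():.2f} +/- {block['score'].std():.2f}  (n={len(block)})")

rho = spearmanr(model.scores["score"], truth.pseudotime).statistic
print(f"Spearman rho(score, planted pseudotime) = {rho:.3f}")

top = model.relevance.ranking.head(8)
print("top contributing variables (relevance share):")
for name, row in top.iterrows():
    print(f"  {name:<28} {row['relevance']:.3f}")
n80 = len(model.relevance.top_set)
print(f"{n80} variables carry >80% of the enriched variance")

# A higher score marks a subject further along the hypertensive
# remodelling trajectory; 0 is the healthiest fit-cohort subject, 1 the
# most remodelled.
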