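"""Internal validation: cross-validated score stability, group
separation (t-test + ROC with Youden-optimal threshold), and the
reduced-feature-set comparison model.

Stability follows the repeated-vs-original construction: the model is
refit on each training fold, held-out normotensive/hypertensive
subjects are re-scored through the held-out path, and the RMSD between
those repeated scores and the full-data model's scores for the same
individuals is computed per fold; a mean RMSD below 0.2 counts as
acceptable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .cohort import GROUP_HYPERTENSIVE, GROUP_NORMOTENSIVE, CohortTable
from .config import ModelParams, PreprocessParams
from .pipeline import FittedPipeline, fit_pipeline
from .preprocess import classify_groups


@dataclass
class CrossValReport:
    fold_assignments: pd.DataFrame    # subject_id, fold
    pairs: pd.DataFrame               # subject_id, fold, original_score, heldout_score
    rmsd_per_fold: np.ndarray
    rmsd_mean: float
    rmsd_sd: float
    threshold: float
    passed: bool


@dataclass
class RocReport:
    auc: float
    curve: pd.DataFrame               # threshold, sensitivity, specificity
    optimal_threshold: float
    sensitivity: float
    specificity: float
    t_statistic: float
    t_test_p: float
    group_means: dict = field(default_factory=dict)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-squared deviation between two score vectors."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("score vectors must have equal length")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def crossval_stability(
    cohort: CohortTable,
    preprocess_params: PreprocessParams | None = None,
    model_params: ModelParams | None = None,
    n_folds: int = 5,
    rmsd_threshold: float = 0.2,
    seed: int = 0,
) -> CrossValReport:
    """Stratified k-fold stability of the remodelling score.

    Folds are stratified over the normotensive + hypertensive subjects
    only (each held out exactly once); intermediate and unassigned
    subjects stay in every training set — they add variance to the
    trajectory but never enter the covariance contrast or the holdout.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    preprocess_params = preprocess_params or PreprocessParams()
    full = fit_pipeline(cohort, preprocess_params, model_params, seed=seed)
    full_scores = full.scores.set_index("subject_id")["score"]

    classified = classify_groups(cohort, preprocess_params)
    groups = classified.groups.to_numpy()
    contrast_mask = np.isin(groups, [GROUP_NORMOTENSIVE, GROUP_HYPERTENSIVE])
    contrast_ids = classified.data.loc[contrast_mask, "subject_id"].to_numpy()
    contrast_labels = groups[contrast_mask]
    if min((contrast_labels == g).sum() for g in (GROUP_NORMOTENSIVE, GROUP_HYPERTENSIVE)) < n_folds:
        raise ValueError("both contrast groups need at least n_folds members")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment_rows, pair_rows, fold_rmsds = [], [], []
    for fold, (_, test_idx) in enumerate(skf.split(contrast_ids, contrast_labels)):
        heldout_ids = set(contrast_ids[test_idx])
        is_held = classified.data["subject_id"].isin(heldout_ids).to_numpy()
        training = cohort.subset(~is_held)
        holdout = cohort.subset(is_held)
        fold_model = fit_pipeline(training, preprocess_params, model_params, seed=seed)
        held_scores = fold_model.score_new(holdout).set_index("subject_id")["score"]
        for sid in sorted(heldout_ids):
            assignment_rows.append({"subject_id": sid, "fold": fold})
            pair_rows.append(
                {
                    "subject_id": sid,
                    "fold": fold,
                    "original_score": float(full_scores[sid]),
                    "heldout_score": float(held_scores[sid]),
                }
            )
        pairs = [r for r in pair_rows if r["fold"] == fold]
        fold_rmsds.append(
            rmsd(
                np.array([r["original_score"] for r in pairs]),
                np.array([r["heldout_score"] for r in pairs]),
            )
        )

    fold_rmsds = np.array(fold_rmsds)
    return CrossValReport(
        fold_assignments=pd.DataFrame(assignment_rows),
        pairs=pd.DataFrame(pair_rows),
        rmsd_per_fold=fold_rmsds,
        rmsd_mean=float(fold_rmsds.mean()),
        rmsd_sd=float(fold_rmsds.std(ddof=1)),
        threshold=rmsd_threshold,
        passed=bool(fold_rmsds.mean() <= rmsd_threshold),
    )


def separation_test(scores: np.ndarray, groups: np.ndarray) -> RocReport:
    """Normotensive-vs-hypertensive separation of the score.

    Two-sided Welch t-test plus ROC over all score thresholds
    (trapezoid AUC); the optimal threshold maximizes Youden's
    J = sensitivity + specificity − 1, ties resolved toward the lower
    threshold.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    normo = scores[groups == GROUP_NORMOTENSIVE]
    hyper = scores[groups == GROUP_HYPERTENSIVE]
    if len(normo) == 0 or len(hyper) == 0:
        raise ValueError("both contrast groups must be non-empty")
    pooled = np.concatenate([normo, hyper])
    if np.ptp(pooled) == 0:
        raise ValueError("constant scores: ROC undefined")

    t_stat, p = stats.ttest_ind(hyper, normo, equal_var=False)
    y = np.concatenate([np.zeros(len(normo)), np.ones(len(hyper))])
    fpr, tpr, thresholds = roc_curve(y, pooled)
    roc_auc = float(_trapezoid_auc(fpr, tpr))
    sens, spec = tpr, 1.0 - fpr
    j = sens + spec - 1.0
    best_j = j.max()
    candidates = np.flatnonzero(np.isclose(j, best_j))
    # roc_curve thresholds descend; the last tied index is the lowest threshold
    best = candidates[-1]
    curve = pd.DataFrame(
        {"threshold": thresholds, "sensitivity": sens, "specificity": spec}
    )
    return RocReport(
        auc=roc_auc,
        curve=curve,
        optimal_threshold=float(thresholds[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        t_statistic=float(t_stat),
        t_test_p=float(p),
        group_means={
            "normotensive": (float(normo.mean()), float(normo.std(ddof=1)) if len(normo) > 1 else 0.0),
            "hypertensive": (float(hyper.mean()), float(hyper.std(ddof=1)) if len(hyper) > 1 else 0.0),
        },
    )


@dataclass
class VariantComparison:
    variant_model: FittedPipeline
    variant_roc: RocReport
    baseline_roc: RocReport


def variant_model(
    cohort: CohortTable,
    excluded_features: list[str],
    preprocess_params: PreprocessParams | None = None,
    model_params: ModelParams | None = None,
    seed: int = 0,
    baseline: FittedPipeline | None = None,
) -> VariantComparison:
    """Refit the full pipeline on a reduced feature set (e.g. without
    the left-atrial strain indices) and compare ROC reports side by
    side with the all-features model."""
    unknown = [f for f in excluded_features if f not in cohort.feature_names]
    if unknown:
        raise ValueError(f"excluded features not in the cohort: {unknown}")
    if len(cohort.feature_names) - len(excluded_features) < 3:
        raise ValueError("exclusion leaves fewer than 3 features")
    if baseline is None:
        baseline = fit_pipeline(cohort, preprocess_params, model_params, seed=seed)
    reduced = cohort.drop_features(excluded_features) if excluded_features else cohort
    variant = fit_pipeline(reduced, preprocess_params, model_params, seed=seed)
    return VariantComparison(
        variant_model=variant,
        variant_roc=separation_test(
            variant.scores["score"].to_numpy(), variant.scores["group"].to_numpy()
        ),
        baseline_roc=separation_test(
            baseline.scores["score"].to_numpy(), baseline.scores["group"].to_numpy()
        ),
    )
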