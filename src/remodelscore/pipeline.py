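"""End-to-end model: cleaning → feature screen → cPCA → MST score.

``fit_pipeline`` runs the whole chain on a baseline cohort and returns a
``FittedPipeline`` that can score held-out or follow-up subjects on the
training scale (training preprocessing parameters, training loadings,
nearest-node MST attachment, training normalization bounds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import GROUP_HYPERTENSIVE, GROUP_NORMOTENSIVE, CohortTable
from .config import ModelParams, PreprocessParams
from .cpca import (
    ContrastiveSubspace,
    FeatureRelevance,
    choose_n_components,
    cpca,
    feature_relevance,
    select_alpha,
)
from .features import FeatureSelectionResult, select_features
from .preprocess import StandardizationModel, classify_groups, preprocess_cohort
from .trajectory import TrajectoryModel, build_trajectory, score, score_new_projections


@dataclass
class FittedPipeline:
    preprocessing: StandardizationModel
    selection: FeatureSelectionResult
    subspace: ContrastiveSubspace
    alpha_diagnostics: pd.DataFrame
    trajectory: TrajectoryModel
    scores: pd.DataFrame          # subject_id, visit, group, raw_distance, score
    relevance: FeatureRelevance
    preprocess_params: PreprocessParams
    model_params: ModelParams

    def score_new(self, cohort: CohortTable) -> pd.DataFrame:
        """Score held-out subjects with training parameters throughout."""
        classified = classify_groups(cohort, self.preprocess_params)
        X = self.preprocessing.transform(classified)
        frame = pd.DataFrame(X, columns=self.preprocessing.feature_names)
        proj = self.subspace.project(frame[self.subspace.feature_names])
        s = score_new_projections(self.trajectory, proj)
        return pd.DataFrame(
            {
                "subject_id": classified.data["subject_id"].to_numpy(),
                "visit": classified.data["visit"].to_numpy(),
                "group": classified.data["group"].to_numpy(),
                "score": s,
            }
        )


def fit_pipeline(
    cohort: CohortTable,
    preprocess_params: PreprocessParams | None = None,
    model_params: ModelParams | None = None,
    seed: int = 0,
) -> FittedPipeline:
    """Fit the full remodelling-score model on a baseline cohort.

    Steps: missingness exclusion, TSR imputation, group classification,
    sex adjustment, standardization; neighbourhood-variance feature
    screen; contrastive PCA of hypertensive vs normotensive covariance
    with automatic α; MST trajectory anchored at the normotensive
    centroid; min–max score normalization. Intermediate (and
    unassigned) subjects contribute variance to the trajectory but not
    to the covariance contrast.
    """
    preprocess_params = preprocess_params or PreprocessParams()
    model_params = model_params or ModelParams()
    model_params.validate()

    clean, preprocessing, _report = preprocess_cohort(cohort, preprocess_params)
    groups = clean.groups.to_numpy()
    normo = groups == GROUP_NORMOTENSIVE
    hyper = groups == GROUP_HYPERTENSIVE
    if normo.sum() < 3 or hyper.sum() < 3:
        raise ValueError(
            f"need at least 3 normotensive and 3 hypertensive subjects "
            f"(got {int(normo.sum())} / {int(hyper.sum())})"
        )

    selection = select_features(
        clean.features, model_params.k_neighbours, model_params.keep_fraction
    )
    feats = clean.features[selection.retained]
    target = feats.loc[hyper]
    background = feats.loc[normo]

    alpha, diagnostics = select_alpha(
        target,
        background,
        grid=model_params.alpha_grid,
        n_components="auto",
        variance_threshold=model_params.variance_threshold,
        max_components=model_params.max_components,
        shrinkage=model_params.shrinkage,
        sampling_fraction=model_params.hopkins_fraction,
        n_resamples=model_params.hopkins_resamples,
        seed=seed,
    )
    probe = cpca(target, background, alpha, model_params.max_components, model_params.shrinkage)
    k = choose_n_components(
        probe.contrast_eigenvalues, model_params.variance_threshold, model_params.max_components
    )
    subspace = cpca(
        target, background, alpha, k, model_params.shrinkage, model_params.variance_threshold
    )

    projections = subspace.project(feats)
    trajectory = build_trajectory(projections, normo)
    scoreset = score(trajectory)
    scores = pd.DataFrame(
        {
            "subject_id": clean.data["subject_id"].to_numpy(),
            "visit": clean.data["visit"].to_numpy(),
            "group": groups,
            "raw_distance": trajectory.raw_distances,
            "score": scoreset.scores,
        }
    )
    return FittedPipeline(
        preprocessing=preprocessing,
        selection=selection,
        subspace=subspace,
        alpha_diagnostics=diagnostics,
        trajectory=trajectory,
        scores=scores,
        relevance=feature_relevance(subspace),
        preprocess_params=preprocess_params,
        model_params=model_params,
    )
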