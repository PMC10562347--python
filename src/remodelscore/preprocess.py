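"""Data-cleaning chain applied before the contrastive model.

Order: missingness exclusion (subjects first, then features, both with a
strict >30% rule) → trimmed-scores-regression imputation → blood-pressure
group classification → additive sex adjustment → z-score standardization.
All fitted parameters are retained in a ``StandardizationModel`` so that
held-out subjects are transformed with *training* parameters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (
    GROUP_HYPERTENSIVE,
    GROUP_INTERMEDIATE,
    GROUP_NORMOTENSIVE,
    GROUP_UNASSIGNED,
    CohortTable,
    SchemaError,
)
from .config import PreprocessParams

logger = logging.getLogger(__name__)


@dataclass
class StandardizationModel:
    """Training-cohort preprocessing parameters, reusable on new data."""

    feature_names: list[str]
    impute_means: pd.Series | None = None      # training column means (imputation fallback)
    sex_slopes: pd.Series | None = None        # per-feature OLS slope on sex
    sex_mean: float | None = None              # training mean of the sex indicator
    means: pd.Series | None = None             # post-adjustment feature means
    sds: pd.Series | None = None               # post-adjustment feature SDs
    tsr_basis: np.ndarray | None = None        # training PCA basis (features × rank), z-scale
    dropped_features: list[str] = field(default_factory=list)

    def transform(self, cohort: CohortTable) -> np.ndarray:
        """Adjust, standardize and impute new subjects with training
        parameters only; returns the standardized feature matrix.

        Missing cells are reconstructed by the conditional mean under
        the training PCA model (least-squares scores from the observed
        coordinates), the out-of-sample analogue of the trimmed-scores
        imputation used at fit time; without a stored basis they fall
        back to training column means.
        """
        missing = [f for f in self.feature_names if f not in cohort.feature_names]
        if missing:
            raise SchemaError(f"new cohort lacks model features: {missing}")
        X = cohort.data[self.feature_names].to_numpy(dtype=float)
        nan_mask = np.isnan(X)
        if self.sex_slopes is not None:
            sex = cohort.data["sex"].to_numpy(dtype=float)
            slopes = self.sex_slopes[self.feature_names].to_numpy()
            X = X - np.outer(sex - self.sex_mean, slopes)
        if self.means is not None:
            mu = self.means[self.feature_names].to_numpy()
            sd = self.sds[self.feature_names].to_numpy()
            X = (X - mu[None, :]) / sd[None, :]
        elif self.impute_means is not None:
            fill = self.impute_means[self.feature_names].to_numpy()
            X = np.where(nan_mask, fill[None, :], X)
            return X
        if not nan_mask.any():
            return X
        if self.tsr_basis is None:
            return np.where(nan_mask, 0.0, X)  # training mean in z-units
        V = self.tsr_basis
        out = X.copy()
        for i in np.flatnonzero(nan_mask.any(axis=1)):
            obs = ~nan_mask[i]
            if not obs.any():
                out[i, :] = 0.0
                continue
            s, *_ = np.linalg.lstsq(V[obs], X[i, obs], rcond=None)
            out[i, ~obs] = V[~obs] @ s
        return out


def filter_missing(
    cohort: CohortTable, params: PreprocessParams | None = None
) -> tuple[CohortTable, pd.DataFrame]:
    """Exclude subjects, then features, with strictly more than the
    allowed missing fraction (default 0.30: exactly 30% is retained)."""
    params = params or PreprocessParams()
    X = cohort.features.to_numpy(dtype=float)
    report_rows = []

    subject_frac = np.isnan(X).mean(axis=1)
    drop_subj = subject_frac > params.subject_missing_max
    for sid, frac in zip(cohort.data.loc[drop_subj, "subject_id"], subject_frac[drop_subj]):
        report_rows.append({"kind": "subject", "id": sid, "missing_fraction": float(frac)})
    kept = cohort.subset(~drop_subj)
    if len(kept) == 0:
        raise ValueError("all subjects excluded by the missingness rule")

    X2 = kept.features.to_numpy(dtype=float)
    feature_frac = np.isnan(X2).mean(axis=0)
    drop_feat = feature_frac > params.feature_missing_max
    for name, frac in zip(np.array(kept.feature_names)[drop_feat], feature_frac[drop_feat]):
        report_rows.append({"kind": "feature", "id": name, "missing_fraction": float(frac)})
    if drop_feat.any():
        kept = kept.drop_features(list(np.array(kept.feature_names)[drop_feat]))

    report = pd.DataFrame(report_rows, columns=["kind", "id", "missing_fraction"])
    return kept, report


def _choose_rank(Z: np.ndarray, params: PreprocessParams) -> int:
    """Rank for the TSR PCA model: smallest k explaining the variance
    target on complete rows, hard-capped."""
    if params.tsr_components is not None:
        return int(params.tsr_components)
    complete = Z[~np.isnan(Z).any(axis=1)]
    cap = int(min(params.tsr_component_cap, Z.shape[1] - 1, max(1, Z.shape[0] - 1)))
    if complete.shape[0] < 3:
        return cap
    centred = complete - complete.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    ratio = np.cumsum(s**2) / np.sum(s**2)
    k = int(np.searchsorted(ratio, params.tsr_var_target) + 1)
    return int(min(max(1, k), cap, complete.shape[0] - 1))


def impute_tsr(
    cohort: CohortTable, params: PreprocessParams | None = None
) -> CohortTable:
    """Trimmed-scores-regression imputation: iterative PCA-model
    regression of the missing cells.

    Missing cells start at column means; the loop alternates a rank-k
    PCA fit on the completed matrix with replacement of the missing
    cells by their PCA reconstruction, until the largest absolute cell
    change falls below ``tsr_tol``. Observed cells are never altered.
    Internally the matrix is z-scored with observed-cell moments so
    large-scale variables do not dominate the PCA model.
    """
    params = params or PreprocessParams()
    X = cohort.features.to_numpy(dtype=float).copy()
    nan_mask = np.isnan(X)
    if not nan_mask.any():
        return cohort

    col_mean = np.nanmean(X, axis=0)
    col_sd = np.nanstd(X, axis=0, ddof=0)
    col_sd[col_sd == 0] = 1.0
    Z = (X - col_mean[None, :]) / col_sd[None, :]
    k = _choose_rank(Z, params)

    Z_filled = np.where(nan_mask, 0.0, Z)  # column mean in z-units
    delta = np.inf
    for _ in range(params.tsr_max_iter):
        mu = Z_filled.mean(axis=0)
        centred = Z_filled - mu[None, :]
        U, s, Vt = np.linalg.svd(centred, full_matrices=False)
        recon = (U[:, :k] * s[:k]) @ Vt[:k] + mu[None, :]
        new = np.where(nan_mask, recon, Z_filled)
        delta = float(np.max(np.abs(new - Z_filled)[nan_mask]))
        Z_filled = new
        if delta < params.tsr_tol:
            break
    else:
        warnings.warn(
            f"TSR imputation did not converge in {params.tsr_max_iter} "
            f"iterations (last max cell change {delta:.3g})",
            RuntimeWarning,
        )

    imputed = Z_filled * col_sd[None, :] + col_mean[None, :]
    result = np.where(nan_mask, imputed, X)
    logger.info(
        "TSR imputation: %.2f%% of cells imputed (rank %d)",
        100.0 * nan_mask.mean(),
        k,
    )
    out = cohort.copy()
    out.data[cohort.feature_names] = result
    return out


def classify_groups(
    cohort: CohortTable, params: PreprocessParams | None = None
) -> CohortTable:
    """Assign blood-pressure strata: normotensive (SBP < 120 mmHg and
    off anti-hypertensive medication), hypertensive (SBP >= 160 mmHg),
    intermediate otherwise; missing SBP -> unassigned."""
    params = params or PreprocessParams()
    sbp = cohort.data["sbp"].to_numpy(dtype=float)
    med = cohort.data["on_medication"].to_numpy(dtype=float)
    group = np.full(len(cohort), GROUP_INTERMEDIATE, dtype=object)
    group[(sbp < params.sbp_normo_max) & (med == 0)] = GROUP_NORMOTENSIVE
    group[sbp >= params.sbp_hyper_min] = GROUP_HYPERTENSIVE
    group[np.isnan(sbp)] = GROUP_UNASSIGNED
    out = cohort.copy()
    out.data["group"] = group
    return out


def adjust_sex(cohort: CohortTable) -> tuple[CohortTable, StandardizationModel]:
    """Remove additive sex effects feature by feature.

    Each feature is replaced by its least-squares residual on the sex
    indicator plus the feature's grand mean, so per-feature means are
    preserved and the post-adjustment slope on sex is exactly zero.
    Slopes are stored for adjusting held-out subjects with training
    coefficients. A single-sex cohort is returned unchanged (warning).
    """
    X = cohort.features.to_numpy(dtype=float)
    sex = cohort.data["sex"].to_numpy(dtype=float)
    model = StandardizationModel(feature_names=list(cohort.feature_names))
    if np.unique(sex).size < 2:
        warnings.warn("single-sex cohort: sex adjustment skipped", RuntimeWarning)
        model.sex_slopes = pd.Series(0.0, index=cohort.feature_names)
        model.sex_mean = float(sex.mean()) if len(sex) else 0.0
        return cohort.copy(), model

    sex_c = sex - sex.mean()
    slopes = (sex_c @ X) / (sex_c @ sex_c)
    adjusted = X - np.outer(sex_c, slopes)
    model.sex_slopes = pd.Series(slopes, index=cohort.feature_names)
    model.sex_mean = float(sex.mean())
    out = cohort.copy()
    out.data[cohort.feature_names] = adjusted
    return out, model


def standardize(
    cohort: CohortTable, model: StandardizationModel | None = None
) -> tuple[CohortTable, StandardizationModel]:
    """z-score features; with a supplied model, its training mean/SD are
    used (held-out data). Zero-variance features are dropped (warning).
    """
    if model is not None and model.means is not None:
        out = cohort.copy()
        if model.dropped_features:
            out = out.drop_features([f for f in model.dropped_features if f in out.feature_names])
        mu = model.means[out.feature_names].to_numpy()
        sd = model.sds[out.feature_names].to_numpy()
        X = out.features.to_numpy(dtype=float)
        out.data[out.feature_names] = (X - mu[None, :]) / sd[None, :]
        return out, model

    X = cohort.features.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    constant = sd == 0
    names = np.array(cohort.feature_names)
    out = cohort.copy()
    if constant.any():
        warnings.warn(
            f"dropping zero-variance features: {list(names[constant])}", RuntimeWarning
        )
        out = out.drop_features(list(names[constant]))
        X = out.features.to_numpy(dtype=float)
        mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    out.data[out.feature_names] = (X - mu[None, :]) / sd[None, :]
    fitted = StandardizationModel(
        feature_names=list(out.feature_names),
        means=pd.Series(mu, index=out.feature_names),
        sds=pd.Series(sd, index=out.feature_names),
        dropped_features=list(names[constant]),
    )
    return out, fitted


def preprocess_cohort(
    cohort: CohortTable, params: PreprocessParams | None = None
) -> tuple[CohortTable, StandardizationModel, pd.DataFrame]:
    """Full cleaning chain; returns the standardized cohort, the fitted
    transform for held-out data, and the exclusion report."""
    params = params or PreprocessParams()
    params.validate()
    kept, report = filter_missing(cohort, params)
    imputed = impute_tsr(kept, params)
    classified = classify_groups(imputed, params)
    adjusted, sex_model = adjust_sex(classified)
    standardized, std_model = standardize(adjusted)
    Z = standardized.features.to_numpy(dtype=float)
    rank = _choose_rank(Z, params)
    _, _, Vt = np.linalg.svd(Z - Z.mean(axis=0), full_matrices=False)
    model = StandardizationModel(
        feature_names=list(standardized.feature_names),
        impute_means=pd.Series(
            np.nanmean(kept.features.to_numpy(dtype=float), axis=0), index=kept.feature_names
        ),
        sex_slopes=sex_model.sex_slopes,
        sex_mean=sex_model.sex_mean,
        means=std_model.means,
        sds=std_model.sds,
        tsr_basis=Vt[:rank].T,
        dropped_features=std_model.dropped_features,
    )
    return standardized, model, report
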