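"""Clinical-validation analytics for the remodelling score.

Three views: (1) score-bin groups and the per-bin variable-mean
heat-map table; (2) min–max-rescaled variable trajectories along the
score with a local-regression smooth; (3) the exercise-intervention
change analysis (regression of the score change on
ventilatory-threshold change, correlation with gym attendance,
compliant-vs-non-compliant comparison, and the group-level pre/post
paired test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

import statsmodels.api as sm


@dataclass
class PatternTable:
    rescaled: pd.DataFrame     # per-variable values min-max rescaled to [0, 1]
    smoothed: pd.DataFrame     # 'score' column + one smoothed column per variable
    bins: np.ndarray           # heat-map bin label per subject
    heatmap: pd.DataFrame      # bin × variable mean of rescaled values


@dataclass
class InterventionSummary:
    slope_vt: float            # regression slope of delta_score on vt_change
    slope_vt_ci: tuple[float, float]
    slope_vt_p: float
    pearson_active_days: float
    pearson_active_days_p: float
    t_compliant: float | None
    p_compliant: float | None
    mean_delta_compliant: float | None
    mean_delta_noncompliant: float | None
    paired_t: float
    paired_p: float
    n: int
    warnings_: list[str] = field(default_factory=list)


def bin_subjects(
    scores: np.ndarray,
    low_score_max: float = 0.25,
    bin_size: int = 20,
    max_bins: int = 10,
) -> np.ndarray:
    """Heat-map grouping: every subject with score ≤ 0.25 is Group 1;
    the rest are sorted ascending by score and chunked into consecutive
    groups of 20, labelled 2, 3, …, capped at ``max_bins`` (residual
    subjects merge into the last group). Depends only on score ranks
    above the fixed cutoff."""
    scores = np.asarray(scores, dtype=float)
    bins = np.ones(len(scores), dtype=int)
    above = np.flatnonzero(scores > low_score_max)
    if above.size == 0:
        warnings.warn("no subjects above the Group-1 cutoff: single group", RuntimeWarning)
        return bins
    order = above[np.argsort(scores[above], kind="stable")]
    for rank, idx in enumerate(order):
        bins[idx] = min(2 + rank // bin_size, max_bins)
    return bins


def trajectory_patterns(
    values: pd.DataFrame,
    scores: np.ndarray,
    variables: list[str] | None = None,
    span: float = 0.5,
    low_score_max: float = 0.25,
    bin_size: int = 20,
    max_bins: int = 10,
) -> PatternTable:
    """Rescaled variable trajectories along the score.

    Each variable is min–max rescaled to [0, 1] and smoothed against
    the score with LOWESS (local linear regression, fraction ``span``),
    giving the line-graph table; bin means of the rescaled values give
    the heat-map table.
    """
    scores = np.asarray(scores, dtype=float)
    variables = list(variables) if variables is not None else list(values.columns)
    missing = [v for v in variables if v not in values.columns]
    if missing:
        raise ValueError(f"variables not present: {missing}")

    rescaled = {}
    for v in variables:
        x = values[v].to_numpy(dtype=float)
        rng_ = np.nanmax(x) - np.nanmin(x)
        if rng_ == 0:
            warnings.warn(f"variable {v!r} is constant: flat line", RuntimeWarning)
            rescaled[v] = np.zeros_like(x)
        else:
            rescaled[v] = (x - np.nanmin(x)) / rng_
    rescaled = pd.DataFrame(rescaled, index=values.index)

    order = np.argsort(scores, kind="stable")
    smoothed = pd.DataFrame({"score": scores[order]})
    for v in variables:
        fit = lowess(rescaled[v].to_numpy()[order], scores[order], frac=span, return_sorted=False)
        smoothed[v] = fit

    bins = bin_subjects(scores, low_score_max, bin_size, max_bins)
    heat = rescaled.groupby(bins).mean()
    heat.index.name = "bin"
    return PatternTable(rescaled=rescaled, smoothed=smoothed, bins=bins, heatmap=heat)


def intervention_analysis(
    records: pd.DataFrame, compliance_threshold: float = 0.8
) -> InterventionSummary:
    """Exercise-intervention change analysis.

    ``records`` needs columns: subject_id, baseline_score,
    followup_score, active_days, vt_change, compliant (bool; the ≥80%
    planned-sessions rule). delta_score = followup − baseline.
    Reports (a) OLS of delta_score on vt_change, (b) Pearson r of
    delta_score with active_days, (c) Welch t-test of delta_score
    compliant vs non-compliant, and the group-level paired pre/post
    comparison.
    """
    required = {"baseline_score", "followup_score", "active_days", "vt_change", "compliant"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"intervention records missing columns: {sorted(missing)}")
    records = records.dropna(subset=["baseline_score", "followup_score"])
    if len(records) < 3:
        raise ValueError("need at least 3 records with both visits")

    notes: list[str] = []
    delta = (records["followup_score"] - records["baseline_score"]).to_numpy(dtype=float)
    vt = records["vt_change"].to_numpy(dtype=float)
    days = records["active_days"].to_numpy(dtype=float)
    compliant = records["compliant"].to_numpy(dtype=bool)

    X = sm.add_constant(vt)
    ols = sm.OLS(delta, X).fit()
    ci = ols.conf_int(alpha=0.05)
    r, r_p = stats.pearsonr(delta, days)

    if compliant.all() or (~compliant).all():
        notes.append("all subjects on one side of the compliance rule: comparison skipped")
        t_c = p_c = mean_c = mean_nc = None
    else:
        t_c, p_c = stats.ttest_ind(delta[compliant], delta[~compliant], equal_var=False)
        t_c, p_c = float(t_c), float(p_c)
        mean_c = float(delta[compliant].mean())
        mean_nc = float(delta[~compliant].mean())
    paired_t, paired_p = stats.ttest_rel(
        records["followup_score"].to_numpy(dtype=float),
        records["baseline_score"].to_numpy(dtype=float),
    )
    for note in notes:
        warnings.warn(note, RuntimeWarning)
    return InterventionSummary(
        slope_vt=float(ols.params[1]),
        slope_vt_ci=(float(ci[1][0]), float(ci[1][1])),
        slope_vt_p=float(ols.pvalues[1]),
        pearson_active_days=float(r),
        pearson_active_days_p=float(r_p),
        t_compliant=t_c,
        p_compliant=p_c,
        mean_delta_compliant=mean_c,
        mean_delta_noncompliant=mean_nc,
        paired_t=float(paired_t),
        paired_p=float(paired_p),
        n=len(records),
        warnings_=notes,
    )


def build_intervention_records(
    baseline_scores: pd.DataFrame,
    followup_scores: pd.DataFrame,
    followup_cohort_data: pd.DataFrame,
    compliance_threshold_sessions: float = 0.8,
    planned_sessions: int = 48,
) -> pd.DataFrame:
    """Merge baseline and follow-up score tables with the intervention
    covariates (active_days, vt_change) into the analysis record set.
    Compliance = attended at least 80% of planned sessions."""
    base = baseline_scores.set_index("subject_id")["score"]
    fu = followup_scores.set_index("subject_id")["score"]
    cov = followup_cohort_data.set_index("subject_id")
    ids = [s for s in fu.index if s in base.index]
    rec = pd.DataFrame(
        {
            "subject_id": ids,
            "baseline_score": base[ids].to_numpy(),
            "followup_score": fu[ids].to_numpy(),
            "active_days": cov.loc[ids, "active_days"].to_numpy(dtype=float),
            "vt_change": cov.loc[ids, "vt_change"].to_numpy(dtype=float),
        }
    )
    rec["delta_score"] = rec["followup_score"] - rec["baseline_score"]
    rec["compliant"] = rec["active_days"] >= compliance_threshold_sessions * planned_sessions
    return rec
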