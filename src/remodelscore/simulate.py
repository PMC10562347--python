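"""Synthetic cohort generator with known ground truth.

The generator emulates the statistical structure the scoring pipeline
assumes in a young-adult blood-pressure cohort:

* a latent disease pseudotime ``t`` in [0, 1] per subject, drawn from a
  mixture (40% Beta(2,8), 40% Uniform(0,1), 20% Beta(8,2)) so that the
  blood-pressure thresholds later carve out normotensive / intermediate /
  hypertensive strata of realistic size;
* shared background factor variance affecting all subjects;
* disease-enriched variance expressed along ``t`` through a monotone
  response ``g(t) = (t^2 + t)/2`` (nonlinear remodelling; a linear
  response is available by config), planted on clinically signed feature
  supports (left atrial function, LV volumes, Doppler indices);
* additive per-feature sex shifts, Gaussian measurement noise;
* systolic blood pressure linear in ``t`` plus noise, and a medication
  probability increasing with ``t``;
* completely-at-random missingness.

A follow-up visit regenerates features from a compliance-reduced
pseudotime with fresh measurement noise, emitting gym-attendance and
ventilatory-threshold surrogate columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import (
    GROUP_UNASSIGNED,
    VISIT_BASELINE,
    VISIT_FOLLOWUP,
    CohortTable,
    SyntheticTruth,
)
from .config import ConfigError, SimConfig
from .variables import CALIBRATED_MOMENTS, DISEASE_FACTOR_SUPPORT, ECHO_VARIABLES

#: Planned supervised sessions in the 16-week programme (3 per week).
PLANNED_SESSIONS = 48


def _response(t: np.ndarray, kind: str) -> np.ndarray:
    """Monotone disease response g(t) mapping [0,1] -> [0,1]."""
    if kind == "linear":
        return t
    return (t**2 + t) / 2.0


def _draw_pseudotime(rng: np.random.Generator, n: int) -> np.ndarray:
    comp = rng.choice(3, size=n, p=[0.4, 0.4, 0.2])
    t = np.empty(n)
    t[comp == 0] = rng.beta(2, 8, size=(comp == 0).sum())
    t[comp == 1] = rng.uniform(0, 1, size=(comp == 1).sum())
    t[comp == 2] = rng.beta(8, 2, size=(comp == 2).sum())
    return t


def _unit_columns(m: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(m, axis=0)
    norms[norms == 0] = 1.0
    return m / norms


def _feature_names(config: SimConfig) -> list[str]:
    if config.n_features == len(ECHO_VARIABLES):
        return list(ECHO_VARIABLES)
    return [f"feature_{i + 1:03d}" for i in range(config.n_features)]


def _disease_loadings(
    rng: np.random.Generator, names: list[str], config: SimConfig
) -> np.ndarray:
    """Unit-norm disease loading columns on clinically signed supports.

    With the default 68-variable panel the factors sit on the left
    atrial, LV-volume and Doppler variable groups with fixed signs;
    otherwise each factor gets a random sparse support (~15% of
    features).
    """
    p, q = len(names), config.n_disease_factors
    loadings = np.zeros((p, q))
    index = {n: i for i, n in enumerate(names)}
    for k in range(q):
        template = DISEASE_FACTOR_SUPPORT[k % len(DISEASE_FACTOR_SUPPORT)] if names == ECHO_VARIABLES else None
        if template is not None:
            for name, sign in template.items():
                loadings[index[name], k] = sign * rng.uniform(0.5, 1.0)
        else:
            support = rng.choice(p, size=max(3, int(round(0.15 * p))), replace=False)
            loadings[support, k] = rng.choice([-1, 1], size=len(support)) * rng.uniform(0.5, 1.0, size=len(support))
    return _unit_columns(loadings)


def simulate_cohort(config: SimConfig) -> tuple[CohortTable, SyntheticTruth]:
    """Generate a baseline cohort and its planted ground truth.

    Deterministic given ``config.seed``. Features are produced on a
    standardized latent scale as

    ``X = B z_b + s · D r(t) + sex shift + noise``

    (B background loadings, D disease loadings, s the disease effect
    scale, r the response g(t) expressed in units of its cohort SD so
    that s is a disease-to-background variance ratio) and then mapped
    to clinical scales using published cohort means/SDs where
    available.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, names = config.n_subjects, _feature_names(config)
    p = len(names)

    t = _draw_pseudotime(rng, n)
    sex = rng.integers(0, 2, size=n)

    background = _unit_columns(rng.normal(size=(p, config.n_background_factors)))
    disease = _disease_loadings(rng, names, config)
    z_b = rng.normal(size=(n, config.n_background_factors))
    sex_effects = rng.normal(0.0, config.sex_effect_sd, size=p) if config.sex_effect_sd > 0 else np.zeros(p)
    exponents = np.ones(config.n_disease_factors)

    g = _response(t, config.response)
    factor_scores = g[:, None] ** exponents[None, :]          # n × q
    # express each factor amplitude in units of its cohort SD, so the
    # disease effect scale is directly comparable to the unit-variance
    # background factors (the disease-to-background variance ratio)
    response_scales = factor_scores.std(axis=0, ddof=0)
    response_scales[response_scales == 0] = 1.0
    factor_scores = factor_scores / response_scales[None, :]
    latent = (
        z_b @ background.T
        + config.disease_effect_scale * factor_scores @ disease.T
        + (sex[:, None] - 0.5) * sex_effects[None, :]
        + rng.normal(0.0, config.noise_sd, size=(n, p))
    )

    means = np.array([CALIBRATED_MOMENTS.get(f, (0.0, 1.0))[0] for f in names])
    sds = np.array([CALIBRATED_MOMENTS.get(f, (0.0, 1.0))[1] for f in names])
    X = means[None, :] + sds[None, :] * latent

    if config.missing_rate > 0:
        mask = rng.uniform(size=X.shape) < config.missing_rate
        X = np.where(mask, np.nan, X)

    sbp = config.sbp_intercept + config.sbp_slope * t + rng.normal(0.0, config.sbp_noise_sd, size=n)
    sbp = np.clip(sbp, 85.0, None)
    on_med = (rng.uniform(size=n) < np.clip(0.05 + 0.5 * t, 0.0, 0.95)).astype(int)

    ids = [f"S{i + 1:04d}" for i in range(n)]
    data = pd.DataFrame(
        {
            "subject_id": ids,
            "visit": VISIT_BASELINE,
            "sex": sex,
            "sbp": np.round(sbp, 2),
            "on_medication": on_med,
            "group": GROUP_UNASSIGNED,
        }
    )
    data[names] = X
    cohort = CohortTable(data, names)
    truth = SyntheticTruth(
        pseudotime=t,
        disease_loadings=pd.DataFrame(disease, index=names),
        background_loadings=pd.DataFrame(background, index=names),
        sex=sex,
        background_scores=z_b,
        sex_effects=sex_effects,
        response_exponents=exponents,
        response_scales=response_scales,
        subject_ids=ids,
    )
    return cohort, truth


def select_substudy(
    cohort: CohortTable,
    n: int = 60,
    sbp_range: tuple[float, float] = (140.0, 160.0),
    seed: int = 0,
) -> list[str]:
    """Pick the exercise-intervention sub-study participants.

    A hypertension-prevention exercise trial enrols young adults with
    elevated / stage-1 blood pressure, below the established-hypertension
    threshold; eligibility is therefore baseline SBP within
    ``sbp_range`` (default 140–160 mmHg), from which ``n`` subjects are
    sampled without replacement.
    """
    base = cohort.visit_rows(VISIT_BASELINE).data
    eligible = base.loc[
        (base["sbp"] >= sbp_range[0]) & (base["sbp"] < sbp_range[1]), "subject_id"
    ].tolist()
    if not eligible:
        raise ValueError(f"no subjects with SBP in [{sbp_range[0]}, {sbp_range[1]})")
    rng = np.random.default_rng(seed)
    take = min(n, len(eligible))
    return sorted(rng.choice(eligible, size=take, replace=False).tolist())


def _draw_compliance(rng: np.random.Generator, n: int) -> np.ndarray:
    """Bimodal compliance: engaged participants cluster near full
    attendance, disengaged ones well below the 80% threshold."""
    high = rng.uniform(size=n) < 0.5
    c = np.where(high, rng.uniform(0.8, 1.0, size=n), rng.uniform(0.0, 0.6, size=n))
    return c


def simulate_followup(
    cohort: CohortTable,
    truth: SyntheticTruth,
    config: SimConfig,
    subject_ids: list[str] | None = None,
) -> tuple[CohortTable, SyntheticTruth]:
    """Simulate a post-intervention visit for (a subset of) the cohort.

    Follow-up pseudotime is ``max(0, t - exercise_effect · compliance)``;
    features are regenerated from the reduced pseudotime with the
    subject's original background scores and sex shifts but fresh
    measurement noise. Emits ``active_days`` (gym attendance out of 48
    planned sessions) and ``vt_change`` (ventilatory-threshold change,
    ml/kg/min, positively tied to compliance).

    Returns the follow-up rows as a new ``CohortTable`` plus an updated
    truth carrying compliance and the follow-up pseudotime.
    """
    if not config.followup:
        raise ConfigError("followup flag not set in SimConfig")
    baseline_ids = list(cohort.visit_rows(VISIT_BASELINE).data["subject_id"])
    if subject_ids is None:
        subject_ids = baseline_ids
    absent = [s for s in subject_ids if s not in baseline_ids]
    if absent:
        raise ValueError(f"follow-up requested for subjects absent at baseline: {absent}")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7_042]))
    idx = [truth.subject_ids.index(s) for s in subject_ids]
    n = len(idx)
    names = list(truth.disease_loadings.index)
    p = len(names)

    compliance = _draw_compliance(rng, n)
    t0 = truth.pseudotime[idx]
    t_fu = np.maximum(0.0, t0 - config.exercise_effect * compliance)

    g = _response(t_fu, config.response)
    factor_scores = g[:, None] ** truth.response_exponents[None, :]
    scales = truth.response_scales if truth.response_scales is not None else np.ones(factor_scores.shape[1])
    factor_scores = factor_scores / scales[None, :]  # baseline units, scores comparable across visits
    latent = (
        truth.background_scores[idx] @ truth.background_loadings.to_numpy().T
        + config.disease_effect_scale * factor_scores @ truth.disease_loadings.to_numpy().T
        + (truth.sex[idx, None] - 0.5) * truth.sex_effects[None, :]
        + rng.normal(0.0, config.noise_sd, size=(n, p))
    )
    means = np.array([CALIBRATED_MOMENTS.get(f, (0.0, 1.0))[0] for f in names])
    sds = np.array([CALIBRATED_MOMENTS.get(f, (0.0, 1.0))[1] for f in names])
    X = means[None, :] + sds[None, :] * latent
    if config.missing_rate > 0:
        mask = rng.uniform(size=X.shape) < config.missing_rate
        X = np.where(mask, np.nan, X)

    sbp = config.sbp_intercept + config.sbp_slope * t_fu + rng.normal(0.0, config.sbp_noise_sd, size=n)
    active_days = np.clip(
        np.round(compliance * PLANNED_SESSIONS + rng.normal(0, 1.5, size=n)), 0, PLANNED_SESSIONS
    ).astype(int)
    vt_change = 3.0 * compliance - 0.5 + rng.normal(0.0, 0.6, size=n)

    base = cohort.data.set_index("subject_id")
    data = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "visit": VISIT_FOLLOWUP,
            "sex": truth.sex[idx],
            "sbp": np.round(np.clip(sbp, 85.0, None), 2),
            "on_medication": base.loc[subject_ids, "on_medication"].to_numpy(),
            "group": GROUP_UNASSIGNED,
            "active_days": active_days,
            "vt_change": np.round(vt_change, 4),
        }
    )
    data[names] = X
    followup = CohortTable(data, names)

    full_compliance = np.full(len(truth.subject_ids), np.nan)
    full_t_fu = np.full(len(truth.subject_ids), np.nan)
    full_compliance[idx] = compliance
    full_t_fu[idx] = t_fu
    updated = SyntheticTruth(
        pseudotime=truth.pseudotime,
        disease_loadings=truth.disease_loadings,
        background_loadings=truth.background_loadings,
        sex=truth.sex,
        background_scores=truth.background_scores,
        sex_effects=truth.sex_effects,
        response_exponents=truth.response_exponents,
        response_scales=truth.response_scales,
        subject_ids=truth.subject_ids,
        compliance=full_compliance,
        followup_pseudotime=full_t_fu,
    )
    return followup, updated
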