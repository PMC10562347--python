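"""The cohort table: subjects × variables plus clinical covariates.

``CohortTable`` is the universal exchange object of the pipeline: one row
per (subject, visit) holding sex, resting systolic blood pressure,
anti-hypertensive medication flag, a blood-pressure-defined group label,
and the echocardiographic feature columns. It reads and writes a plain
CSV schema (UTF-8, comma-separated, header required, empty cell =
missing value).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VISIT_BASELINE = "baseline"
VISIT_FOLLOWUP = "followup"

GROUP_NORMOTENSIVE = "normotensive"
GROUP_INTERMEDIATE = "intermediate"
GROUP_HYPERTENSIVE = "hypertensive"
GROUP_UNASSIGNED = "unassigned"
GROUPS = (GROUP_NORMOTENSIVE, GROUP_INTERMEDIATE, GROUP_HYPERTENSIVE, GROUP_UNASSIGNED)

#: Covariate columns, in CSV order, ahead of the feature columns.
COVARIATE_COLUMNS = ["subject_id", "visit", "sex", "sbp", "on_medication", "group"]

#: Optional intervention covariates emitted by the follow-up simulator.
INTERVENTION_COLUMNS = ["active_days", "vt_change"]


class SchemaError(ValueError):
    """Raised when a cohort table violates the documented CSV schema."""


@dataclass
class CohortTable:
    """Subjects × variables table with clinical covariates.

    Parameters
    ----------
    data
        One row per (subject, visit). Must contain ``COVARIATE_COLUMNS``
        and every name in ``feature_names``. ``sex`` is 0/1 (1 = male),
        ``on_medication`` is 0/1, missing feature cells are NaN.
    feature_names
        Ordered, unique list of feature columns.
    """

    data: pd.DataFrame
    feature_names: list[str]

    def __post_init__(self) -> None:
        if len(set(self.feature_names)) != len(self.feature_names):
            raise SchemaError("feature names must be unique")
        missing_cov = [c for c in COVARIATE_COLUMNS if c not in self.data.columns]
        if missing_cov:
            raise SchemaError(f"cohort table missing required columns: {missing_cov}")
        missing_feat = [f for f in self.feature_names if f not in self.data.columns]
        if missing_feat:
            raise SchemaError(f"cohort table missing feature columns: {missing_feat}")
        dup = self.data.duplicated(subset=["subject_id", "visit"])
        if dup.any():
            raise SchemaError("one row per (subject, visit) required; duplicates found")
        bad = set(self.data["group"].dropna()) - set(GROUPS)
        if bad:
            raise SchemaError(f"unknown group labels: {sorted(bad)}")
        self.data = self.data.reset_index(drop=True)

    # -- views -------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def features(self) -> pd.DataFrame:
        """Feature matrix (copy-free column view, rows aligned to data)."""
        return self.data[self.feature_names]

    @property
    def groups(self) -> pd.Series:
        return self.data["group"]

    def visit_rows(self, visit: str) -> "CohortTable":
        return self.subset(self.data["visit"] == visit)

    def subset(self, mask: Sequence[bool] | pd.Series) -> "CohortTable":
        mask = np.asarray(mask, dtype=bool)
        return CohortTable(self.data.loc[mask].copy(), list(self.feature_names))

    def drop_features(self, names: Iterable[str]) -> "CohortTable":
        names = list(names)
        unknown = [n for n in names if n not in self.feature_names]
        if unknown:
            raise SchemaError(f"cannot drop unknown features: {unknown}")
        kept = [f for f in self.feature_names if f not in names]
        return CohortTable(self.data.drop(columns=names), kept)

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), list(self.feature_names))

    def missing_fraction(self) -> float:
        block = self.features.to_numpy(dtype=float)
        return float(np.isnan(block).mean())

    # -- CSV schema --------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        extra = [c for c in INTERVENTION_COLUMNS if c in self.data.columns]
        cols = COVARIATE_COLUMNS + extra + self.feature_names
        self.data[cols].to_csv(path, index=False, na_rep="")

    @classmethod
    def from_csv(cls, path: str | Path, feature_names: Sequence[str] | None = None) -> "CohortTable":
        frame = pd.read_csv(path)
        missing = [c for c in COVARIATE_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"{path}: missing required columns {missing}")
        if feature_names is None:
            reserved = set(COVARIATE_COLUMNS) | set(INTERVENTION_COLUMNS)
            feature_names = [c for c in frame.columns if c not in reserved]
        frame["group"] = frame["group"].fillna(GROUP_UNASSIGNED)
        for col in feature_names:
            frame[col] = pd.to_numeric(frame[col], errors="coerce")
        return cls(frame, list(feature_names))


@dataclass
class SyntheticTruth:
    """Planted ground truth of a simulated cohort.

    Retains everything needed both for parameter-recovery tests and for
    regenerating features at a follow-up visit: the latent pseudotime,
    factor loadings (unit-norm columns), per-subject background factor
    scores, per-feature sex shifts, and — for follow-up scenarios —
    compliance and the reduced pseudotime.
    """

    pseudotime: np.ndarray                  # in [0, 1], one per subject
    disease_loadings: pd.DataFrame          # features × disease factors
    background_loadings: pd.DataFrame       # features × background factors
    sex: np.ndarray                         # 0/1
    background_scores: np.ndarray           # subjects × background factors
    sex_effects: np.ndarray                 # per-feature shift for sex==1
    response_exponents: np.ndarray          # per-disease-factor exponent on g(t)
    response_scales: np.ndarray | None = None  # per-factor SD of g(t)^q at baseline
    subject_ids: list[str] = field(default_factory=list)
    compliance: np.ndarray | None = None    # in [0, 1], follow-up scenarios
    followup_pseudotime: np.ndarray | None = None

    @property
    def disease_support(self) -> list[str]:
        """Features carrying any nonzero planted disease loading."""
        mask = (self.disease_loadings != 0).any(axis=1)
        return list(self.disease_loadings.index[mask])

    def to_csv(self, path: str | Path) -> None:
        out = pd.DataFrame({"subject_id": self.subject_ids, "pseudotime": self.pseudotime, "sex": self.sex})
        if self.compliance is not None:
            out["compliance"] = self.compliance
        if self.followup_pseudotime is not None:
            out["followup_pseudotime"] = self.followup_pseudotime
        out.to_csv(path, index=False)
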