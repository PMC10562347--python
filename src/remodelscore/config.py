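"""Configuration objects for every pipeline stage, with YAML round-trip.

All tunables live in small frozen-ish dataclasses so a whole run is
described by one ``PipelineConfig`` that hashes deterministically and
round-trips through YAML without loss. Unknown keys are rejected on load.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised for invalid or unknown configuration values."""


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    The generator superimposes a low-dimensional disease-enriched signal,
    expressed along a latent pseudotime in [0, 1], on shared background
    factor variance, with sex effects, measurement noise, blood pressure
    linked linearly to pseudotime, and completely-at-random missingness.
    """

    n_subjects: int = 400
    n_features: int = 68
    n_background_factors: int = 6
    n_disease_factors: int = 3
    disease_effect_scale: float = 1.5
    noise_sd: float = 0.3
    missing_rate: float = 0.03
    sbp_slope: float = 70.0       # mmHg per unit pseudotime
    sbp_intercept: float = 108.0  # mmHg
    sbp_noise_sd: float = 12.0    # mmHg
    sex_effect_sd: float = 0.5    # per-feature sex shift SD, z-scale
    response: str = "nonlinear"   # 'nonlinear' -> g(t)=(t^2+t)/2, or 'linear'
    followup: bool = False
    exercise_effect: float = 0.2  # pseudotime reduction per unit compliance
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_subjects": self.n_subjects,
            "n_features": self.n_features,
            "n_background_factors": self.n_background_factors,
            "n_disease_factors": self.n_disease_factors,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigError(f"{name} must be a count >= 1, got {value!r}")
        if self.n_disease_factors + self.n_background_factors >= self.n_features:
            raise ConfigError(
                "n_disease_factors + n_background_factors must be < n_features"
            )
        if not 0.0 <= self.missing_rate < 0.3:
            raise ConfigError(
                "missing_rate must lie in [0, 0.3); higher rates would wipe "
                f"out the cohort under the exclusion rule (got {self.missing_rate})"
            )
        for name in ("disease_effect_scale", "noise_sd", "sbp_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.sex_effect_sd < 0 or self.exercise_effect < 0:
            raise ConfigError("sex_effect_sd and exercise_effect must be nonnegative")
        if self.response not in ("nonlinear", "linear"):
            raise ConfigError("response must be 'nonlinear' or 'linear'")


@dataclass
class PreprocessParams:
    """Cleaning-chain thresholds: exclusion, imputation, group definition."""

    subject_missing_max: float = 0.30
    feature_missing_max: float = 0.30
    tsr_components: int | None = None  # None -> smallest k with >=90% var, cap 10
    tsr_var_target: float = 0.90
    tsr_component_cap: int = 10
    tsr_tol: float = 1e-6
    tsr_max_iter: int = 500
    sbp_normo_max: float = 120.0
    sbp_hyper_min: float = 160.0

    def validate(self) -> None:
        for name in ("subject_missing_max", "feature_missing_max"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ConfigError(f"{name} must be a fraction in (0, 1)")
        if self.sbp_normo_max >= self.sbp_hyper_min:
            raise ConfigError("sbp_normo_max must be below sbp_hyper_min")
        if self.tsr_tol <= 0 or self.tsr_max_iter < 1:
            raise ConfigError("tsr_tol must be > 0 and tsr_max_iter >= 1")


@dataclass
class ModelParams:
    """Feature selection, contrastive subspace and trajectory settings."""

    k_neighbours: int = 10
    keep_fraction: float = 1.0
    alpha_grid: list[float] | None = None  # None -> 0 plus 40 log-spaced in [1e-2, 1e3]
    variance_threshold: float = 0.80
    max_components: int = 10
    hopkins_fraction: float = 0.25
    hopkins_resamples: int = 20
    shrinkage: bool = True

    def validate(self) -> None:
        if not 0.0 < self.keep_fraction <= 1.0:
            raise ConfigError("keep_fraction must lie in (0, 1]")
        if not 0.0 < self.variance_threshold <= 1.0:
            raise ConfigError("variance_threshold must lie in (0, 1]")
        if self.k_neighbours < 1 or self.max_components < 1:
            raise ConfigError("k_neighbours and max_components must be >= 1")
        if self.alpha_grid is not None and any(a < 0 for a in self.alpha_grid):
            raise ConfigError("alpha grid values must be nonnegative")


@dataclass
class ValidationParams:
    n_folds: int = 5
    rmsd_threshold: float = 0.2
    excluded_features: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")


@dataclass
class ClinicalParams:
    bin_low_score_max: float = 0.25
    bin_size: int = 20
    max_bins: int = 10
    lowess_span: float = 0.5
    compliance_threshold: float = 0.8

    def validate(self) -> None:
        if self.bin_size < 1 or self.max_bins < 1:
            raise ConfigError("bin_size and max_bins must be >= 1")
        if not 0.0 < self.lowess_span <= 1.0:
            raise ConfigError("lowess_span must lie in (0, 1]")


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one run end to end."""

    sim: SimConfig = field(default_factory=SimConfig)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    model: ModelParams = field(default_factory=ModelParams)
    validation: ValidationParams = field(default_factory=ValidationParams)
    clinical: ClinicalParams = field(default_factory=ClinicalParams)
    seed: int = 0

    def validate(self) -> None:
        self.sim.validate()
        self.preprocess.validate()
        self.model.validate()
        self.validation.validate()
        self.clinical.validate()

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        blocks = {
            "sim": SimConfig,
            "preprocess": PreprocessParams,
            "model": ModelParams,
            "validation": ValidationParams,
            "clinical": ClinicalParams,
        }
        unknown = set(raw) - set(blocks) - {"seed"}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for name, klass in blocks.items():
            block = raw.get(name, {})
            if not isinstance(block, dict):
                raise ConfigError(f"config block {name!r} must be a mapping")
            allowed = {f.name for f in dataclasses.fields(klass)}
            bad = set(block) - allowed
            if bad:
                raise ConfigError(f"unknown keys in {name!r}: {sorted(bad)}")
            kwargs[name] = klass(**block)
        config = cls(seed=int(raw.get("seed", 0)), **kwargs)
        config.validate()
        return config

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def hash(self) -> str:
        """Stable short hash identifying this configuration."""
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
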