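"""Validated run configuration.

Two pydantic models: :class:`SyntheticConfig` parameterises the synthetic
day-care cohort generator, and :class:`RunConfig` parameterises the analysis
pipeline (windowing, model settings, split settings).  Unknown keys are
rejected so configuration typos fail before any computation.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class ConfigError(ValueError):
    """Invalid configuration detected before any sampling or fitting."""


class SyntheticConfig(BaseModel):
    """Parameters of the synthetic cohort generator.

    Defaults emulate the scale of the study cohort: 23 participants observed
    for 30 days at 20 facial-expression records per day (13,800 records) with
    38 NPI assessments, NPI totals spanning roughly 0-50 with a large share
    of exact zeros.
    """

    model_config = ConfigDict(extra="forbid")

    n_participants: int = Field(23, ge=2)
    days: int = Field(30, ge=8)
    records_per_day: int = Field(20, ge=1)
    #: Beta(a, b) shape of the latent severity s in [0, 1].
    severity_shape: tuple[float, float] = (1.2, 2.2)
    #: Logistic slope moving mood mass onto {anger, sadness} as s grows.
    emission_slope: float = 3.6
    #: Increase of the per-step switch probability per unit severity.
    switch_slope: float = Field(0.5, ge=0.0)
    #: (intercept, weight on freq_negative, weight on switch_frequency).
    npi_coeffs: tuple[float, float, float] = (-16.0, 0.45, 0.15)
    noise_sd: float = Field(3.0, ge=0.0)
    #: How many participants receive a second NPI assessment (23 + 15 = 38).
    n_second_assessments: int = Field(15, ge=0)
    window_days: int = Field(7, ge=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        from .synthetic import SWITCH_BASE  # local import avoids a cycle

        if SWITCH_BASE + self.switch_slope > 0.9 + 1e-12:
            raise ConfigError(
                f"per-step switch probability {SWITCH_BASE} + {self.switch_slope}*s "
                "exceeds the 0.9 cap at s=1"
            )
        if self.days < self.window_days:
            raise ConfigError(
                f"days={self.days} too short for any full "
                f"{self.window_days}-day assessment window"
            )
        if self.n_second_assessments > self.n_participants:
            raise ConfigError("n_second_assessments exceeds n_participants")
        return self


class RunConfig(BaseModel):
    """Pipeline settings: windowing, models, splits, seed."""

    model_config = ConfigDict(extra="forbid")

    window_days: int = Field(7, ge=1)
    aggregate_daily: bool = False
    normalize_features: bool = False

    # model settings
    alpha_enter: float = Field(0.05, gt=0, lt=1)
    alpha_remove: float = Field(0.10, gt=0, lt=1)
    n_trees: int = Field(500, ge=1)
    top_k: int = Field(6, ge=1, le=10)
    use_permutation_importance: bool = False
    correlation_method: str = Field("pearson", pattern="^(pearson|spearman)$")

    # split settings
    stage1_size: int = Field(7, ge=1)
    n_folds: int = Field(6, ge=2)
    test_fraction: float = Field(1 / 6, gt=0, lt=1)
    npi_mild_max: int = Field(12, ge=1)
    age_cut: float = 80.0
    biased_coin_p: float = Field(1.0, ge=0.5, le=1.0)

    synthetic: SyntheticConfig = Field(default_factory=SyntheticConfig)
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return RunConfig.model_validate(data or {})
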