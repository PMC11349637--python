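"""Application configuration: tier thresholds and decision-table knobs.

A single YAML file can override any subset of the defaults::

    risk_thresholds:
      lifetime_low: 0.15
      lifetime_high: 0.20
      five_year_elevated: 0.0167
    decision:
      hormone_threshold_years: 5.0
      transwoman_average_age: 40
      transwoman_elevated_age: 25
      transman_average_age: 40
      transman_intermediate_age: 30
      transman_high_age: 25
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from .acr_decision import DecisionConfig
from .errors import ConfigurationError
from .gail_engine import RiskThresholds, load_constants


class AppConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    risk_thresholds: RiskThresholds = RiskThresholds()
    decision: DecisionConfig = DecisionConfig()

    def validated(self) -> "AppConfig":
        self.risk_thresholds.validated()
        self.decision.validated()
        return self


DEFAULT_CONFIG = AppConfig()

DISCLAIMER = (
    "Decision support only — not a diagnosis; review results with a clinician."
)


def constants_version() -> str:
    return load_constants().version


def load_config(path: str | Path | None = None) -> AppConfig:
    """Load an :class:`AppConfig`, applying YAML overrides if given."""
    if path is None:
        return DEFAULT_CONFIG
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    return AppConfig(
        risk_thresholds=RiskThresholds(**raw.get("risk_thresholds", {})),
        decision=DecisionConfig(**raw.get("decision", {})),
    ).validated()
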