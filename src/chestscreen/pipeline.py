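"""End-to-end scoring: risk projection -> tiering -> decision table."""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, ConfigDict

from .acr_decision import ScreeningRecommendation, classify_variant, recommend
from .config import AppConfig, DEFAULT_CONFIG
from .gail_engine import GailRiskEstimate, estimate_risk, load_constants
from .profiles import (
    ChestSurgery,
    RiskFactorProfile,
    SexAssignedAtBirth,
    TransPatientProfile,
)


class ScreeningReport(BaseModel):
    """Joint output of the risk engine and the decision table."""

    model_config = ConfigDict(frozen=True)

    estimate: Optional[GailRiskEstimate]
    recommendation: ScreeningRecommendation


def screen(
    trans_profile: TransPatientProfile,
    risk_profile: RiskFactorProfile,
    config: AppConfig = DEFAULT_CONFIG,
) -> ScreeningReport:
    """Score one patient end to end.

    Projects 5-year and lifetime risk from the risk-factor profile,
    derives the categorical tiers, matches the decision table and builds
    the imaging recommendation. A bilateral-mastectomy history skips the
    risk projection entirely — the matching row covers any risk. (The
    shortcut applies only on the transman arm; the transwoman arm does
    not condition on surgery.)
    """
    if (
        trans_profile.chest_surgery is ChestSurgery.BILATERAL_MASTECTOMY
        and trans_profile.sex_assigned_at_birth is SexAssignedAtBirth.FEMALE
    ):
        variant = classify_variant(trans_profile, config=config.decision)
        rec = recommend(variant, profile=trans_profile, config=config.decision)
        return ScreeningReport(estimate=None, recommendation=rec)
    estimate = estimate_risk(
        risk_profile,
        constants=load_constants(risk_profile.race_group),
        thresholds=config.risk_thresholds,
    )
    variant = classify_variant(
        trans_profile,
        two_tier=estimate.two_tier,
        three_tier=estimate.three_tier,
        config=config.decision,
    )
    rec = recommend(
        variant,
        profile=trans_profile,
        two_tier=estimate.two_tier,
        three_tier=estimate.three_tier,
        config=config.decision,
    )
    return ScreeningReport(estimate=estimate, recommendation=rec)
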