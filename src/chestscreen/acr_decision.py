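"""Appropriateness-criteria screening decision table.

A total, deterministic mapping from a transgender/nonbinary patient
profile plus a categorical risk tier to one of eight published clinical
variants (or an explicit no-match outcome) and its imaging
recommendation.

The table has two arms. The transwoman arm (patients assigned male at
birth) conditions on age, cumulative gender-affirming hormone exposure
and the two-level risk tier (average vs higher than average); the
transman arm (assigned female at birth) conditions on age, chest
surgical history and the three-level tier (average / intermediate /
high). Bilateral ("top") mastectomy dominates everything else on the
transman arm: screening is rated usually-not-appropriate at any age and
any risk tier. All age and hormone thresholds are inclusive on the
"at least" side; the hormone split is at exactly 5.0 years.

Profiles covered by no published row (e.g. a 30-year-old average-risk
transwoman with 5+ years of hormones) return an explicit NO_MATCH with a
reason code and a re-evaluation hint rather than a silent default: the
published table is not total, and this module surfaces that honestly.
Nonbinary identities are routed by sex assigned at birth and the output
is tagged as an extrapolation beyond the published arms.
"""

from __future__ import annotations

from enum import Enum
from itertools import product
from typing import Iterable, Optional

from pydantic import BaseModel, ConfigDict

from .errors import ConfigurationError, ProfileValidationError
from .gail_engine import ThreeTier, TwoTier
from .profiles import (
    ChestSurgery,
    GenderIdentity,
    SexAssignedAtBirth,
    TransPatientProfile,
    MAX_AGE,
    MIN_AGE,
)


class Rating(str, Enum):
    USUALLY_APPROPRIATE = "usually_appropriate"
    MAY_BE_APPROPRIATE = "may_be_appropriate"
    USUALLY_NOT_APPROPRIATE = "usually_not_appropriate"
    NOT_INDICATED = "not_indicated"


#: Total order on ratings. ``usually_not_appropriate`` and
#: ``not_indicated`` share a rank: both mean "no screening recommended",
#: differing only in whether a published row says so explicitly.
RATING_RANK = {
    Rating.USUALLY_APPROPRIATE: 3,
    Rating.MAY_BE_APPROPRIATE: 2,
    Rating.USUALLY_NOT_APPROPRIATE: 1,
    Rating.NOT_INDICATED: 1,
}


class Arm(str, Enum):
    TRANSWOMAN = "transwoman"
    TRANSMAN = "transman"


class VariantId(str, Enum):
    V1 = "V1"
    V2 = "V2"
    V3 = "V3"
    V4 = "V4"
    V5 = "V5"
    V6 = "V6"
    V7 = "V7"
    V8 = "V8"
    NO_MATCH = "NO_MATCH"


class NoMatchReason(str, Enum):
    BELOW_AGE_THRESHOLD = "below_age_threshold"
    INSUFFICIENT_HORMONE_EXPOSURE = "insufficient_hormone_exposure"


class ScreeningVariant(BaseModel):
    model_config = ConfigDict(frozen=True)

    id: VariantId
    arm: Arm
    no_match_reason: Optional[NoMatchReason] = None


class ScreeningRecommendation(BaseModel):
    """Imaging recommendation for one matched variant (or NO_MATCH)."""

    model_config = ConfigDict(frozen=True)

    variant: ScreeningVariant
    mammography_rating: Rating
    ultrasound_rating: Rating
    rationale: str
    reevaluation_hint: Optional[str] = None
    extrapolated: bool = False


class DecisionConfig(BaseModel):
    """Thresholds of the decision table (all inclusive on ">=")."""

    model_config = ConfigDict(frozen=True)

    hormone_threshold_years: float = 5.0
    transwoman_average_age: int = 40  # V1
    transwoman_elevated_age: int = 25  # V2 and V4
    transman_average_age: int = 40  # V6
    transman_intermediate_age: int = 30  # V7
    transman_high_age: int = 25  # V8

    def validated(self) -> "DecisionConfig":
        ages = (
            self.transwoman_average_age,
            self.transwoman_elevated_age,
            self.transman_average_age,
            self.transman_intermediate_age,
            self.transman_high_age,
        )
        if any(a < MIN_AGE or a > MAX_AGE for a in ages):
            raise ConfigurationError(f"age thresholds must lie in [{MIN_AGE}, {MAX_AGE}]")
        if self.hormone_threshold_years < 0:
            raise ConfigurationError("hormone_threshold_years must be non-negative")
        return self


DEFAULT_DECISION_CONFIG = DecisionConfig()


def arm_for(profile: TransPatientProfile) -> Arm:
    """Decision-table arm, routed by sex assigned at birth."""
    if profile.sex_assigned_at_birth is SexAssignedAtBirth.MALE:
        return Arm.TRANSWOMAN
    return Arm.TRANSMAN


def is_extrapolated(profile: TransPatientProfile) -> bool:
    return profile.gender_identity in (
        GenderIdentity.NONBINARY_AMAB,
        GenderIdentity.NONBINARY_AFAB,
    )


def _match_transwoman(
    age: float, hormone_years: float, tier: TwoTier, cfg: DecisionConfig
) -> Optional[VariantId]:
    exposed = hormone_years >= cfg.hormone_threshold_years
    if exposed:
        if tier is TwoTier.AVERAGE and age >= cfg.transwoman_average_age:
            return VariantId.V1
        if tier is TwoTier.HIGHER_THAN_AVERAGE and age >= cfg.transwoman_elevated_age:
            return VariantId.V2
    else:
        if tier is TwoTier.AVERAGE:
            return VariantId.V3  # any age
        if age >= cfg.transwoman_elevated_age:
            return VariantId.V4
    return None


def _match_transman(
    age: float, surgery: ChestSurgery, tier: ThreeTier, cfg: DecisionConfig
) -> Optional[VariantId]:
    if surgery is ChestSurgery.BILATERAL_MASTECTOMY:
        return VariantId.V5  # any age, any risk; dominates V6-V8
    if tier is ThreeTier.AVERAGE and age >= cfg.transman_average_age:
        return VariantId.V6
    if tier is ThreeTier.INTERMEDIATE and age >= cfg.transman_intermediate_age:
        return VariantId.V7
    if tier is ThreeTier.HIGH and age >= cfg.transman_high_age:
        return VariantId.V8
    return None


def _first_matching_age(
    profile: TransPatientProfile,
    two_tier: Optional[TwoTier],
    three_tier: Optional[ThreeTier],
    cfg: DecisionConfig,
) -> Optional[int]:
    """Smallest age in [profile.age, MAX_AGE] at which the profile would match."""
    for age in range(profile.age, MAX_AGE + 1):
        if arm_for(profile) is Arm.TRANSWOMAN:
            hit = _match_transwoman(age, profile.hormone_duration_years, two_tier, cfg)
        else:
            hit = _match_transman(age, profile.chest_surgery, three_tier, cfg)
        if hit is not None:
            return age
    return None


def classify_variant(
    profile: TransPatientProfile,
    *,
    two_tier: Optional[TwoTier] = None,
    three_tier: Optional[ThreeTier] = None,
    config: DecisionConfig = DEFAULT_DECISION_CONFIG,
) -> ScreeningVariant:
    """Match a profile to exactly one variant, or NO_MATCH with a reason.

    The transwoman arm consumes the two-level tier, the transman arm the
    three-level tier (mirroring the published table's vocabulary); only
    the tier the routed arm consumes is required. A transman-arm profile
    with bilateral mastectomy needs no tier at all (the row covers any
    risk).
    """
    cfg = config.validated()
    arm = arm_for(profile)
    if arm is Arm.TRANSWOMAN:
        if two_tier is None:
            raise ProfileValidationError("transwoman arm requires the two-level risk tier")
        hit = _match_transwoman(profile.age, profile.hormone_duration_years, two_tier, cfg)
    else:
        if profile.chest_surgery is ChestSurgery.BILATERAL_MASTECTOMY:
            return ScreeningVariant(id=VariantId.V5, arm=arm)
        if three_tier is None:
            raise ProfileValidationError("transman arm requires the three-level risk tier")
        hit = _match_transman(profile.age, profile.chest_surgery, three_tier, cfg)
    if hit is not None:
        return ScreeningVariant(id=hit, arm=arm)

    # No published row covers this profile; attribute the gap.
    if _first_matching_age(profile, two_tier, three_tier, cfg) is not None:
        reason = NoMatchReason.BELOW_AGE_THRESHOLD
    else:
        reason = NoMatchReason.INSUFFICIENT_HORMONE_EXPOSURE
    return ScreeningVariant(id=VariantId.NO_MATCH, arm=arm, no_match_reason=reason)


_RATINGS: dict[VariantId, tuple[Rating, Rating, str]] = {
    VariantId.V1: (
        Rating.MAY_BE_APPROPRIATE,
        Rating.NOT_INDICATED,
        "Transwoman arm: age >=40, hormone use >=5 years, average risk — "
        "mammography may be appropriate.",
    ),
    VariantId.V2: (
        Rating.USUALLY_APPROPRIATE,
        Rating.NOT_INDICATED,
        "Transwoman arm: age >=25, hormone use >=5 years, higher-than-average "
        "risk — mammography usually appropriate.",
    ),
    VariantId.V3: (
        Rating.USUALLY_NOT_APPROPRIATE,
        Rating.USUALLY_NOT_APPROPRIATE,
        "Transwoman arm: any age, hormone use <5 years, average risk — "
        "screening usually not appropriate.",
    ),
    VariantId.V4: (
        Rating.MAY_BE_APPROPRIATE,
        Rating.NOT_INDICATED,
        "Transwoman arm: age >=25, hormone use <5 years, higher-than-average "
        "risk — mammography may be appropriate.",
    ),
    VariantId.V5: (
        Rating.USUALLY_NOT_APPROPRIATE,
        Rating.USUALLY_NOT_APPROPRIATE,
        "Transman arm: bilateral mastectomy, any age, any risk — screening "
        "usually not appropriate.",
    ),
    VariantId.V6: (
        Rating.USUALLY_APPROPRIATE,
        Rating.NOT_INDICATED,
        "Transman arm: age >=40, no surgery or breast reduction, average risk "
        "— mammography usually appropriate.",
    ),
    VariantId.V7: (
        Rating.USUALLY_APPROPRIATE,
        Rating.MAY_BE_APPROPRIATE,
        "Transman arm: age >=30, no surgery or breast reduction, intermediate "
        "risk — mammography usually appropriate; ultrasound may be appropriate.",
    ),
    VariantId.V8: (
        Rating.USUALLY_APPROPRIATE,
        Rating.MAY_BE_APPROPRIATE,
        "Transman arm: age >=25, no surgery or breast reduction, high risk — "
        "mammography usually appropriate; ultrasound may be appropriate.",
    ),
}


def recommend(
    variant: ScreeningVariant,
    *,
    profile: Optional[TransPatientProfile] = None,
    two_tier: Optional[TwoTier] = None,
    three_tier: Optional[ThreeTier] = None,
    config: DecisionConfig = DEFAULT_DECISION_CONFIG,
) -> ScreeningRecommendation:
    """Imaging recommendation for a matched variant.

    For NO_MATCH outcomes the optional ``profile``/tier arguments let the
    hint name the age at which the profile would first match a row.
    """
    extrapolated = is_extrapolated(profile) if profile is not None else False
    if variant.id is not VariantId.NO_MATCH:
        mammo, us, rationale = _RATINGS[variant.id]
        if extrapolated:
            rationale += (
                " Routed by sex assigned at birth; extrapolation beyond the "
                "published binary arms for a nonbinary identity."
            )
        return ScreeningRecommendation(
            variant=variant,
            mammography_rating=mammo,
            ultrasound_rating=us,
            rationale=rationale,
            extrapolated=extrapolated,
        )

    hint = "Re-evaluate when the patient's age, hormone history or risk profile changes."
    if profile is not None:
        first_age = _first_matching_age(profile, two_tier, three_tier, config.validated())
        if first_age is not None:
            hint = (
                f"No published row matches yet; with an unchanged history this "
                f"profile would first match at age {first_age}."
            )
        elif variant.no_match_reason is NoMatchReason.INSUFFICIENT_HORMONE_EXPOSURE:
            hint = (
                "No published row matches at any age with this hormone history; "
                f"re-evaluate once cumulative hormone exposure reaches "
                f"{config.hormone_threshold_years:g} years."
            )
    return ScreeningRecommendation(
        variant=variant,
        mammography_rating=Rating.NOT_INDICATED,
        ultrasound_rating=Rating.NOT_INDICATED,
        rationale=(
            "No published screening row covers this profile "
            f"(reason: {variant.no_match_reason.value})."
        ),
        reevaluation_hint=hint,
        extrapolated=extrapolated,
    )


class DecisionRow(BaseModel):
    """One distinct cell of the rendered decision table."""

    model_config = ConfigDict(frozen=True)

    arm: Arm
    variant_id: VariantId
    no_match_reason: Optional[NoMatchReason]
    conditions: str
    mammography_rating: Rating
    ultrasound_rating: Rating


def _representative_ages(cfg: DecisionConfig) -> list[int]:
    """One probe age per distinct region of the age axis."""
    cuts = sorted(
        {
            MIN_AGE,
            cfg.transwoman_average_age,
            cfg.transwoman_elevated_age,
            cfg.transman_average_age,
            cfg.transman_intermediate_age,
            cfg.transman_high_age,
        }
    )
    return [a for a in cuts if MIN_AGE <= a <= MAX_AGE]


def decision_table(config: DecisionConfig = DEFAULT_DECISION_CONFIG) -> list[DecisionRow]:
    """Enumerate every distinct (condition -> recommendation) rule cell.

    Probes one representative profile per region of the discretized
    condition space and deduplicates by outcome, yielding the published
    eight variant rows plus the explicit NO_MATCH rows under the default
    thresholds.
    """
    cfg = config.validated()
    ages = _representative_ages(cfg)
    hormone_levels = (max(0.0, cfg.hormone_threshold_years - 1.0), cfg.hormone_threshold_years)
    h = cfg.hormone_threshold_years
    canonical_conditions = {
        VariantId.V1: f"age>={cfg.transwoman_average_age}, hormones>={h:g}y, average",
        VariantId.V2: f"age>={cfg.transwoman_elevated_age}, hormones>={h:g}y, higher_than_average",
        VariantId.V3: f"any age, hormones<{h:g}y, average",
        VariantId.V4: f"age>={cfg.transwoman_elevated_age}, hormones<{h:g}y, higher_than_average",
        VariantId.V5: "any age, bilateral_mastectomy, any risk",
        VariantId.V6: f"age>={cfg.transman_average_age}, none|breast_reduction, average",
        VariantId.V7: f"age>={cfg.transman_intermediate_age}, none|breast_reduction, intermediate",
        VariantId.V8: f"age>={cfg.transman_high_age}, none|breast_reduction, high",
        VariantId.NO_MATCH: "profiles younger than every row matching their history",
    }
    rows: dict[tuple, DecisionRow] = {}

    def add(arm: Arm, variant: ScreeningVariant, rec: ScreeningRecommendation, cond: str):
        key = (arm, variant.id, variant.no_match_reason)
        if key not in rows:
            rows[key] = DecisionRow(
                arm=arm,
                variant_id=variant.id,
                no_match_reason=variant.no_match_reason,
                conditions=canonical_conditions.get(variant.id, cond),
                mammography_rating=rec.mammography_rating,
                ultrasound_rating=rec.ultrasound_rating,
            )

    for age, hormones, tier in product(ages, hormone_levels, TwoTier):
        profile = TransPatientProfile(
            gender_identity=GenderIdentity.TRANSFEMININE,
            sex_assigned_at_birth=SexAssignedAtBirth.MALE,
            age=age,
            hormone_duration_years=hormones,
        )
        variant = classify_variant(profile, two_tier=tier, config=cfg)
        rec = recommend(variant, profile=profile, two_tier=tier, config=cfg)
        add(
            Arm.TRANSWOMAN,
            variant,
            rec,
            f"age>={age}, hormones {'>=' if hormones >= cfg.hormone_threshold_years else '<'}"
            f"{cfg.hormone_threshold_years:g}y, {tier.value}",
        )
    for age, surgery, tier in product(ages, ChestSurgery, ThreeTier):
        profile = TransPatientProfile(
            gender_identity=GenderIdentity.TRANSMASCULINE,
            sex_assigned_at_birth=SexAssignedAtBirth.FEMALE,
            age=age,
            hormone_duration_years=0.0,
            chest_surgery=surgery,
        )
        variant = classify_variant(profile, three_tier=tier, config=cfg)
        rec = recommend(variant, profile=profile, three_tier=tier, config=cfg)
        add(Arm.TRANSMAN, variant, rec, f"age>={age}, {surgery.value}, {tier.value}")

    order = {v: i for i, v in enumerate(VariantId)}
    return sorted(rows.values(), key=lambda r: (r.arm.value, order[r.variant_id]))


def render_decision_table(rows: Iterable[DecisionRow]) -> str:
    """Plain-text facsimile of the decision table for docs and the CLI."""
    lines = []
    for row in rows:
        label = row.variant_id.value
        if row.no_match_reason is not None:
            label += f"({row.no_match_reason.value})"
        lines.append(
            f"{row.arm.value:10s} {label:30s} {row.conditions:45s} "
            f"mammography={row.mammography_rating.value}, "
            f"ultrasound={row.ultrasound_rating.value}"
        )
    return "\n".join(lines)
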