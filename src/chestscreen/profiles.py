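"""Patient-facing domain types.

Two profile objects feed the tool:

* :class:`RiskFactorProfile` — the classical breast-cancer risk factors
  (menarche, parity, biopsies, atypical hyperplasia, first-degree family
  history, race/ethnicity group) consumed by the absolute-risk engine.
* :class:`TransPatientProfile` — gender identity, sex assigned at birth,
  age, cumulative gender-affirming hormone exposure and chest surgical
  history, consumed by the screening decision table.

Category vocabularies mirror the risk model's discrete coding: every
factor maps to exactly one category index, and ``unknown`` always maps to
the model's baseline category.
"""

from __future__ import annotations

from enum import Enum

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ProfileValidationError

MIN_AGE = 18
MAX_AGE = 90


class MenarcheCategory(str, Enum):
    """Age at first menstrual period (baseline: 14 or older)."""

    GE_14 = "ge14"
    AGE_12_13 = "12-13"
    LT_12 = "lt12"
    UNKNOWN = "unknown"


class FirstBirthCategory(str, Enum):
    """Age at first live birth; nulliparity shares the 25–29 category,
    following the risk model's coding."""

    LT_20 = "lt20"
    AGE_20_24 = "20-24"
    AGE_25_29_OR_NULLIPAROUS = "25-29_or_nulliparous"
    GE_30 = "ge30"
    UNKNOWN = "unknown"


class BiopsyCategory(str, Enum):
    NONE = "0"
    ONE = "1"
    GE_2 = "2+"
    UNKNOWN = "unknown"


class HyperplasiaStatus(str, Enum):
    PRESENT = "present"
    ABSENT = "absent"
    UNKNOWN = "unknown"


class RelativesCategory(str, Enum):
    """First-degree relatives with breast cancer."""

    NONE = "0"
    ONE = "1"
    GE_2 = "2+"
    UNKNOWN = "unknown"


class RaceGroup(str, Enum):
    WHITE = "white"
    BLACK = "black"
    HISPANIC = "hispanic"
    ASIAN_PACIFIC_ISLANDER = "asian_pacific_islander"
    OTHER_UNKNOWN = "other_unknown"


class GenderIdentity(str, Enum):
    TRANSFEMININE = "transfeminine"
    TRANSMASCULINE = "transmasculine"
    NONBINARY_AMAB = "nonbinary_amab"
    NONBINARY_AFAB = "nonbinary_afab"


class SexAssignedAtBirth(str, Enum):
    FEMALE = "female"
    MALE = "male"


class ChestSurgery(str, Enum):
    NONE = "none"
    BREAST_REDUCTION = "breast_reduction"
    BILATERAL_MASTECTOMY = "bilateral_mastectomy"


#: Gender identities routed through each decision-table arm.
AMAB_IDENTITIES = frozenset({GenderIdentity.TRANSFEMININE, GenderIdentity.NONBINARY_AMAB})
AFAB_IDENTITIES = frozenset({GenderIdentity.TRANSMASCULINE, GenderIdentity.NONBINARY_AFAB})


def expected_sex_at_birth(identity: GenderIdentity) -> SexAssignedAtBirth:
    if identity in AMAB_IDENTITIES:
        return SexAssignedAtBirth.MALE
    return SexAssignedAtBirth.FEMALE


class RiskFactorProfile(BaseModel):
    """Risk-factor record for the absolute-risk engine.

    Unknown values are legal everywhere and resolve to the baseline
    category; non-applicable natal history (e.g. menarche for a patient
    assigned male at birth) should likewise be left ``unknown``.
    """

    model_config = ConfigDict(frozen=True)

    current_age: int = Field(ge=MIN_AGE, le=MAX_AGE)
    age_at_menarche: MenarcheCategory = MenarcheCategory.UNKNOWN
    age_at_first_live_birth: FirstBirthCategory = FirstBirthCategory.UNKNOWN
    n_biopsies: BiopsyCategory = BiopsyCategory.UNKNOWN
    atypical_hyperplasia: HyperplasiaStatus = HyperplasiaStatus.UNKNOWN
    n_first_degree_relatives: RelativesCategory = RelativesCategory.UNKNOWN
    race_group: RaceGroup = RaceGroup.OTHER_UNKNOWN

    @model_validator(mode="after")
    def _hyperplasia_requires_biopsy(self) -> "RiskFactorProfile":
        if self.atypical_hyperplasia is HyperplasiaStatus.PRESENT and self.n_biopsies not in (
            BiopsyCategory.ONE,
            BiopsyCategory.GE_2,
        ):
            raise ProfileValidationError(
                "atypical_hyperplasia=present requires n_biopsies >= 1 "
                f"(got n_biopsies={self.n_biopsies.value!r})"
            )
        return self


class TransPatientProfile(BaseModel):
    """Demographic / transition-history record for the decision table."""

    model_config = ConfigDict(frozen=True)

    gender_identity: GenderIdentity
    sex_assigned_at_birth: SexAssignedAtBirth
    age: int = Field(ge=MIN_AGE, le=MAX_AGE)
    hormone_duration_years: float = Field(ge=0.0)
    chest_surgery: ChestSurgery = ChestSurgery.NONE

    @model_validator(mode="after")
    def _identity_consistent_with_sex(self) -> "TransPatientProfile":
        expected = expected_sex_at_birth(self.gender_identity)
        if self.sex_assigned_at_birth is not expected:
            raise ProfileValidationError(
                f"gender_identity={self.gender_identity.value!r} requires "
                f"sex_assigned_at_birth={expected.value!r}"
            )
        return self
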