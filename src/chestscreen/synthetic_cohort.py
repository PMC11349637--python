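"""Seeded synthetic patient cohorts and the exhaustive profile grid.

Everything the rest of the package needs for testing is generated here;
no external dataset is required. Cohort defaults are chosen for
*coverage* of the decision space, not epidemiological realism: ages are
uniform over the supported range, every surgery state appears, and the
hormone-exposure mixture (60% never-users, the rest uniform on 0-10
years) puts 20% of the cohort at or beyond the 5-year decision
threshold. These are test fixtures, not population estimates.
"""

from __future__ import annotations

from typing import Iterator, NamedTuple, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigurationError
from .gail_engine import ThreeTier, TwoTier
from .profiles import (
    AMAB_IDENTITIES,
    BiopsyCategory,
    ChestSurgery,
    FirstBirthCategory,
    GenderIdentity,
    HyperplasiaStatus,
    MenarcheCategory,
    RaceGroup,
    RelativesCategory,
    RiskFactorProfile,
    SexAssignedAtBirth,
    TransPatientProfile,
    expected_sex_at_birth,
    MAX_AGE,
    MIN_AGE,
)

_SURGERIES = (ChestSurgery.NONE, ChestSurgery.BREAST_REDUCTION, ChestSurgery.BILATERAL_MASTECTOMY)
_MENARCHE = (MenarcheCategory.GE_14, MenarcheCategory.AGE_12_13, MenarcheCategory.LT_12)
_FIRST_BIRTH = (
    FirstBirthCategory.LT_20,
    FirstBirthCategory.AGE_20_24,
    FirstBirthCategory.AGE_25_29_OR_NULLIPAROUS,
    FirstBirthCategory.GE_30,
)
_BIOPSIES = (BiopsyCategory.NONE, BiopsyCategory.ONE, BiopsyCategory.GE_2)
_RELATIVES = (RelativesCategory.NONE, RelativesCategory.ONE, RelativesCategory.GE_2)
_RACES = tuple(RaceGroup)


def _normalized(name: str, probs: tuple[float, ...], expected_len: int) -> tuple[float, ...]:
    if len(probs) != expected_len:
        raise ConfigurationError(f"{name} must have {expected_len} entries")
    if any(p < 0 for p in probs):
        raise ConfigurationError(f"{name} entries must be non-negative")
    total = sum(probs)
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ConfigurationError(f"{name} must sum to 1 (got {total})")
    return probs


class CohortConfig(BaseModel):
    """Sampling configuration for :func:`sample_cohort`."""

    model_config = ConfigDict(frozen=True)

    n: int = Field(ge=1, default=100)
    seed: int = 0
    identity_mix: tuple[float, float, float, float] = (0.40, 0.40, 0.10, 0.10)
    age_min: int = MIN_AGE
    age_max: int = MAX_AGE
    #: P(no hormone exposure at all); the remainder is uniform on
    #: (0, hormone_uniform_max] years, so the default puts 20% of the
    #: cohort at >=5 years.
    hormone_zero_inflation: float = 0.60
    hormone_uniform_max: float = 10.0
    surgery_prevalence_afab: tuple[float, float, float] = (0.50, 0.20, 0.30)
    surgery_prevalence_amab: tuple[float, float, float] = (0.95, 0.05, 0.00)
    menarche_prevalence: tuple[float, float, float] = (0.50, 0.30, 0.20)
    first_birth_prevalence: tuple[float, float, float, float] = (0.25, 0.30, 0.30, 0.15)
    biopsy_prevalence: tuple[float, float, float] = (0.70, 0.20, 0.10)
    hyperplasia_given_biopsy: float = 0.10
    relatives_prevalence: tuple[float, float, float] = (0.80, 0.15, 0.05)
    race_prevalence: tuple[float, float, float, float, float] = (0.2, 0.2, 0.2, 0.2, 0.2)

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        _normalized("identity_mix", self.identity_mix, 4)
        _normalized("surgery_prevalence_afab", self.surgery_prevalence_afab, 3)
        _normalized("surgery_prevalence_amab", self.surgery_prevalence_amab, 3)
        _normalized("menarche_prevalence", self.menarche_prevalence, 3)
        _normalized("first_birth_prevalence", self.first_birth_prevalence, 4)
        _normalized("biopsy_prevalence", self.biopsy_prevalence, 3)
        _normalized("relatives_prevalence", self.relatives_prevalence, 3)
        _normalized("race_prevalence", self.race_prevalence, 5)
        if not (self.age_min <= self.age_max):
            raise ConfigurationError("age_min must not exceed age_max")
        if not (0.0 <= self.hormone_zero_inflation <= 1.0):
            raise ConfigurationError("hormone_zero_inflation must lie in [0, 1]")
        if not (0.0 <= self.hyperplasia_given_biopsy <= 1.0):
            raise ConfigurationError("hyperplasia_given_biopsy must lie in [0, 1]")
        if self.hormone_uniform_max <= 0:
            raise ConfigurationError("hormone_uniform_max must be positive")
        return self


_IDENTITY_ORDER = (
    GenderIdentity.TRANSFEMININE,
    GenderIdentity.TRANSMASCULINE,
    GenderIdentity.NONBINARY_AMAB,
    GenderIdentity.NONBINARY_AFAB,
)


def sample_cohort(
    config: CohortConfig = CohortConfig(),
) -> list[tuple[TransPatientProfile, RiskFactorProfile]]:
    """Draw ``config.n`` profile pairs, reproducibly under ``config.seed``.

    Both profile invariants hold by construction: sex assigned at birth
    follows the sampled identity, atypical hyperplasia is only sampled
    for biopsy-positive histories, and natal menarche/parity factors are
    left unknown (baseline) for patients assigned male at birth.
    """
    rng = np.random.default_rng(config.seed)
    records: list[tuple[TransPatientProfile, RiskFactorProfile]] = []
    for _ in range(config.n):
        identity = _IDENTITY_ORDER[rng.choice(4, p=config.identity_mix)]
        saab = expected_sex_at_birth(identity)
        age = int(rng.integers(config.age_min, config.age_max + 1))
        if rng.random() < config.hormone_zero_inflation:
            hormones = 0.0
        else:
            hormones = float(rng.uniform(0.0, config.hormone_uniform_max))
        surgery_p = (
            config.surgery_prevalence_amab
            if saab is SexAssignedAtBirth.MALE
            else config.surgery_prevalence_afab
        )
        surgery = _SURGERIES[rng.choice(3, p=surgery_p)]
        trans_profile = TransPatientProfile(
            gender_identity=identity,
            sex_assigned_at_birth=saab,
            age=age,
            hormone_duration_years=hormones,
            chest_surgery=surgery,
        )

        biopsies = _BIOPSIES[rng.choice(3, p=config.biopsy_prevalence)]
        if biopsies is BiopsyCategory.NONE:
            hyperplasia = HyperplasiaStatus.UNKNOWN
        else:
            hyperplasia = (
                HyperplasiaStatus.PRESENT
                if rng.random() < config.hyperplasia_given_biopsy
                else HyperplasiaStatus.ABSENT
            )
        if saab is SexAssignedAtBirth.MALE:
            menarche = MenarcheCategory.UNKNOWN
            first_birth = FirstBirthCategory.UNKNOWN
        else:
            menarche = _MENARCHE[rng.choice(3, p=config.menarche_prevalence)]
            first_birth = _FIRST_BIRTH[rng.choice(4, p=config.first_birth_prevalence)]
        risk_profile = RiskFactorProfile(
            current_age=age,
            age_at_menarche=menarche,
            age_at_first_live_birth=first_birth,
            n_biopsies=biopsies,
            atypical_hyperplasia=hyperplasia,
            n_first_degree_relatives=_RELATIVES[rng.choice(3, p=config.relatives_prevalence)],
            race_group=_RACES[rng.choice(5, p=config.race_prevalence)],
        )
        records.append((trans_profile, risk_profile))
    return records


class GridCase(NamedTuple):
    """One point of the exhaustive decision grid.

    Exactly one of ``two_tier``/``three_tier`` is set, matching the tier
    vocabulary the profile's decision-table arm consumes.
    """

    profile: TransPatientProfile
    two_tier: Optional[TwoTier]
    three_tier: Optional[ThreeTier]


GRID_HORMONE_YEARS = tuple(range(0, 41))


def grid_size() -> int:
    """Analytic size of the exhaustive grid (for the count oracle)."""
    n_ages = MAX_AGE - MIN_AGE + 1
    n_h = len(GRID_HORMONE_YEARS)
    n_surgery = len(_SURGERIES)
    amab_tiers = len(TwoTier)
    afab_tiers = len(ThreeTier)
    n_identities_per_arm = 2
    return n_ages * n_h * n_surgery * n_identities_per_arm * (amab_tiers + afab_tiers)


def exhaustive_grid() -> Iterator[GridCase]:
    """Every profile on the discretized decision grid.

    Cross-product of ages 18-90 (step 1) x hormone years 0-40 x three
    surgery states x all four identities x the tier vocabulary of the
    routed arm. Consistency is enforced constructively (sex assigned at
    birth follows identity), so the yield count equals the analytic
    product with no post-hoc filtering.
    """
    for identity in _IDENTITY_ORDER:
        saab = expected_sex_at_birth(identity)
        amab = identity in AMAB_IDENTITIES
        tiers: tuple = tuple(TwoTier) if amab else tuple(ThreeTier)
        for age in range(MIN_AGE, MAX_AGE + 1):
            for hormones in GRID_HORMONE_YEARS:
                for surgery in _SURGERIES:
                    profile = TransPatientProfile(
                        gender_identity=identity,
                        sex_assigned_at_birth=saab,
                        age=age,
                        hormone_duration_years=float(hormones),
                        chest_surgery=surgery,
                    )
                    for tier in tiers:
                        if amab:
                            yield GridCase(profile, tier, None)
                        else:
                            yield GridCase(profile, None, tier)
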