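import pytest

from chestscreen import (
    GenderIdentity,
    RiskFactorProfile,
    SexAssignedAtBirth,
    TransPatientProfile,
)


@pytest.fixture
def reference_profile() -> RiskFactorProfile:
    """Fixed multi-factor reference: 45y, menarche 12-13, first birth 25-29,
    one biopsy without hyperplasia, one first-degree relative, White."""
    return RiskFactorProfile(
        current_age=45,
        age_at_menarche="12-13",
        age_at_first_live_birth="25-29_or_nulliparous",
        n_biopsies="1",
        atypical_hyperplasia="absent",
        n_first_degree_relatives="1",
        race_group="white",
    )


@pytest.fixture
def baseline_profile() -> RiskFactorProfile:
    """All factors at the baseline category."""
    return RiskFactorProfile(
        current_age=45,
        age_at_menarche="ge14",
        age_at_first_live_birth="lt20",
        n_biopsies="0",
        atypical_hyperplasia="unknown",
        n_first_degree_relatives="0",
        race_group="white",
    )


def transwoman(age: int, hormones: float, **kw) -> TransPatientProfile:
    return TransPatientProfile(
        gender_identity=GenderIdentity.TRANSFEMININE,
        sex_assigned_at_birth=SexAssignedAtBirth.MALE,
        age=age,
        hormone_duration_years=hormones,
        **kw,
    )


def transman(age: int, **kw) -> TransPatientProfile:
    kw.setdefault("hormone_duration_years", 0.0)
    return TransPatientProfile(
        gender_identity=GenderIdentity.TRANSMASCULINE,
        sex_assigned_at_birth=SexAssignedAtBirth.FEMALE,
        age=age,
        **kw,
    )
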