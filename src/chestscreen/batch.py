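"""Batch CSV scoring and the cohort CSV schema.

The batch schema has one header-named column per profile field; empty
cells mean "unknown" wherever the vocabulary allows it. The header is
validated before any row is scored; malformed rows are flagged in the
output (``error`` column) and never abort the batch. No patient data is
persisted or logged beyond the requested output file.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Optional

import pandas as pd

from .config import AppConfig, DEFAULT_CONFIG, DISCLAIMER, constants_version
from .errors import ProfileValidationError
from .pipeline import screen
from .profiles import (
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
)

logger = logging.getLogger(__name__)

INPUT_COLUMNS = [
    "gender_identity",
    "sex_assigned_at_birth",
    "age",
    "hormone_duration_years",
    "chest_surgery",
    "age_at_menarche",
    "age_at_first_live_birth",
    "n_biopsies",
    "atypical_hyperplasia",
    "n_first_degree_relatives",
    "race_group",
]

OUTPUT_COLUMNS = INPUT_COLUMNS + [
    "variant",
    "arm",
    "no_match_reason",
    "mammography_rating",
    "ultrasound_rating",
    "five_year_risk",
    "lifetime_risk",
    "three_tier",
    "two_tier",
    "extrapolated",
    "rationale",
    "reevaluation_hint",
    "error",
]

_UNKNOWNABLE = {
    "age_at_menarche": MenarcheCategory.UNKNOWN,
    "age_at_first_live_birth": FirstBirthCategory.UNKNOWN,
    "n_biopsies": BiopsyCategory.UNKNOWN,
    "atypical_hyperplasia": HyperplasiaStatus.UNKNOWN,
    "n_first_degree_relatives": RelativesCategory.UNKNOWN,
    "race_group": RaceGroup.OTHER_UNKNOWN,
}


def _cell(row: dict[str, Any], name: str) -> Optional[str]:
    value = row.get(name)
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    return text or None


def profiles_from_row(row: dict[str, Any]) -> tuple[TransPatientProfile, RiskFactorProfile]:
    """Parse one batch row into the two profile objects.

    Raises :class:`ProfileValidationError` (or pydantic's validation
    error) naming the offending field; the caller turns that into a
    per-row flag.
    """
    age_text = _cell(row, "age")
    if age_text is None:
        raise ProfileValidationError("age is required")
    identity_text = _cell(row, "gender_identity")
    if identity_text is None:
        raise ProfileValidationError("gender_identity is required")
    identity = GenderIdentity(identity_text)
    saab_text = _cell(row, "sex_assigned_at_birth")
    saab = (
        SexAssignedAtBirth(saab_text)
        if saab_text is not None
        else expected_sex_at_birth(identity)
    )
    trans_profile = TransPatientProfile(
        gender_identity=identity,
        sex_assigned_at_birth=saab,
        age=int(float(age_text)),
        hormone_duration_years=float(_cell(row, "hormone_duration_years") or 0.0),
        chest_surgery=ChestSurgery(_cell(row, "chest_surgery") or "none"),
    )
    kwargs: dict[str, Any] = {"current_age": trans_profile.age}
    for name, unknown in _UNKNOWNABLE.items():
        text = _cell(row, name)
        kwargs[name] = type(unknown)(text) if text is not None else unknown
    return trans_profile, RiskFactorProfile(**kwargs)


def row_from_profiles(
    trans_profile: TransPatientProfile, risk_profile: RiskFactorProfile
) -> dict[str, Any]:
    """Serialize a profile pair to one input-schema row."""
    return {
        "gender_identity": trans_profile.gender_identity.value,
        "sex_assigned_at_birth": trans_profile.sex_assigned_at_birth.value,
        "age": trans_profile.age,
        "hormone_duration_years": trans_profile.hormone_duration_years,
        "chest_surgery": trans_profile.chest_surgery.value,
        "age_at_menarche": risk_profile.age_at_menarche.value,
        "age_at_first_live_birth": risk_profile.age_at_first_live_birth.value,
        "n_biopsies": risk_profile.n_biopsies.value,
        "atypical_hyperplasia": risk_profile.atypical_hyperplasia.value,
        "n_first_degree_relatives": risk_profile.n_first_degree_relatives.value,
        "race_group": risk_profile.race_group.value,
    }


def cohort_to_csv(
    records: list[tuple[TransPatientProfile, RiskFactorProfile]], path: str | Path
) -> None:
    """Write a cohort in the batch input schema (round-trips losslessly)."""
    pd.DataFrame([row_from_profiles(t, r) for t, r in records], columns=INPUT_COLUMNS).to_csv(
        path, index=False
    )


def cohort_from_csv(path: str | Path) -> list[tuple[TransPatientProfile, RiskFactorProfile]]:
    df = read_batch_input(path)
    return [profiles_from_row(row) for row in df.to_dict(orient="records")]


def read_batch_input(path: str | Path) -> pd.DataFrame:
    """Read and header-validate a batch CSV (no rows scored yet)."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in INPUT_COLUMNS if c not in df.columns]
    if missing:
        raise ProfileValidationError(
            f"batch input {path} is missing required columns: {missing}"
        )
    return df


def score_row(row: dict[str, Any], config: AppConfig = DEFAULT_CONFIG) -> dict[str, Any]:
    """Score one row; on failure return the row with the error flagged."""
    out = {c: row.get(c) for c in INPUT_COLUMNS}
    out.update({c: None for c in OUTPUT_COLUMNS if c not in INPUT_COLUMNS})
    try:
        trans_profile, risk_profile = profiles_from_row(row)
        report = screen(trans_profile, risk_profile, config)
    except (ProfileValidationError, ValueError) as exc:
        out["error"] = str(exc)
        return out
    rec = report.recommendation
    out.update(
        {
            "variant": rec.variant.id.value,
            "arm": rec.variant.arm.value,
            "no_match_reason": rec.variant.no_match_reason.value
            if rec.variant.no_match_reason
            else None,
            "mammography_rating": rec.mammography_rating.value,
            "ultrasound_rating": rec.ultrasound_rating.value,
            "extrapolated": rec.extrapolated,
            "rationale": rec.rationale,
            "reevaluation_hint": rec.reevaluation_hint,
        }
    )
    if report.estimate is not None:
        out.update(
            {
                "five_year_risk": report.estimate.five_year_risk,
                "lifetime_risk": report.estimate.lifetime_risk,
                "three_tier": report.estimate.three_tier.value,
                "two_tier": report.estimate.two_tier.value,
            }
        )
    return out


def run_batch(
    input_path: str | Path,
    output_path: str | Path,
    config: AppConfig = DEFAULT_CONFIG,
) -> dict[str, int]:
    """Score a batch CSV; returns the summary ``{"scored": .., "errors": ..}``.

    Output format follows the extension: ``.json`` writes a list of
    records, anything else a CSV with :data:`OUTPUT_COLUMNS`.
    """
    df = read_batch_input(input_path)
    results = [score_row(row, config) for row in df.to_dict(orient="records")]
    out = pd.DataFrame(results, columns=OUTPUT_COLUMNS)
    output_path = Path(output_path)
    if output_path.suffix.lower() == ".json":
        output_path.write_text(json.dumps(results, indent=2, default=str), encoding="utf-8")
    else:
        out.to_csv(output_path, index=False)
    summary = {
        "scored": int(out["error"].isna().sum()),
        "errors": int(out["error"].notna().sum()),
    }
    logger.info(
        "%s | constants version %s | %d scored, %d rows flagged",
        DISCLAIMER,
        constants_version(),
        summary["scored"],
        summary["errors"],
    )
    return summary
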