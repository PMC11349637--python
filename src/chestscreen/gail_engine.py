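"""Absolute breast-cancer risk engine (Gail-model family).

The model projects the probability that a person free of invasive breast
cancer at a start age develops it before an end age, combining

* a multiplicative relative risk built from discrete risk-factor
  categories (age at menarche, age at first live birth, number of breast
  biopsies, atypical hyperplasia, first-degree relatives with breast
  cancer), with separate coefficients below and at/above attained age 50
  and two interaction terms (biopsies x age stratum; first birth x
  relatives);
* race-group-specific composite incidence hazards on 5-year age bands,
  deflated by the attributable-risk complement ``1-AR`` so that the
  baseline-category population carries the baseline hazard; and
* competing non-breast-cancer mortality on the same bands.

Hazards are piecewise constant, so the absolute risk over an interval has
an exact closed form: splitting the interval at band edges (age 50 is a
band edge), each segment with cause-specific hazard ``h1`` and competing
hazard ``h2`` contributes ``S * h1/(h1+h2) * (1 - exp(-(h1+h2)*dt))``
where ``S`` is the probability of having survived both causes through all
earlier segments.

Constant tables are shipped as human-readable YAML, one file per race
group (see ``data/gail/``); ``other_unknown`` resolves to the White block,
following the convention of the public NCI tool.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from importlib import resources
from typing import Mapping, NamedTuple, Sequence

import yaml
from pydantic import BaseModel, ConfigDict

from .errors import ConfigurationError, InternalConsistencyError, ProfileValidationError
from .profiles import (
    BiopsyCategory,
    FirstBirthCategory,
    HyperplasiaStatus,
    MenarcheCategory,
    RaceGroup,
    RelativesCategory,
    RiskFactorProfile,
)

logger = logging.getLogger(__name__)

PROJECTION_FLOOR = 20.0  # youngest age covered by the hazard bands
PROJECTION_CEILING = 90.0  # exclusive upper end of the projection window
AGE_STRATUM_SPLIT = 50.0  # relative risk switches coefficients here

_CONSTANTS_FILES: Mapping[RaceGroup, str] = {
    RaceGroup.WHITE: "white.yaml",
    RaceGroup.BLACK: "black_hazards_synthetic.yaml",
    RaceGroup.HISPANIC: "hispanic_hazards_synthetic.yaml",
    RaceGroup.ASIAN_PACIFIC_ISLANDER: "asian_pacific_islander_hazards_synthetic.yaml",
    # NCI convention: unknown/other race scored with the White block.
    RaceGroup.OTHER_UNKNOWN: "white.yaml",
}

_MENARCHE_INDEX = {
    MenarcheCategory.GE_14: 0,
    MenarcheCategory.AGE_12_13: 1,
    MenarcheCategory.LT_12: 2,
    MenarcheCategory.UNKNOWN: 0,
}
_FIRST_BIRTH_INDEX = {
    FirstBirthCategory.LT_20: 0,
    FirstBirthCategory.AGE_20_24: 1,
    FirstBirthCategory.AGE_25_29_OR_NULLIPAROUS: 2,
    FirstBirthCategory.GE_30: 3,
    FirstBirthCategory.UNKNOWN: 0,
}
_BIOPSY_INDEX = {
    BiopsyCategory.NONE: 0,
    BiopsyCategory.ONE: 1,
    BiopsyCategory.GE_2: 2,
    BiopsyCategory.UNKNOWN: 0,
}
_RELATIVES_INDEX = {
    RelativesCategory.NONE: 0,
    RelativesCategory.ONE: 1,
    RelativesCategory.GE_2: 2,
    RelativesCategory.UNKNOWN: 0,
}


class AgeStratum(str, Enum):
    UNDER_50 = "<50"
    GE_50 = ">=50"


class FactorIndices(NamedTuple):
    """One category index per risk factor (0 = baseline)."""

    menarche: int
    first_birth: int
    biopsies: int
    relatives: int
    hyperplasia: int


@dataclass(frozen=True)
class GailModelConstants:
    """One race group's coefficient and hazard block."""

    race_group: str
    version: str
    band_start: int
    band_width: int
    n_bands: int
    coefficients: Mapping[str, tuple[float, ...]]
    inter_biopsies_age_ge50: float
    inter_first_birth_x_relatives: float
    one_minus_ar_under_50: float
    one_minus_ar_ge_50: float
    baseline_hazard: tuple[float, ...]
    competing_hazard: tuple[float, ...]
    hazards_synthetic: bool = False

    def __post_init__(self) -> None:
        expected_lengths = {
            "age_at_menarche": 3,
            "age_at_first_live_birth": 4,
            "n_biopsies": 3,
            "n_first_degree_relatives": 3,
            "atypical_hyperplasia": 3,
        }
        for name, n in expected_lengths.items():
            block = self.coefficients.get(name)
            if block is None or len(block) != n:
                raise InternalConsistencyError(
                    f"constants[{self.race_group}]: coefficient block {name!r} "
                    f"missing or wrong length (expected {n})"
                )
            if block[0] != 0.0:
                raise InternalConsistencyError(
                    f"constants[{self.race_group}]: baseline coefficient of "
                    f"{name!r} must be 0"
                )
        for name, rates in (
            ("baseline_hazard", self.baseline_hazard),
            ("competing_hazard", self.competing_hazard),
        ):
            if len(rates) != self.n_bands:
                raise InternalConsistencyError(
                    f"constants[{self.race_group}]: {name} has {len(rates)} "
                    f"bands, expected {self.n_bands}"
                )
            if any(r < 0 for r in rates):
                raise InternalConsistencyError(
                    f"constants[{self.race_group}]: negative rate in {name}"
                )
        if self.band_start + self.band_width * self.n_bands != PROJECTION_CEILING:
            raise InternalConsistencyError(
                f"constants[{self.race_group}]: age bands do not tile "
                f"[{self.band_start}, {PROJECTION_CEILING})"
            )
        if not (0 < self.one_minus_ar_under_50 <= 1 and 0 < self.one_minus_ar_ge_50 <= 1):
            raise InternalConsistencyError(
                f"constants[{self.race_group}]: 1-AR values must lie in (0, 1]"
            )

    def band_index(self, age: float) -> int:
        if not (self.band_start <= age < PROJECTION_CEILING):
            raise ValueError(f"age {age} outside [{self.band_start}, {PROJECTION_CEILING})")
        return int((age - self.band_start) // self.band_width)

    def band_edges(self) -> list[float]:
        return [
            float(self.band_start + i * self.band_width) for i in range(self.n_bands + 1)
        ]


@lru_cache(maxsize=None)
def load_constants(race_group: RaceGroup = RaceGroup.WHITE) -> GailModelConstants:
    """Load (and cache) the constant block for one race group."""
    race_group = RaceGroup(race_group)
    filename = _CONSTANTS_FILES[race_group]
    text = (
        resources.files("chestscreen").joinpath("data").joinpath("gail").joinpath(filename)
    ).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    bands = raw["age_bands"]
    return GailModelConstants(
        race_group=raw["race_group"],
        version=str(raw["version"]),
        band_start=int(bands["start"]),
        band_width=int(bands["width"]),
        n_bands=int(bands["count"]),
        coefficients={k: tuple(float(x) for x in v) for k, v in raw["coefficients"].items()},
        inter_biopsies_age_ge50=float(raw["interactions"]["biopsies_age_ge50"]),
        inter_first_birth_x_relatives=float(
            raw["interactions"]["first_birth_x_relatives"]
        ),
        one_minus_ar_under_50=float(raw["one_minus_ar"]["under_50"]),
        one_minus_ar_ge_50=float(raw["one_minus_ar"]["ge_50"]),
        baseline_hazard=tuple(float(x) for x in raw["baseline_hazard"]),
        competing_hazard=tuple(float(x) for x in raw["competing_hazard"]),
        hazards_synthetic=bool(raw.get("hazards_synthetic", False)),
    )


def categorize_risk_factors(profile: RiskFactorProfile) -> FactorIndices:
    """Map a profile to one category index per factor (unknown -> baseline).

    The atypical-hyperplasia index follows the model's convention: 0 when
    there is no (or unknown) biopsy history or the hyperplasia finding is
    unknown, 1 for biopsy-positive histories without atypical hyperplasia,
    2 when atypical hyperplasia was found.
    """
    biopsies = _BIOPSY_INDEX[profile.n_biopsies]
    if biopsies == 0 or profile.atypical_hyperplasia is HyperplasiaStatus.UNKNOWN:
        hyperplasia = 0
    elif profile.atypical_hyperplasia is HyperplasiaStatus.ABSENT:
        hyperplasia = 1
    else:
        hyperplasia = 2
    return FactorIndices(
        menarche=_MENARCHE_INDEX[profile.age_at_menarche],
        first_birth=_FIRST_BIRTH_INDEX[profile.age_at_first_live_birth],
        biopsies=biopsies,
        relatives=_RELATIVES_INDEX[profile.n_first_degree_relatives],
        hyperplasia=hyperplasia,
    )


def relative_risk(
    indices: FactorIndices,
    age_stratum: AgeStratum | str,
    constants: GailModelConstants | None = None,
) -> float:
    """Multiplicative relative risk versus the all-baseline profile."""
    constants = constants or load_constants()
    age_stratum = AgeStratum(age_stratum)
    coef = constants.coefficients
    try:
        log_rr = (
            coef["age_at_menarche"][indices.menarche]
            + coef["age_at_first_live_birth"][indices.first_birth]
            + coef["n_biopsies"][indices.biopsies]
            + coef["n_first_degree_relatives"][indices.relatives]
            + coef["atypical_hyperplasia"][indices.hyperplasia]
        )
    except IndexError as exc:
        raise InternalConsistencyError(
            f"category index {indices} out of range for constants "
            f"block {constants.race_group!r}"
        ) from exc
    log_rr += constants.inter_first_birth_x_relatives * indices.first_birth * indices.relatives
    if age_stratum is AgeStratum.GE_50:
        log_rr += constants.inter_biopsies_age_ge50 * indices.biopsies
    return math.exp(log_rr)


def _segments(start: float, end: float, edges: Sequence[float]) -> list[tuple[float, float]]:
    """Split [start, end) at every interior band edge."""
    cuts = [start] + [e for e in edges if start < e < end] + [end]
    return [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1)]


def absolute_risk(
    profile: RiskFactorProfile,
    start_age: float,
    end_age: float,
    constants: GailModelConstants | None = None,
) -> float:
    """Absolute risk of invasive breast cancer over ``[start_age, end_age)``.

    Exact closed form for piecewise-constant hazards with competing
    mortality. The interval is clipped to the hazard tables' support
    ``[20, 90)`` (with a logged warning); a reversed interval is an error.
    """
    if end_age < start_age:
        raise ProfileValidationError(
            f"reversed projection interval [{start_age}, {end_age})"
        )
    if start_age < profile.current_age:
        raise ProfileValidationError(
            f"start_age {start_age} precedes current_age {profile.current_age}"
        )
    constants = constants or load_constants(profile.race_group)
    s = max(float(start_age), float(PROJECTION_FLOOR))
    e = min(float(end_age), float(PROJECTION_CEILING))
    if (s, e) != (float(start_age), float(end_age)):
        logger.warning(
            "projection interval [%s, %s) clipped to [%s, %s) — hazard tables "
            "cover ages [20, 90) only",
            start_age, end_age, s, e,
        )
    if s >= e:
        return 0.0

    indices = categorize_risk_factors(profile)
    rr = {
        AgeStratum.UNDER_50: relative_risk(indices, AgeStratum.UNDER_50, constants),
        AgeStratum.GE_50: relative_risk(indices, AgeStratum.GE_50, constants),
    }
    one_minus_ar = {
        AgeStratum.UNDER_50: constants.one_minus_ar_under_50,
        AgeStratum.GE_50: constants.one_minus_ar_ge_50,
    }

    survival = 1.0
    risk = 0.0
    for u, v in _segments(s, e, constants.band_edges()):
        stratum = AgeStratum.UNDER_50 if u < AGE_STRATUM_SPLIT else AgeStratum.GE_50
        j = constants.band_index(u)
        h1 = constants.baseline_hazard[j] * one_minus_ar[stratum] * rr[stratum]
        h2 = constants.competing_hazard[j]
        h = h1 + h2
        dt = v - u
        if h > 0.0:
            decay = math.exp(-h * dt)
            risk += survival * (h1 / h) * (1.0 - decay)
            survival *= decay
    return risk


class ThreeTier(str, Enum):
    AVERAGE = "average"
    INTERMEDIATE = "intermediate"
    HIGH = "high"


class TwoTier(str, Enum):
    AVERAGE = "average"
    HIGHER_THAN_AVERAGE = "higher_than_average"


class RiskThresholds(BaseModel):
    """Tier cut-points on the two projected probabilities.

    Defaults follow the screening-guideline convention (lifetime risk
    under 15% average, 15-20% intermediate, 20%+ high) and the risk
    tool's elevated short-term threshold (5-year risk of 1.67%). All
    boundaries are closed on the lower side: a lifetime risk of exactly
    0.15 is intermediate and exactly 0.20 is high.
    """

    model_config = ConfigDict(frozen=True)

    lifetime_low: float = 0.15
    lifetime_high: float = 0.20
    five_year_elevated: float = 0.0167

    def validated(self) -> "RiskThresholds":
        if not (0.0 < self.lifetime_low < self.lifetime_high < 1.0):
            raise ConfigurationError(
                f"lifetime thresholds must satisfy 0 < low < high < 1 "
                f"(got low={self.lifetime_low}, high={self.lifetime_high})"
            )
        if not (0.0 < self.five_year_elevated < 1.0):
            raise ConfigurationError(
                f"five_year_elevated must lie in (0, 1) (got {self.five_year_elevated})"
            )
        return self


DEFAULT_RISK_THRESHOLDS = RiskThresholds()


class GailRiskEstimate(BaseModel):
    """Projected risks plus the derived categorical tiers."""

    model_config = ConfigDict(frozen=True)

    five_year_risk: float
    lifetime_risk: float
    three_tier: ThreeTier
    two_tier: TwoTier


def classify_gail_category(
    five_year_risk: float,
    lifetime_risk: float,
    thresholds: RiskThresholds = DEFAULT_RISK_THRESHOLDS,
) -> tuple[ThreeTier, TwoTier]:
    """Tier the two projected probabilities (total on [0, 1) x [0, 1))."""
    thresholds.validated()
    for name, p in (("five_year_risk", five_year_risk), ("lifetime_risk", lifetime_risk)):
        if not (0.0 <= p < 1.0):
            raise ProfileValidationError(f"{name} must lie in [0, 1) (got {p})")
    if lifetime_risk < thresholds.lifetime_low:
        three = ThreeTier.AVERAGE
    elif lifetime_risk < thresholds.lifetime_high:
        three = ThreeTier.INTERMEDIATE
    else:
        three = ThreeTier.HIGH
    elevated = three is not ThreeTier.AVERAGE or five_year_risk >= thresholds.five_year_elevated
    two = TwoTier.HIGHER_THAN_AVERAGE if elevated else TwoTier.AVERAGE
    return three, two


def estimate_risk(
    profile: RiskFactorProfile,
    constants: GailModelConstants | None = None,
    thresholds: RiskThresholds = DEFAULT_RISK_THRESHOLDS,
) -> GailRiskEstimate:
    """Project 5-year and lifetime (to age 90) risk and derive the tiers.

    Projections start at ``max(current_age, 20)``: the hazard tables
    begin at age 20, so for 18- and 19-year-olds the first one or two
    years contribute no modelled risk.
    """
    constants = constants or load_constants(profile.race_group)
    start = max(float(profile.current_age), PROJECTION_FLOOR)
    five = absolute_risk(profile, start, min(start + 5.0, PROJECTION_CEILING), constants)
    life = absolute_risk(profile, start, PROJECTION_CEILING, constants)
    three, two = classify_gail_category(five, life, thresholds)
    return GailRiskEstimate(
        five_year_risk=five, lifetime_risk=life, three_tier=three, two_tier=two
    )
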