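"""Unit and property tests for the absolute-risk engine."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chestscreen import (
    AgeStratum,
    FactorIndices,
    ProfileValidationError,
    RaceGroup,
    RiskFactorProfile,
    RiskThresholds,
    ThreeTier,
    TwoTier,
    absolute_risk,
    categorize_risk_factors,
    classify_gail_category,
    estimate_risk,
    load_constants,
    relative_risk,
)
from chestscreen.errors import ConfigurationError

from oracles import load_raw_constants, numeric_absolute_risk, oracle_relative_risk


class TestCategorize:
    def test_all_baseline_maps_to_zero_vector(self, baseline_profile):
        assert categorize_risk_factors(baseline_profile) == FactorIndices(0, 0, 0, 0, 0)

    def test_unknowns_map_to_baseline(self):
        profile = RiskFactorProfile(current_age=40)  # everything unknown
        assert categorize_risk_factors(profile) == FactorIndices(0, 0, 0, 0, 0)

    def test_hyperplasia_without_biopsy_rejected(self):
        # pydantic wraps the invariant's ProfileValidationError
        with pytest.raises(ValueError, match="n_biopsies"):
            RiskFactorProfile(
                current_age=40, atypical_hyperplasia="present", n_biopsies="0"
            )

    def test_out_of_range_age_rejected(self):
        with pytest.raises(Exception, match="current_age"):
            RiskFactorProfile(current_age=17)

    def test_non_baseline_vector(self):
        """Menarche <12, 1 biopsy, 1 relative, first birth >=30 land on the
        non-baseline indices of the shipped category tables."""
        profile = RiskFactorProfile(
            current_age=40,
            age_at_menarche="lt12",
            n_biopsies="1",
            n_first_degree_relatives="1",
            age_at_first_live_birth="ge30",
        )
        idx = categorize_risk_factors(profile)
        assert idx == FactorIndices(menarche=2, first_birth=3, biopsies=1, relatives=1, hyperplasia=0)
        # index positions line up with the per-category coefficient tables
        raw = load_raw_constants("white")
        assert len(raw["coefficients"]["age_at_menarche"]) == 3
        assert len(raw["coefficients"]["age_at_first_live_birth"]) == 4

    def test_hyperplasia_index_depends_on_biopsy_history(self):
        present = RiskFactorProfile(
            current_age=40, n_biopsies="1", atypical_hyperplasia="present"
        )
        absent = RiskFactorProfile(
            current_age=40, n_biopsies="1", atypical_hyperplasia="absent"
        )
        unknown = RiskFactorProfile(current_age=40, n_biopsies="1")
        assert categorize_risk_factors(present).hyperplasia == 2
        assert categorize_risk_factors(absent).hyperplasia == 1
        assert categorize_risk_factors(unknown).hyperplasia == 0


@st.composite
def _index_strategy(draw) -> FactorIndices:
    biopsies = draw(st.integers(0, 2))
    # the hyperplasia index is only defined for biopsy-positive histories
    hyperplasia = draw(st.integers(0, 2)) if biopsies else 0
    return FactorIndices(
        menarche=draw(st.integers(0, 2)),
        first_birth=draw(st.integers(0, 3)),
        biopsies=biopsies,
        relatives=draw(st.integers(0, 2)),
        hyperplasia=hyperplasia,
    )


_INDEX_STRATEGY = _index_strategy()


class TestRelativeRisk:
    @pytest.mark.parametrize("stratum", list(AgeStratum))
    @pytest.mark.parametrize("race", list(RaceGroup))
    def test_baseline_is_exactly_one(self, stratum, race):
        constants = load_constants(race)
        assert relative_risk(FactorIndices(0, 0, 0, 0, 0), stratum, constants) == 1.0

    @pytest.mark.parametrize(
        "idx, coef_name, position",
        [
            (FactorIndices(1, 0, 0, 0, 0), "age_at_menarche", 1),
            (FactorIndices(2, 0, 0, 0, 0), "age_at_menarche", 2),
            (FactorIndices(0, 3, 0, 0, 0), "age_at_first_live_birth", 3),
            (FactorIndices(0, 0, 2, 0, 0), "n_biopsies", 2),
            (FactorIndices(0, 0, 0, 1, 0), "n_first_degree_relatives", 1),
        ],
    )
    def test_single_factor_is_exp_of_its_coefficient(self, idx, coef_name, position):
        raw = load_raw_constants("white")
        expected = math.exp(raw["coefficients"][coef_name][position])
        assert relative_risk(idx, AgeStratum.UNDER_50) == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(idx=_INDEX_STRATEGY, ge50=st.booleans(), race=st.sampled_from(list(RaceGroup)))
    def test_matches_sorted_order_summation_oracle(self, idx, ge50, race):
        constants = load_constants(race)
        stratum = AgeStratum.GE_50 if ge50 else AgeStratum.UNDER_50
        raw = load_raw_constants(race.value)
        assert relative_risk(idx, stratum, constants) == pytest.approx(
            oracle_relative_risk(raw, idx, ge50), rel=1e-12
        )

    @settings(max_examples=100, deadline=None)
    @given(
        menarche=st.integers(1, 2),
        biopsies=st.integers(1, 2),
        ge50=st.booleans(),
    )
    def test_multiplicative_for_disjoint_deviations(self, menarche, biopsies, ge50):
        """Single-factor deviations with no shared interaction term compose
        multiplicatively (menarche and biopsies never interact)."""
        stratum = AgeStratum.GE_50 if ge50 else AgeStratum.UNDER_50
        both = relative_risk(FactorIndices(menarche, 0, biopsies, 0, 0), stratum)
        only_men = relative_risk(FactorIndices(menarche, 0, 0, 0, 0), stratum)
        only_bio = relative_risk(FactorIndices(0, 0, biopsies, 0, 0), stratum)
        assert both == pytest.approx(only_men * only_bio, rel=1e-12)

    def test_first_birth_relatives_share_an_interaction(self):
        """The documented exception: first birth x relatives do interact."""
        both = relative_risk(FactorIndices(0, 2, 0, 1, 0), AgeStratum.UNDER_50)
        fb = relative_risk(FactorIndices(0, 2, 0, 0, 0), AgeStratum.UNDER_50)
        rel = relative_risk(FactorIndices(0, 0, 0, 1, 0), AgeStratum.UNDER_50)
        raw = load_raw_constants("white")
        inter = math.exp(raw["interactions"]["first_birth_x_relatives"] * 2 * 1)
        assert both == pytest.approx(fb * rel * inter, rel=1e-12)


class TestAbsoluteRisk:
    def test_empty_interval_is_zero(self, reference_profile):
        assert absolute_risk(reference_profile, 45, 45) == 0.0

    def test_reversed_interval_rejected(self, reference_profile):
        with pytest.raises(ProfileValidationError, match="reversed"):
            absolute_risk(reference_profile, 50, 45)

    def test_start_before_current_age_rejected(self, reference_profile):
        with pytest.raises(ProfileValidationError, match="current_age"):
            absolute_risk(reference_profile, 30, 50)

    def test_interval_clipped_with_warning(self, caplog):
        profile = RiskFactorProfile(current_age=18)
        with caplog.at_level("WARNING", logger="chestscreen.gail_engine"):
            risk = absolute_risk(profile, 18, 95)
        assert any("clipped" in r.message for r in caplog.records)
        assert 0 < risk < 1

    def test_all_baseline_reduces_to_adjusted_baseline_risk(self, baseline_profile):
        """With RR = 1 the closed form is the attributable-risk-adjusted
        baseline cumulative risk; recompute it directly from the YAML."""
        raw = load_raw_constants("white")
        risk = 0.0
        survival = 1.0
        for j in range(14):
            lo, hi = 20 + 5 * j, 25 + 5 * j
            oar = raw["one_minus_ar"]["under_50" if lo < 50 else "ge_50"]
            h1 = raw["baseline_hazard"][j] * oar
            h2 = raw["competing_hazard"][j]
            h = h1 + h2
            if hi <= 45:
                continue
            dt = hi - max(lo, 45)
            risk += survival * (h1 / h) * (1 - math.exp(-h * dt))
            survival *= math.exp(-h * dt)
        assert absolute_risk(baseline_profile, 45, 90) == pytest.approx(risk, abs=1e-15)

    def test_reference_profile_matches_numeric_integrator(self, reference_profile):
        raw = load_raw_constants("white")
        idx = categorize_risk_factors(reference_profile)
        closed = absolute_risk(reference_profile, 45, 50)
        numeric = numeric_absolute_risk(raw, idx, 45, 50)
        assert closed == pytest.approx(numeric, abs=1e-6)

    def test_monotone_in_end_age(self, reference_profile):
        risks = [absolute_risk(reference_profile, 45, end) for end in range(45, 91)]
        assert all(b >= a for a, b in zip(risks, risks[1:]))

    def test_scaling_competing_mortality_never_increases_risk(self, reference_profile):
        constants = load_constants(RaceGroup.WHITE)
        base = absolute_risk(reference_profile, 45, 90, constants)
        for scale in (1.5, 3.0, 10.0):
            scaled = dataclasses.replace(
                constants,
                competing_hazard=tuple(scale * h for h in constants.competing_hazard),
            )
            assert absolute_risk(reference_profile, 45, 90, scaled) <= base

    def test_zero_hazards_give_exactly_zero(self, reference_profile):
        constants = load_constants(RaceGroup.WHITE)
        zeroed = dataclasses.replace(
            constants, baseline_hazard=(0.0,) * 14, competing_hazard=(0.0,) * 14
        )
        assert absolute_risk(reference_profile, 45, 90, zeroed) == 0.0

    def test_huge_relative_risk_stays_below_one(self):
        """Push the hazard scale up several orders of magnitude: the
        competing-risk closed form must stay a probability."""
        constants = load_constants(RaceGroup.WHITE)
        profile = RiskFactorProfile(
            current_age=20,
            age_at_menarche="lt12",
            age_at_first_live_birth="ge30",
            n_biopsies="2+",
            atypical_hyperplasia="present",
            n_first_degree_relatives="2+",
        )
        inflated = dataclasses.replace(
            constants, baseline_hazard=tuple(1e4 * h for h in constants.baseline_hazard)
        )
        risk = absolute_risk(profile, 20, 90, inflated)
        assert 0.99 < risk < 1.0

    def test_five_year_never_exceeds_lifetime(self, reference_profile):
        est = estimate_risk(reference_profile)
        assert 0 <= est.five_year_risk <= est.lifetime_risk < 1


class TestClassifyCategory:
    def test_far_below_thresholds_is_average(self):
        assert classify_gail_category(0.005, 0.05) == (ThreeTier.AVERAGE, TwoTier.AVERAGE)

    def test_above_high_threshold(self):
        three, two = classify_gail_category(0.005, 0.25)
        assert three is ThreeTier.HIGH
        assert two is TwoTier.HIGHER_THAN_AVERAGE

    def test_boundaries_closed_on_lower_side(self):
        assert classify_gail_category(0.0, 0.15)[0] is ThreeTier.INTERMEDIATE
        assert classify_gail_category(0.0, 0.20)[0] is ThreeTier.HIGH
        assert classify_gail_category(0.0167, 0.05) == (
            ThreeTier.AVERAGE,
            TwoTier.HIGHER_THAN_AVERAGE,
        )

    def test_elevated_five_year_alone_raises_two_tier(self):
        three, two = classify_gail_category(0.02, 0.05)
        assert three is ThreeTier.AVERAGE
        assert two is TwoTier.HIGHER_THAN_AVERAGE

    def test_malformed_thresholds_rejected(self):
        bad = RiskThresholds(lifetime_low=0.25, lifetime_high=0.20)
        with pytest.raises(ConfigurationError):
            classify_gail_category(0.01, 0.1, bad)

    @pytest.mark.parametrize("threshold", [0.15, 0.20])
    def test_exactly_one_flip_per_lifetime_threshold(self, threshold):
        """ulp-scan around each lifetime threshold: the three-level tier
        changes exactly once."""
        points = [np.nextafter(threshold, 0), threshold, np.nextafter(threshold, 1)]
        tiers = [classify_gail_category(0.0, p)[0] for p in points]
        flips = sum(a != b for a, b in zip(tiers, tiers[1:]))
        assert flips == 1
        assert tiers[1] == tiers[2]  # closed lower bound

    def test_exactly_one_flip_at_five_year_threshold(self):
        t = 0.0167
        points = [np.nextafter(t, 0), t, np.nextafter(t, 1)]
        tiers = [classify_gail_category(p, 0.05)[1] for p in points]
        assert sum(a != b for a, b in zip(tiers, tiers[1:])) == 1
        assert tiers[1] is TwoTier.HIGHER_THAN_AVERAGE

    @settings(max_examples=300, deadline=None)
    @given(five=st.floats(0, 0.9999), life=st.floats(0, 0.9999))
    def test_total_on_unit_square(self, five, life):
        three, two = classify_gail_category(five, life)
        assert three in ThreeTier and two in TwoTier
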