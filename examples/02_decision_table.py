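"""Match transgender patient profiles against the screening decision table.

Scores two scenarios directly (a 52-year-old transfeminine patient with
8 years of hormone therapy at average risk; a transmasculine patient
with bilateral mastectomy), then prints the full table facsimile.
"""

from chestscreen import (
    ChestSurgery,
    TransPatientProfile,
    TwoTier,
    classify_variant,
    decision_table,
    recommend,
    render_decision_table,
)

tw = TransPatientProfile(
    gender_identity="transfeminine",
    sex_assigned_at_birth="male",
    age=52,
    hormone_duration_years=8.0,
)
variant = classify_variant(tw, two_tier=TwoTier.AVERAGE)
rec = recommend(variant)
print(f"{variant.id.value}: mammography {rec.mammography_rating.value}")

tm = TransPatientProfile(
    gender_identity="transmasculine",
    sex_assigned_at_birth="female",
    age=35,
    hormone_duration_years=4.0,
    chest_surgery=ChestSurgery.BILATERAL_MASTECTOMY,
)
variant = classify_variant(tm)  # the mastectomy row covers any risk
rec = recommend(variant)
print(f"{variant.id.value}: mammography {rec.mammography_rating.value}")

print()
print("Full decision table (distinct rule cells):")
print(render_decision_table(decision_table()))
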