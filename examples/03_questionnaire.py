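"""Drive the 16-item yes/no questionnaire from a recorded answer string.

The string encodes a patient assigned female at birth, transmasculine,
no chest surgery, age 40+, no family history, no biopsies, menarche at
12 or later, first birth before 30 — landing on the average-risk
transman row.
"""

from chestscreen import replay

result = replay("NNNNYYYNNNN")

print("answers      :", "".join("Y" if a else "N" for _, a in result.answered))
print("profile      :", result.trans_profile.gender_identity.value,
      f"age {result.trans_profile.age}")
if result.estimate is not None:
    print(f"lifetime risk: {result.estimate.lifetime_risk:.4f} "
          f"({result.estimate.three_tier.value})")
print("variant      :", result.recommendation.variant.id.value)
print("mammography  :", result.recommendation.mammography_rating.value)
print()
print(
    "The questionnaire reconstructs the same profiles the direct API "
    "consumes; its recommendation is identical to classify_variant + "
    "recommend on those profiles (a property the test suite checks over "
    "every path)."
)
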