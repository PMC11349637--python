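"""Project absolute breast-cancer risk for one risk-factor profile.

Builds a 45-year-old with menarche at 12-13, first live birth at 25-29,
one benign biopsy and one first-degree relative with breast cancer, then
prints the 5-year and lifetime (to age 90) absolute risks and the
categorical tiers derived from them.
"""

from chestscreen import RiskFactorProfile, estimate_risk

profile = RiskFactorProfile(
    current_age=45,
    age_at_menarche="12-13",
    age_at_first_live_birth="25-29_or_nulliparous",
    n_biopsies="1",
    atypical_hyperplasia="absent",
    n_first_degree_relatives="1",
    race_group="white",
)

est = estimate_risk(profile)
print(f"5-year risk : {est.five_year_risk:.4f}")
print(f"lifetime    : {est.lifetime_risk:.4f}")
print(f"three-tier  : {est.three_tier.value}")
print(f"two-tier    : {est.two_tier.value}")
print()
print(
    "The 5-year figure is the probability of an invasive breast cancer "
    "diagnosis in the next five years, net of competing mortality; the "
    "lifetime figure projects to age 90. The tiers feed the screening "
    "decision table."
)
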