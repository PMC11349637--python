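# chestscreen

Chest/breast cancer screening decision support for transgender and
nonbinary patients.

Standard breast cancer screening guidance was developed around cisgender
populations, and primary-care clinicians often lack a concise,
evidence-anchored way to decide *whether and how* to image a transgender
patient's chest. `chestscreen` combines the two pieces such a decision
needs:

1. **An absolute-risk engine** in the Gail-model (BCRAT) family. It
   projects the probability of invasive breast cancer over an age
   interval from the classical risk factors — age at menarche, age at
   first live birth, number of breast biopsies, atypical hyperplasia,
   and first-degree family history — combining a category-based relative
   risk `RR = exp(Σ βᵢxᵢ)` (with separate coefficients below/above
   attained age 50 and two interaction terms) with race-group-specific
   composite incidence hazards `λ₁(t)`, an attributable-risk correction
   `(1−AR)`, and competing mortality `λ₂(t)` on 5-year age bands:

   `P(a, b) = Σⱼ S(tⱼ) · h₁ⱼ/(h₁ⱼ+λ₂ⱼ) · (1 − e^{−(h₁ⱼ+λ₂ⱼ)Δⱼ})`,
   with `h₁ⱼ = λ₁ⱼ (1−AR) RRⱼ` and `S` the joint survival through
   earlier bands. Lifetime risk projects to age 90; tiers default to
   lifetime <15% *average*, 15–20% *intermediate*, ≥20% *high*, with a
   5-year risk ≥1.67% also counting as *higher than average*.

2. **An appropriateness-criteria decision table** with eight published
   clinical variants: a transwoman arm conditioned on age, cumulative
   gender-affirming hormone exposure (split at 5 years) and the
   two-level risk tier, and a transman arm conditioned on age, chest
   surgical history and the three-level tier, with bilateral ("top")
   mastectomy dominating everything else on that arm. Profiles no
   published row covers return an explicit `NO_MATCH` with a reason and
   a re-evaluation hint; nonbinary identities are routed by sex assigned
   at birth and tagged as extrapolations.

Both are exposed three ways: a direct Python API, a **16-item yes/no
questionnaire** whose every terminal path provably emits the same
recommendation as the direct classifiers, and a thin CLI for
interactive, machine-string, and batch-CSV use.

This is decision support, not diagnosis: outputs carry a disclaimer and
the constants version, and nothing is persisted beyond the requested
output file.

## Worked example

```python
from chestscreen import RiskFactorProfile, TransPatientProfile, screen

risk = RiskFactorProfile(
    current_age=45, age_at_menarche="12-13",
    age_at_first_live_birth="25-29_or_nulliparous",
    n_biopsies="1", atypical_hyperplasia="absent",
    n_first_degree_relatives="1", race_group="white",
)
patient = TransPatientProfile(
    gender_identity="transfeminine", sex_assigned_at_birth="male",
    age=45, hormone_duration_years=8.0,
)
report = screen(patient, risk)
print(round(report.estimate.five_year_risk, 4))   # 0.0265
print(round(report.estimate.lifetime_risk, 4))    # 0.2305
print(report.estimate.two_tier.value)             # higher_than_average
print(report.recommendation.variant.id.value)     # V2
print(report.recommendation.mammography_rating.value)  # usually_appropriate
```

Read: this 45-year-old transfeminine patient has a 2.65% modelled 5-year
and 23.1% lifetime risk of invasive breast cancer — higher than average
— and with 8 years of hormone therapy falls on the variant-2 row:
mammography usually appropriate.

The same result through the questionnaire (assigned male at birth → yes,
transfeminine → yes, hormones ever/≥5y → yes/yes, age ≥25 → yes,
≥40 → yes, one relative → yes/no, one biopsy → yes/no/no-hyperplasia):

```bash
chestscreen answers YYYYYYYNYNN
```

More narrative walk-throughs live in `examples/` (risk projection,
decision table, questionnaire, synthetic-cohort batch scoring); each
prints the numbers it computes and a line on what they mean. The
decision-table facsimile is printed by `chestscreen table`.

## A note on the shipped constants

Model coefficients and the White-women hazard tables are transcribed
from the published model as distributed with the public NCI risk tool.
The Black, Hispanic and Asian/Pacific-Islander *hazard* tables bundled
here are clearly labelled synthetic stand-ins (rescaled White tables);
their files and `docs/methods.md` say so explicitly. The model also
inherits its source's documented limitations (no BRCA/genetic inputs, no
second-degree family history, no transgender-specific calibration data).
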