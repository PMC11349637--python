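# Constant block: Asian Pacific Islander women.
# version 2024.1
#
# Provenance
#   coefficients: published coefficients of the Asian/Pacific-Islander recalibration (no interaction terms in that model).
#     Main effects are linear in the category index; per-category values
#     are the expanded index*beta sums. The atypical-hyperplasia block
#     holds the published log multipliers (x0.93 absent, x1.82 present)
#     shared across all constant blocks.
#   hazards: SYNTHETIC stand-in. Authoritative digit-exact race-specific
#     incidence/mortality tables are not bundled with this package; these
#     rates are the White-women tables rescaled by smooth race-specific
#     factors chosen to reflect the published relative incidence and
#     mortality patterns. Suitable for testing and for relative
#     comparisons; not for clinical counselling.
#   one_minus_ar: SYNTHETIC stand-in, rounded to two decimals near the
#     published attributable-risk complements.
version: "2024.1"
race_group: asian_pacific_islander
hazards_synthetic: true
age_bands:
  start: 20
  width: 5
  count: 14
coefficients:
  age_at_menarche: [0.0, 0.0749925759, 0.1499851518]
  age_at_first_live_birth: [0.0, 0.2763826829, 0.5527653658, 0.8291480487]
  n_biopsies: [0.0, 0.5526361226, 1.1052722452]
  n_first_degree_relatives: [0.0, 0.7918563372, 1.5837126744]
  atypical_hyperplasia: [0.0, -0.0725706928, 0.5988365011]
interactions:
  # added per biopsy-category index when attained age >= 50
  biopsies_age_ge50: 0.0000000000
  # added per (first-birth index * relatives index)
  first_birth_x_relatives: 0.0000000000
one_minus_ar:
  under_50: 0.48
  ge_50: 0.5
baseline_hazard:
  [0.00000915, 0.00005557, 0.00017227, 0.00042367, 0.00087338,
   0.00146437, 0.00196155, 0.00227093, 0.00275677, 0.00315218,
   0.00354810, 0.00370688, 0.00362475, 0.00308828]
competing_hazard:
  [0.00036975, 0.00039825, 0.00046875, 0.00061875, 0.00098025,
   0.00163575, 0.00274125, 0.00438900, 0.00707925, 0.01127100,
   0.01787925, 0.03123600, 0.06034050, 0.11230350]
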