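# Constant block: Hispanic women.
# version 2024.1
#
# Provenance
#   coefficients: published coefficients of the US-born-Hispanic recalibration (no menarche or interaction terms in that model).
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
race_group: hispanic
hazards_synthetic: true
age_bands:
  start: 20
  width: 5
  count: 14
coefficients:
  age_at_menarche: [0.0, 0.0000000000, 0.0000000000]
  age_at_first_live_birth: [0.0, 0.2318368334, 0.4636736668, 0.6955105002]
  n_biopsies: [0.0, 0.0970783641, 0.1941567282]
  n_first_degree_relatives: [0.0, 0.1666854410, 0.3333708820]
  atypical_hyperplasia: [0.0, -0.0725706928, 0.5988365011]
interactions:
  # added per biopsy-category index when attained age >= 50
  biopsies_age_ge50: 0.0000000000
  # added per (first-birth index * relatives index)
  first_birth_x_relatives: 0.0000000000
one_minus_ar:
  under_50: 0.75
  ge_50: 0.78
baseline_hazard:
  [0.00000854, 0.00005187, 0.00016079, 0.00039543, 0.00081515,
   0.00136675, 0.00183078, 0.00211953, 0.00257299, 0.00294203,
   0.00331156, 0.00345975, 0.00338310, 0.00288239]
competing_hazard:
  [0.00044370, 0.00047790, 0.00056250, 0.00074250, 0.00117630,
   0.00196290, 0.00328950, 0.00526680, 0.00849510, 0.01352520,
   0.02145510, 0.03748320, 0.07240860, 0.13476420]
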