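# Constant block: Black women.
# version 2024.1
#
# Provenance
#   coefficients: published coefficients of the CARE recalibration for African-American women (first-birth term absent from that model).
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
race_group: black
hazards_synthetic: true
age_bands:
  start: 20
  width: 5
  count: 14
coefficients:
  age_at_menarche: [0.0, 0.0769787813, 0.1539575626]
  age_at_first_live_birth: [0.0, 0.0000000000, 0.0000000000, 0.0000000000]
  n_biopsies: [0.0, 0.1822121131, 0.3644242262]
  n_first_degree_relatives: [0.0, 0.4757242578, 0.9514485156]
  atypical_hyperplasia: [0.0, -0.0725706928, 0.5988365011]
interactions:
  # added per biopsy-category index when attained age >= 50
  biopsies_age_ge50: -0.1119411682
  # added per (first-birth index * relatives index)
  first_birth_x_relatives: 0.0000000000
one_minus_ar:
  under_50: 0.73
  ge_50: 0.74
baseline_hazard:
  [0.00001586, 0.00009633, 0.00029861, 0.00073437, 0.00151385,
   0.00171820, 0.00230155, 0.00266455, 0.00323462, 0.00369855,
   0.00416310, 0.00434940, 0.00425304, 0.00362358]
competing_hazard:
  [0.00069020, 0.00074340, 0.00087500, 0.00115500, 0.00182980,
   0.00305340, 0.00511700, 0.00819280, 0.01321460, 0.02103920,
   0.03337460, 0.05830720, 0.11263560, 0.20963320]
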