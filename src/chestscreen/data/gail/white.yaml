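# Constant block: White women.
# version 2024.1
#
# Provenance
#   coefficients: published logistic-regression coefficients of the 1989
#     invasive-breast-cancer risk model as distributed with the NCI online
#     risk tool (https://bcrisktool.cancer.gov). Main effects are linear in
#     the category index; the per-category values below are the expanded
#     index*beta sums. The atypical-hyperplasia block holds the published
#     log multipliers applied to biopsy-positive histories (x0.93 absent,
#     x1.82 present).
#   hazards: composite invasive-breast-cancer incidence (SEER 1983-87,
#     White women) and competing non-breast-cancer mortality (US vital
#     statistics 1985-87, White women), annual rates on 5-year age bands
#     20-24 ... 85-89, transcribed from the public risk-tool documentation.
#   one_minus_ar: published attributable-risk complement (1-AR) for White
#     women, both age strata.
version: "2024.1"
race_group: white
age_bands:
  start: 20
  width: 5
  count: 14
coefficients:
  age_at_menarche: [0.0, 0.0940103059, 0.1880206118]
  age_at_first_live_birth: [0.0, 0.2186262218, 0.4372524436, 0.6558786654]
  n_biopsies: [0.0, 0.5292641004, 1.0585282008]
  n_first_degree_relatives: [0.0, 0.9583027845, 1.9166055690]
  atypical_hyperplasia: [0.0, -0.0725706928, 0.5988365011]
interactions:
  # added per biopsy-category index when attained age >= 50
  biopsies_age_ge50: -0.2880424830
  # added per (first-birth index * relatives index)
  first_birth_x_relatives: -0.1908113865
one_minus_ar:
  under_50: 0.5788413
  ge_50: 0.5788413
baseline_hazard:
  [0.00001220, 0.00007410, 0.00022970, 0.00056490, 0.00116450,
   0.00195250, 0.00261540, 0.00302790, 0.00367570, 0.00420290,
   0.00473080, 0.00494250, 0.00483300, 0.00411770]
competing_hazard:
  [0.00049300, 0.00053100, 0.00062500, 0.00082500, 0.00130700,
   0.00218100, 0.00365500, 0.00585200, 0.00943900, 0.01502800,
   0.02383900, 0.04164800, 0.08045400, 0.14973800]
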