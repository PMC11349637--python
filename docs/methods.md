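# Methods

## The risk model

`chestscreen`'s risk engine is a Gail-family absolute-risk projection.
A person's discrete risk factors are mapped to category indices
(baseline index 0; *unknown* always maps to baseline):

| factor | categories (index) |
|---|---|
| age at menarche | ≥14 (0), 12–13 (1), <12 (2) |
| age at first live birth | <20 (0), 20–24 (1), 25–29 or nulliparous (2), ≥30 (3) |
| breast biopsies | 0 (0), 1 (1), ≥2 (2) |
| first-degree relatives with breast cancer | 0 (0), 1 (1), ≥2 (2) |
| atypical hyperplasia | no/unknown biopsy context (0), biopsy without AH (1), AH present (2) |

The log relative risk is linear in the indices with two interaction
terms — biopsies × attained-age stratum (<50 vs ≥50) and first-birth ×
relatives — so the relative risk changes once, at age 50, during a
projection. The atypical-hyperplasia block holds the published
multipliers (×0.93 for biopsy-positive histories without atypia, ×1.82
with atypia), expressed as log coefficients so the whole relative risk
is one exponentiated sum.

Absolute risk over `[a, b)` combines three ingredients, all piecewise
constant on 5-year age bands spanning [20, 90):

* composite invasive-cancer incidence `λ₁`, deflated by the
  attributable-risk complement `1−AR` so the baseline-category
  population carries the baseline hazard,
* the age-stratum-dependent relative risk `RR`,
* competing (non-breast-cancer) mortality `λ₂`.

Within a segment of constant hazards the cause-specific probability has
the exact closed form `S · h₁/(h₁+λ₂) · (1 − e^{−(h₁+λ₂)Δ})` with
`h₁ = λ₁(1−AR)RR`; segments are the projection interval split at band
edges (50 is a band edge), and `S` is the joint survival accumulated
through earlier segments. No numerical integration is involved — the
fine-grid midpoint integrator in the test suite exists only as an
independent oracle, and the two agree to better than 1e-6 across seeded
random profiles.

Numerical conventions: ages are integers at the interface and reals
internally; intervals outside [20, 90) are clipped (with a logged
warning on the direct `absolute_risk` call), so projections for 18- and
19-year-olds accrue no modelled risk before age 20; the 5-year risk of
an 18-year-old is therefore the [20, 25) risk. `start == end` returns
exactly 0. Lifetime risk projects to 90.

### Constants and their provenance

Constants ship as one human-readable YAML file per race group under
`src/chestscreen/data/gail/`, each block carrying its own provenance
header and a version string that the CLI reports with every result.
The White-women file transcribes the published coefficients, hazard
tables and attributable-risk complement distributed with the public NCI
risk tool; unknown/other race resolves to the White block, following
that tool's convention. For the Black, Hispanic and Asian/Pacific-
Islander groups the *coefficients* are the published recalibrations, but
the *hazard tables and 1−AR values* are synthetic stand-ins — White
tables rescaled by smooth factors reflecting published relative
incidence/mortality patterns — because no authoritative digit-exact
copy of those tables is bundled. The files are named
`*_hazards_synthetic.yaml` and say this in their headers. They are
adequate for testing and for exercising every code path, not for
counselling; replacing them with transcribed tables requires no code
change.

### Risk tiers

The published decision table names its tiers but attaches no numbers to
them. Defaults follow the common screening-guideline convention:
lifetime risk <15% *average*, 15–20% *intermediate*, ≥20% *high*, and a
5-year risk ≥1.67% (the risk tool's elevated-risk convention) also
counts as *higher than average* in the two-level vocabulary the
transwoman arm uses. All four numbers are configurable; every boundary
is closed on the lower side (exactly 0.15 is intermediate, exactly 0.20
is high). The two-level *higher than average* is treated as the union
of *intermediate* and *high* — the two arms' vocabularies are assumed
consistent.

## The decision table

The eight published variants are encoded as guarded rules; thresholds
are config values, all inclusive on the "at least" side, with the
hormone split at exactly 5.0 years. Design choices where the published
table is silent:

* **Non-totality is surfaced, never hidden.** The printed rows do
  not cover, e.g., a 30-year-old average-risk transwoman with ≥5 years
  of hormones. Such profiles return `NO_MATCH` with a reason code and a
  hint naming the age at which the profile would first match, rather
  than a silent default. `not_indicated` (no row addresses it) and
  `usually_not_appropriate` (a row says don't screen) are distinct
  labels sharing the lowest rank in the rating order — both mean "no
  screening recommended", which keeps the rating monotone in risk tier
  where a rising tier moves a profile out of the printed rows.
* **Mastectomy dominance is scoped to the arm that conditions on
  surgery.** On the transman arm, bilateral mastectomy rates screening
  usually-not-appropriate at any age and any tier (some experts
  disagree with that published recommendation; the table is followed as
  printed). The transwoman arm's rows do not condition on surgery, so
  surgery is ignored there.
* **Nonbinary identities** are routed by sex assigned at birth (AMAB →
  transwoman arm, AFAB → transman arm) and the output is flagged
  `extrapolated`.

`decision_table()` regenerates every distinct rule cell by probing one
representative profile per region of the condition space and
deduplicating by outcome; the test suite checks the row count against a
brute-force enumeration of the full discrete grid.

## The questionnaire

The published instrument is a 16-item yes/no questionnaire; its exact
wording is not public, so this package fixes a canonical 16-item set
covering precisely the fields both models consume: arm selection (items
1–2), hormone exposure (3–4), age brackets (5–7), surgery (8–9), family
history (10–11), biopsies and atypia (12–14), and natal menarche/parity
(15–16). The flow is a DAG over the items; a few items shared between
arms carry per-arm successors resolved against the arm fixed at item 1,
and a build-time self-check verifies the item count, acyclicity,
reachability of all 16 items, and the ≤16-item path bound.

Deliberate coarsenings relative to the direct API: bracketed ages map
to the lowest consistent integer (18/25/30/40); hormone exposure maps
to 0, 2.5 or 5.0 years; a yes on item 16 maps to the 25–29/nulliparous
parity category (the lower-risk category consistent with "after 30, or
none"); natal history is skipped — left baseline — on the transfeminine
arm. Surgery is asked first on the transmasculine arm so a bilateral
mastectomy terminates the flow after three answers; the matching row
covers any age and risk, and a test verifies no consistent answer to a
skipped item could change any terminal recommendation. The central
correctness property — every terminal path's recommendation equals the
direct pipeline on the reconstructed profiles — is checked by
exhaustive traversal (1,232 paths under the default configuration).

## The synthetic cohort generator

`sample_cohort` emulates the *input space*, not an epidemiological
population: uniform integer ages over [18, 90]; an identity mix of
40/40/10/10 (transfeminine / transmasculine / nonbinary AMAB / AFAB);
hormone exposure zero-inflated at 60% with the remainder uniform on
(0, 10] years, putting 20% of the cohort at or past the 5-year decision
threshold; all three surgery states present (mastectomy only sampled on
the AFAB arm by default); and independent risk-factor prevalences with
the hyperplasia⇒biopsy implication enforced by construction. Passing
tests on these cohorts therefore demonstrates correctness of the
decision logic across the whole input space — they say nothing about
real prevalence, correlation structure between risk factors, or
calibration of the risk model in transgender populations (no such
calibration data exists in the model). `exhaustive_grid` complements
sampling with the full discretized cross-product (89,790 cases) used
for the totality and monotonicity guarantees.

## Problem sizes

The default test run exercises the full 89,790-case grid (twice), all
1,232 questionnaire paths, 100-profile oracle comparisons at a 0.005-
year integration step, and 10,000-record cohort draws for the mix
bounds — chosen so the whole suite completes in seconds while every
guarantee is checked exhaustively rather than on a sample.

## Known limitations

* The risk engine inherits the published model's limitations: no
  genetic (BRCA) inputs, no second-degree family history, no lifestyle
  factors, short-term prediction better validated than lifetime, and no
  transgender-specific calibration (hormone exposure influences only
  the decision table, never the risk projection — whether the original
  web tool fed hormone exposure into the risk computation is unknown;
  this package does not).
* Non-White hazard tables are synthetic stand-ins (above).
* Tier thresholds are convention defaults, not published numbers; they
  are configurable and every boundary decision is documented and
  tested.
* The questionnaire's item wording and order are this package's own
  reconstruction; only the count, the yes/no form and the input
  coverage are fixed by the published description.
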