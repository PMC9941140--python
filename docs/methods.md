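# Methods

## Pattern representation

A `PatternComposition` mirrors a USDA pattern table: daily amounts for
vegetables, fruits, whole/refined grains, dairy, dairyALT and the
protein-foods total; weekly amounts for the vegetable subgroups and the
protein subgroups (eggs, beans/peas/lentils, soy products, nuts/seeds,
seafood); oils in g/d; and a discretionary-calorie allowance.  Amounts
are stored at full precision; all display rounding is half-up to two
decimals (the rendering used by the source pattern tables; e.g.
8/7 = 1.142857 oz-eq/d displays as 1.14 and 3.5 + 8/7 as 4.64).

Two consistency notes on the source rendering that the model has to
absorb:

* The printed daily protein-foods total is itself a rounded value: the
  2,000-kcal HVDP prints 3.5 oz-eq/d while its weekly subgroups sum to
  24/7 ≈ 3.43.  The internal consistency check therefore allows a
  0.08 oz-eq discrepancy between the stored daily total and the weekly
  sum / 7; the transformations preserve the *delta* relationship
  exactly (seafood adds exactly `weekly/7` to the daily total).
* The printed grains aggregate stays at 6.5 oz-eq/d even in the seafood
  models whose refined grains drop to 2.5 (3.5 + 2.5 = 6.0).  The
  subgroup rows are treated as authoritative and an aggregate mismatch
  is logged, not raised.

## Transformations

* **Egg replacement** is an equal three-way split in oz-eq (not
  proportional to existing amounts): eggs → 0 and each other vegetarian
  protein subgroup gains eggs/3 per week.  Weekly protein oz-eq is
  conserved to machine precision (property-tested).
* **Seafood addition** sets the weekly seafood amount from the energy
  schedule 1800→8, 2000→8, 2200→9, 2400→10 oz-eq/wk and subtracts a
  constant 0.5 oz-eq/d of refined grains at every energy level.  The
  2,200-kcal value of 9 is an interpolation of the published 8–10 range
  (the source never prints it) and is configurable.  Adding zero seafood
  is the identity; an offset that would drive refined grains negative is
  an error.
* **Dairy swap** moves the dairy amount 1:1 into the fortified-soy
  dairyALT group.
* The pescavegan build composes all three; the operations commute
  (asserted over all six orders).

Only the 2,000-kcal HVDP composition ships as a fixture (it is the only
one printed in full in the source material); builds at other energy
levels accept any user-supplied HVDP composition tagged with that energy
level.

## Totalization and adequacy

`total_nutrients` is the additive FPM sum over the twelve
profile-carrying groups (vegetable subgroup detail is carried by the
daily vegetables aggregate), with oils contributing per gram and the
discretionary allowance added to energy only.  Totals are linear in
amounts; doubling every amount doubles every total (discretionary energy
is excluded from that scaling and documented as such).

Percent of DRI is `100·T/DRI`.  Two modes exist because the source
adequacy tables evidently computed their two derived columns from
different precisions:

* **paper-compatibility** (default): %DRI from the display-rounded
  total (202/600 → 33.67; 251/130 → 193.08), matching the printed %
  columns;
* **analysis**: %DRI from the full-precision total.

Percent change from baseline always uses full-precision totals (the
printed −18.88% for choline 300 → 243 is reproducible only from
unrounded totals).  A zero baseline with a nonzero model value (EPA in
the seafood models) has undefined percent change and renders as "n/a".

Shortfall sets use strict thresholds — `%DRI < 100` and `< 50` — so the
pescatarian vitamin D value of 49.83% classifies as below half the DRI.
Sodium's 2,300 mg reference is the Chronic Disease Risk Reduction intake
(a reduction target, not an adequacy goal); the default replicates the
source convention of counting low sodium as a shortfall, and
`sodium_as_target=False` drops it from the shortfall sets.

AMDR shares use Atwater factors 4/4/9 kcal/g (configurable) with the
pattern's total energy — including oils and discretionary calories — as
the denominator, not the Atwater sum of the macronutrient grams.
Saturated fat is flagged against both the 10%-of-kcal planning limit and
the 5% bound all four 2,000-kcal patterns satisfy.

Population mapping follows the energy-level appropriateness used in the
source analysis: 1,800 kcal → F 31–50; 2,000 → F 19–30 and M 51+;
2,200 → M 31–50; 2,400 → M 19–30.  Evaluating an unmapped pair is an
error unless explicitly overridden.  The F 19–30 DRI column is taken
from the published tables; the other groups carry standard adult DRI
values.

## Synthetic profiles and calibration

The official per-serving nutrient profiles (FPM supplementary data) are
not available to this package, so it generates synthetic stand-ins with
the statistical and arithmetic structure the analysis needs:

1. **Anchors.**  Published per-serving values are pinned exactly:
   seafood vitamin D 69.82 IU/oz-eq and choline 19.53 mg/oz-eq (the
   latter recomputed from the printed 27.9 mg at 10 oz-eq/wk), dairy
   iron 0.08 and dairyALT iron 0.94 mg/cup-eq, dairyALT choline
   52.89 mg/cup-eq, and dairy/dairyALT vitamin D 58.5/108.8 IU/cup-eq
   (recomputed from the printed 3-cup totals 175.5 and 326.4 IU).
   Derived anchors are recomputed from their printed parents at load
   time, never hard-coded.
2. **Generation.**  Unanchored entries are drawn log-uniformly from
   per-(group, nutrient) ranges in `data/profile_ranges.yaml` —
   configuration, not code constants — encoding what a food-group
   composite can plausibly carry per serving (e.g. refined grains
   80–90 kcal/oz-eq, plant groups zero B12/EPA, dairyALT fats soy-oil
   based).  Generation is deterministic per seed.
3. **Calibration.**  Per nutrient (nutrients do not couple in an
   additive totalization), solve min ‖A·p − y‖² subject to p ≥ 0 and the
   anchor equalities, where A is the 4×12 matrix of daily serving
   amounts of the four 2,000-kcal patterns and y the printed total
   columns (discretionary kcal removed from the energy row).  The
   system is under-determined (4 observations, up to 12 free columns),
   so a relative Tikhonov pull toward the generated prior (λ = 1e-5,
   columns scaled by the prior) selects the plausible solution among
   the exact fits; `scipy.optimize.lsq_linear` solves the stacked
   bounded problem.  Entries at the zero bound within 1e-9 of the
   column maximum are snapped to zero.

A nutrient whose fitted totals miss a printed target by more than 2%
relative is flagged rather than silently fitted.  Iron is always
flagged: its printed integer totals (16/17/17/19 mg) are arithmetically
inconsistent with its own printed per-cup pins (the dairy→dairyALT swap
alone contributes +2.58 mg where the printed totals allow +2 including
the egg swap), so the least-squares fit spreads a ~0.5 mg discrepancy
across the four patterns.  This is inherent to the printed inputs, not
a solver artifact.

The high-/low-omega-3 fish profiles are derived from the calibrated
seafood blend by an enrichment factor (EPA/DHA ×2.8, vitamin D ×2.5,
bounded by 1/w_high) such that the consumption-weighted blend
(31% high, 69% low) reproduces the seafood group exactly.

**What passing tests show — and don't.**  The synthetic profiles
reproduce every printed total within tolerance and all printed
per-serving anchors exactly, so the pipeline's algebra and statistics
are fully exercised.  They are *not* the true FPM profiles: individual
unanchored entries (say, vegetable choline per cup-eq) are one plausible
solution of an under-determined system, so conclusions about individual
food groups' contributions — beyond the anchored ones — should not be
read off the synthetic bundle.  Real-data features not emulated include
nutrient bioavailability, within-group item substitution (e.g. choosing
zinc-rich shellfish), and iodine, which is absent from the underlying
food composition data entirely.

## Numerical choices and degenerate inputs

* Rounding is decimal half-up everywhere a display value is produced;
  binary-float ties are resolved via `Decimal(repr(x))`.
* `percent_of_dri` requires a positive reference; `amdr_shares` and
  `saturated_fat_share` require positive total energy; negative amounts
  are rejected at construction.
* Empty or malformed tables raise `SchemaError` naming the offending
  row/column; a consumed group without a profile raises
  `ConfigurationError` naming the group.
* Calibration with no free columns returns the pins; a negative pin is
  a `CalibrationError`.

## Known limitations

* Adequacy columns for population groups other than F 19–30 use
  standard DRI values rather than published table columns (only the
  F 19–30 column is printed in full in the source material); they are
  cross-checked against the narrative percentages the source does print.
* The printed adequacy tables contain a handful of internally
  inconsistent cells (listed with reasons in
  `foodpatterns.fixtures.INCONSISTENT_PCT_CELLS` and relatives); the
  engine reports the arithmetically consistent values.
* The vitamin D target column and its pins disagree by ~2 IU at the
  lacto-vegetarian pattern, so the calibrated %DRI there is 33.5 rather
  than the printed 33.67 — within the calibration tolerance.
* Compositions at 1,800/2,200/2,400 kcal are not bundled; users supply
  their own HVDP tables for those levels.
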