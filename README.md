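# foodpatterns

Food pattern modeling (FPM) for vegetarian adaptations of the USDA
dietary patterns, with full nutrient-adequacy evaluation.

The 2020–2025 Dietary Guidelines for Americans include a Healthy
Vegetarian Dietary Pattern (HVDP), a lacto-ovo vegetarian pattern with
dairy and eggs.  Many vegetarians eat differently: lacto-vegetarians
avoid eggs, pescatarians add seafood, and "pescavegans" eat a vegan diet
plus seafood.  This package constructs those three adaptations from the
HVDP with fixed substitution rules and asks the question a dietary
pattern is designed to answer: does it still meet nutrient
recommendations for the adults it is intended for?

It is aimed at nutrition researchers and dietitians who work with USDA
food patterns and want the substitution algebra, the totalization, and
the adequacy statistics as reusable, tested code.

## The model

A dietary pattern is a vector of food-group amounts **a** (cup-eq/d or
oz-eq/d; weekly subgroup amounts contribute at 1/7 per day), plus oils
(g/d) and a discretionary-calorie allowance.  Given per-serving nutrient
profiles *p<sub>g</sub>*, the daily total of nutrient *n* is the additive
FPM sum

> T(n) = Σ<sub>g</sub> a<sub>g</sub> · p<sub>g</sub>(n)  (+ discretionary
> kcal, energy only)

Three pure transformations build the adapted patterns:

* **lacto-vegetarian** — eggs → 0; each of beans/peas/lentils, soy
  products, and nuts/seeds gains eggs/3 oz-eq/wk (weekly protein oz-eq is
  conserved exactly);
* **pescatarian** — seafood set to the Healthy U.S.-Style pattern's
  weekly amount (8–10 oz-eq/wk by energy level) and refined grains
  reduced by a constant 0.5 oz-eq/d to offset the added energy;
* **pescavegan** — both of the above, plus dairy swapped 1:1 for a
  fortified soy milk/yogurt "dairyALT" group.  The operations commute.

Adequacy statistics per population group (sex × age, mapped to the
energy levels each is appropriate for): percent of DRI
(100·T/DRI), percent change from the HVDP baseline, macronutrient energy
shares against the adult AMDRs (protein 10–35%, carbohydrate 45–65%, fat
20–35% of kcal), the saturated-fat share of energy, and shortfall sets
(nutrients below 100% and below 50% of the DRI, strict inequalities).

Because the official per-serving FPM profiles are not redistributable,
`foodpatterns.synth` generates *synthetic* profiles: published
per-serving anchor values (e.g. seafood vitamin D 69.82 IU/oz-eq,
dairyALT iron 0.94 mg/cup-eq) are pinned exactly, everything else is
drawn from configured plausible ranges and then calibrated by
non-negative regularized least squares so the four 2,000-kcal pattern
totals reproduce the published adequacy-table columns.  See
`docs/methods.md` for assumptions and limitations.

## Worked example

```python
import foodpatterns as fp

bundle = fp.fixture_bundle(seed=0)          # patterns + DRIs + profiles
hvdp = bundle.compositions["HVDP"]          # 2,000 kcal baseline
lacto = fp.build_model(hvdp, "lacto")       # replace eggs

report = fp.evaluate_pattern(lacto, bundle.profiles, bundle.dri,
                             "F19-30", baseline=hvdp)
print(sorted(report.below_100))
# ['choline', 'iron', 'sodium', 'vitamin_d', 'vitamin_e']
print(sorted(report.below_50))
# ['vitamin_d']
print(report.table.loc["choline", ["dri", "total", "pct_dri"]].round(2))
# dri        425.00
# total      243.00
# pct_dri     57.18
```

Reading: at 2,000 kcal the lacto-vegetarian pattern supplies 243 mg
choline against the 425 mg adequate intake for females 19–30 (57.18% of
the DRI), and vitamin D is the only nutrient below half its DRI (201 IU
of 600, 33.5%).  The same pattern stays inside every AMDR (protein
16.1%, carbohydrate 50.5%, fat 24.0% of kcal) with 4.52% of energy from
saturated fat.

The same pipeline is scriptable from a shell:

```sh
foodpatterns build pescavegan 2000 --out pescavegan.csv
foodpatterns fixtures --out bundle --seed 0
foodpatterns evaluate pescavegan.csv --profiles bundle/profiles.csv \
    --population F19-30 --out report
```

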