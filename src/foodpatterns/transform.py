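"""Pattern constructions: the three vegetarian adaptations of the Healthy
Vegetarian Dietary Pattern (HVDP) and the seafood-profile blend.

All operations are pure: they return new objects and leave their inputs
untouched.

* lacto-vegetarian (model 1): eggs replaced by an equal three-way split
  over the other vegetarian protein subgroups.
* pescatarian (model 2): seafood added at the Healthy U.S.-Style pattern's
  weekly amount, with refined grains reduced by a constant 0.5 oz-eq/d to
  offset the added energy.
* pescavegan (model 3): both of the above plus dairy swapped for the
  fortified soy dairy-alternative group.
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional

from .core import (
    BlendWeights, FoodGroupProfile, NutrientVector, PatternComposition,
    ValidationError, weekly_to_daily,
)

#: Weekly seafood amounts (oz-eq/wk) by pattern energy level, from the
#: Healthy U.S.-Style Dietary Pattern's seafood recommendations
#: (8 to 10 oz-eq per week over 1,800-2,400 kcal).
SEAFOOD_WEEKLY_BY_ENERGY: Dict[int, float] = {
    1800: 8.0, 2000: 8.0, 2200: 9.0, 2400: 10.0,
}

#: Constant refined-grain reduction applied whenever seafood is added.
GRAIN_OFFSET_OZ_EQ = 0.5

MODEL_IDS = ("model1_lacto", "model2_pesca", "model3_pescavegan")

_MODEL_ALIASES = {
    "model1": "model1_lacto", "model1_lacto": "model1_lacto",
    "lacto": "model1_lacto", "lacto_vegetarian": "model1_lacto",
    "lacto-vegetarian": "model1_lacto",
    "model2": "model2_pesca", "model2_pesca": "model2_pesca",
    "pescatarian": "model2_pesca", "pesca": "model2_pesca",
    "model3": "model3_pescavegan", "model3_pescavegan": "model3_pescavegan",
    "pescavegan": "model3_pescavegan",
}

_VEG_PROTEIN_GROUPS = ("beans_peas_lentils", "soy_products", "nuts_seeds")


def canonical_model_id(model_id: str) -> str:
    key = str(model_id).strip().lower().replace(" ", "_")
    if key not in _MODEL_ALIASES:
        raise ValidationError(f"unknown model id: {model_id!r}")
    return _MODEL_ALIASES[key]


def blend_seafood_profile(high: FoodGroupProfile, low: FoodGroupProfile,
                          weights: BlendWeights = BlendWeights()
                          ) -> FoodGroupProfile:
    """Blend high- and low-omega-3 fish profiles into one seafood group.

    Every nutrient is the consumption-weighted average
    ``w_high * high + w_low * low`` (high-omega-3 fish are roughly 31% of
    U.S. seafood consumption).
    """
    if high.serving_unit != "oz_eq" or low.serving_unit != "oz_eq":
        raise ValidationError("fish profiles must be per oz-eq")
    if set(high.nutrients) != set(low.nutrients):
        raise ValidationError(
            "fish profiles must cover identical nutrient keys")
    blended: NutrientVector = (weights.w_high * high.nutrients +
                               weights.w_low * low.nutrients)
    return FoodGroupProfile(group="seafood", serving_unit="oz_eq",
                            nutrients=blended)


def replace_eggs(base: PatternComposition) -> PatternComposition:
    """Replace eggs with an equal split over the other vegetarian protein
    subgroups; total weekly protein-food oz-eq is conserved exactly."""
    for group in ("eggs", *_VEG_PROTEIN_GROUPS):
        if group not in base.weekly:
            raise ValidationError(
                f"composition lacks weekly amount for {group}")
    eggs = base.weekly["eggs"]
    out = base.copy()
    if eggs == 0:
        return out
    share = eggs / 3.0
    out.weekly["eggs"] = 0.0
    for group in _VEG_PROTEIN_GROUPS:
        out.weekly[group] = base.weekly[group] + share
    out.validate()
    return out


def add_seafood_with_grain_offset(base: PatternComposition,
                                  seafood_weekly: float
                                  ) -> PatternComposition:
    """Add seafood (oz-eq/wk) and drop refined grains by 0.5 oz-eq/d.

    The grain offset is a constant across energy levels; the daily
    protein-foods total grows by ``seafood_weekly / 7``.  Adding zero
    seafood is the identity.
    """
    if seafood_weekly < 0:
        raise ValidationError("seafood amount must be >= 0")
    out = base.copy()
    if seafood_weekly == 0:
        return out
    refined = base.daily.get("refined_grains", 0.0)
    if refined < GRAIN_OFFSET_OZ_EQ:
        raise ValidationError(
            f"cannot offset seafood energy: refined grains {refined} "
            f"oz-eq/d < {GRAIN_OFFSET_OZ_EQ}")
    out.weekly["seafood"] = seafood_weekly
    out.daily["refined_grains"] = refined - GRAIN_OFFSET_OZ_EQ
    out.daily["protein_foods"] = (base.daily.get("protein_foods", 0.0) +
                                  weekly_to_daily(seafood_weekly))
    out.validate()
    return out


def swap_dairy_for_dairy_alt(base: PatternComposition) -> PatternComposition:
    """Move the dairy amount into the fortified-soy dairy-alternative
    group; all other groups are unchanged."""
    if "dairy" not in base.daily:
        raise ValidationError("composition lacks a dairy amount")
    out = base.copy()
    dairy = base.daily["dairy"]
    if dairy == 0:
        return out
    out.daily["dairy_alt"] = base.daily.get("dairy_alt", 0.0) + dairy
    out.daily["dairy"] = 0.0
    out.validate()
    return out


def build_model(base: PatternComposition, model_id: str,
                energy_level: Optional[int] = None,
                seafood_schedule: Optional[Mapping[int, float]] = None
                ) -> PatternComposition:
    """Construct one of the three adapted patterns from an HVDP composition.

    ``energy_level`` defaults to the composition's own; it selects the
    weekly seafood amount from ``seafood_schedule`` for the models that
    contain seafood.  The constituent operations commute.
    """
    model = canonical_model_id(model_id)
    energy = base.energy_level if energy_level is None else int(energy_level)
    if energy != base.energy_level:
        raise ValidationError(
            f"requested energy level {energy} does not match the "
            f"composition's {base.energy_level}")
    schedule = dict(SEAFOOD_WEEKLY_BY_ENERGY)
    if seafood_schedule is not None:
        schedule.update(seafood_schedule)
    if model in ("model2_pesca", "model3_pescavegan"):
        if energy not in schedule:
            raise ValidationError(
                f"no seafood schedule for energy level {energy}")
        seafood_weekly = schedule[energy]

    out = base.copy()
    if model == "model1_lacto":
        out = replace_eggs(out)
    elif model == "model2_pesca":
        out = add_seafood_with_grain_offset(out, seafood_weekly)
    else:  # pescavegan: all three substitutions (they commute)
        out = replace_eggs(out)
        out = swap_dairy_for_dairy_alt(out)
        out = add_seafood_with_grain_offset(out, seafood_weekly)
    out.pattern_id = model
    return out
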