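"""Core value types for USDA-style food pattern modeling.

A dietary pattern is represented the way the Dietary Guidelines for
Americans (DGA) print it: food-group amounts in cup-equivalents or
ounce-equivalents per day (or per week for subgroups), plus oils in grams
per day and a discretionary-calorie allowance.  Nutrient content is carried
as a :class:`NutrientVector` over a fixed controlled vocabulary whose units
match the DGA nutrient tables (vitamin D in IU, folate in mcg DFE, vitamin
A in mcg RAE).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterator, Mapping, Optional, Tuple


class ValidationError(ValueError):
    """Input violates a model invariant (negative amount, bad unit, ...)."""


class SchemaError(ValidationError):
    """A table is missing required rows/columns or has unknown labels."""


class ConfigurationError(ValidationError):
    """A required profile/reference value is absent from the configuration."""


# --------------------------------------------------------------------------
# Controlled nutrient vocabulary.  Units are fixed per nutrient; one row per
# nutrient of the DGA-style adequacy tables.
# --------------------------------------------------------------------------

NUTRIENT_UNITS: Dict[str, str] = {
    "energy": "kcal",
    "protein": "g",
    "carbohydrate": "g",
    "fiber": "g",
    "total_fat": "g",
    "saturated_fat": "g",
    "monounsaturated_fat": "g",
    "polyunsaturated_fat": "g",
    "linoleic_acid": "g",
    "linolenic_acid": "g",
    "epa": "g",
    "dha": "g",
    "cholesterol": "mg",
    "calcium": "mg",
    "iron": "mg",
    "magnesium": "mg",
    "phosphorus": "mg",
    "potassium": "mg",
    "sodium": "mg",
    "zinc": "mg",
    "copper": "mg",
    "selenium": "mcg",
    "vitamin_a": "mcg",   # RAE
    "vitamin_e": "mg",    # alpha-tocopherol
    "vitamin_d": "IU",
    "vitamin_c": "mg",
    "thiamin": "mg",
    "riboflavin": "mg",
    "niacin": "mg",
    "vitamin_b6": "mg",
    "vitamin_b12": "mcg",
    "choline": "mg",
    "vitamin_k": "mcg",
    "folate": "mcg",      # DFE
}

NUTRIENTS: Tuple[str, ...] = tuple(NUTRIENT_UNITS)

#: Decimal places used when a nutrient amount is displayed the way the
#: source tables print it (integers for most minerals, one decimal for
#: small-milligram vitamins, three for EPA/DHA).
DISPLAY_DECIMALS: Dict[str, int] = {
    "energy": 0, "protein": 0, "carbohydrate": 0, "fiber": 0,
    "total_fat": 0, "saturated_fat": 0, "monounsaturated_fat": 0,
    "polyunsaturated_fat": 0, "linoleic_acid": 0, "linolenic_acid": 1,
    "epa": 3, "dha": 3, "cholesterol": 0, "calcium": 0, "iron": 0,
    "magnesium": 0, "phosphorus": 0, "potassium": 0, "sodium": 0,
    "zinc": 0, "copper": 1, "selenium": 0, "vitamin_a": 0, "vitamin_e": 0,
    "vitamin_d": 0, "vitamin_c": 0, "thiamin": 1, "riboflavin": 1,
    "niacin": 0, "vitamin_b6": 1, "vitamin_b12": 1, "choline": 0,
    "vitamin_k": 0, "folate": 0,
}


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the rendering rule used throughout).

    Python's builtin ``round`` is banker's rounding; the source tables
    render 4.642857 -> 4.64 and 1.435 -> 1.44, i.e. half-up.
    """
    if isinstance(value, float) and (math.isnan(value) or math.isinf(value)):
        return value
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def display_amount(nutrient: str, value: float) -> float:
    """Round a nutrient amount to the table's display precision."""
    return round_half_up(value, DISPLAY_DECIMALS.get(nutrient, 2))


class NutrientVector:
    """Named map nutrient-id -> amount with component-wise algebra.

    Amounts are non-negative unless ``allow_negative`` is set (used only
    for change metrics).  Addition and scalar multiplication are defined
    component-wise; missing entries read as zero.
    """

    __slots__ = ("_entries", "_allow_negative")

    def __init__(self, entries: Optional[Mapping[str, float]] = None, *,
                 allow_negative: bool = False) -> None:
        self._allow_negative = allow_negative
        self._entries: Dict[str, float] = {}
        for key, value in (entries or {}).items():
            if key not in NUTRIENT_UNITS:
                raise ValidationError(f"unknown nutrient id: {key!r}")
            value = float(value)
            if not allow_negative and value < 0:
                raise ValidationError(
                    f"negative amount for {key}: {value}")
            self._entries[key] = value

    # -- mapping-ish interface ------------------------------------------
    def get(self, nutrient: str, default: float = 0.0) -> float:
        if nutrient not in NUTRIENT_UNITS:
            raise ValidationError(f"unknown nutrient id: {nutrient!r}")
        return self._entries.get(nutrient, default)

    def __getitem__(self, nutrient: str) -> float:
        return self.get(nutrient)

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def items(self):
        return self._entries.items()

    def to_dict(self) -> Dict[str, float]:
        return dict(self._entries)

    # -- algebra --------------------------------------------------------
    def __add__(self, other: "NutrientVector") -> "NutrientVector":
        if not isinstance(other, NutrientVector):
            return NotImplemented
        keys = set(self._entries) | set(other._entries)
        neg = self._allow_negative or other._allow_negative
        return NutrientVector(
            {k: self.get(k) + other.get(k) for k in keys}, allow_negative=neg)

    def __mul__(self, scalar: float) -> "NutrientVector":
        scalar = float(scalar)
        neg = self._allow_negative or scalar < 0
        return NutrientVector(
            {k: v * scalar for k, v in self._entries.items()},
            allow_negative=neg)

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NutrientVector):
            return NotImplemented
        keys = set(self._entries) | set(other._entries)
        return all(self.get(k) == other.get(k) for k in keys)

    def isclose(self, other: "NutrientVector", rel: float = 1e-9,
                abs_tol: float = 1e-12) -> bool:
        keys = set(self._entries) | set(other._entries)
        return all(math.isclose(self.get(k), other.get(k),
                                rel_tol=rel, abs_tol=abs_tol) for k in keys)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"NutrientVector({self._entries!r})"

    @staticmethod
    def zero() -> "NutrientVector":
        return NutrientVector({})


# --------------------------------------------------------------------------
# Food groups
# --------------------------------------------------------------------------

#: Food groups that carry a per-serving nutrient profile, with the serving
#: unit each is expressed in ("g" for oils = per gram).
GROUP_UNITS: Dict[str, str] = {
    "vegetables": "cup_eq",
    "fruits": "cup_eq",
    "whole_grains": "oz_eq",
    "refined_grains": "oz_eq",
    "dairy": "cup_eq",
    "dairy_alt": "cup_eq",
    "eggs": "oz_eq",
    "beans_peas_lentils": "oz_eq",
    "soy_products": "oz_eq",
    "nuts_seeds": "oz_eq",
    "seafood": "oz_eq",
    "oils": "g",
}

PROFILE_GROUPS: Tuple[str, ...] = tuple(GROUP_UNITS)

#: Daily composition fields (amounts per day).
DAILY_GROUPS: Tuple[str, ...] = (
    "vegetables", "fruits", "whole_grains", "refined_grains",
    "dairy", "dairy_alt", "protein_foods",
)

#: Weekly vegetable subgroups (cup-eq/wk); detail under the daily total.
WEEKLY_VEG_GROUPS: Tuple[str, ...] = (
    "dark_green", "red_orange", "beans_peas_lentils_veg",
    "starchy_veg", "other_veg",
)

#: Weekly protein-food subgroups (oz-eq/wk).
WEEKLY_PROTEIN_GROUPS: Tuple[str, ...] = (
    "eggs", "beans_peas_lentils", "soy_products", "nuts_seeds", "seafood",
)


@dataclass
class FoodGroupProfile:
    """Nutrients per one serving unit (cup-eq, oz-eq, or gram) of a group."""

    group: str
    serving_unit: str
    nutrients: NutrientVector

    def __post_init__(self) -> None:
        if self.group not in GROUP_UNITS:
            raise ValidationError(f"unknown food group: {self.group!r}")
        expected = GROUP_UNITS[self.group]
        if self.serving_unit != expected:
            raise ValidationError(
                f"profile for {self.group} must be per {expected}, "
                f"got {self.serving_unit}")
        if "energy" not in set(self.nutrients):
            raise ValidationError(
                f"profile for {self.group} lacks an energy entry")


@dataclass(frozen=True)
class BlendWeights:
    """Consumption-share weights for blending fish groups into seafood."""

    w_high: float = 0.31
    w_low: float = 0.69

    def __post_init__(self) -> None:
        if not (0.0 <= self.w_high <= 1.0 and 0.0 <= self.w_low <= 1.0):
            raise ValidationError("blend weights must lie in [0, 1]")
        if abs(self.w_high + self.w_low - 1.0) > 1e-9:
            raise ValidationError("blend weights must sum to 1")


@dataclass(frozen=True)
class AtwaterFactors:
    """Energy conversion factors, kcal per gram of macronutrient."""

    protein: float = 4.0
    carbohydrate: float = 4.0
    fat: float = 9.0

    def __post_init__(self) -> None:
        if min(self.protein, self.carbohydrate, self.fat) <= 0:
            raise ValidationError("Atwater factors must be positive")


ENERGY_LEVELS: Tuple[int, ...] = (1800, 2000, 2200, 2400)

PATTERN_IDS: Tuple[str, ...] = (
    "HVDP", "model1_lacto", "model2_pesca", "model3_pescavegan",
)


@dataclass
class PatternComposition:
    """Food-group amounts of one dietary pattern at one energy level.

    ``daily`` holds cup-eq/d or oz-eq/d amounts (including the printed
    protein-foods daily total); ``weekly`` holds the vegetable and
    protein-food subgroup amounts per week.  The printed daily
    protein-foods total is the DGA's own rounding of the weekly subgroup
    sum / 7, so the consistency check uses a tolerance wide enough to
    cover that source rounding.
    """

    pattern_id: str
    energy_level: int
    daily: Dict[str, float] = field(default_factory=dict)
    weekly: Dict[str, float] = field(default_factory=dict)
    oils_g: float = 0.0
    discretionary_kcal: float = 0.0

    PROTEIN_CONSISTENCY_TOL = 0.08  # covers the source table's rounding

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities ---------------------------------------------
    @property
    def grains_total(self) -> float:
        return self.daily.get("whole_grains", 0.0) + \
            self.daily.get("refined_grains", 0.0)

    def protein_weekly_sum(self) -> float:
        return sum(self.weekly.get(g, 0.0) for g in WEEKLY_PROTEIN_GROUPS)

    def daily_amount(self, group: str) -> float:
        """Amount per day of a profile-carrying group (weekly / 7)."""
        if group == "oils":
            return self.oils_g
        if group in self.daily and group != "protein_foods":
            return self.daily[group]
        if group in WEEKLY_PROTEIN_GROUPS or group in WEEKLY_VEG_GROUPS:
            return weekly_to_daily(self.weekly.get(group, 0.0))
        raise ValidationError(f"unknown group: {group!r}")

    # -- validation ------------------------------------------------------
    def validate(self, protein_tol: Optional[float] = None) -> None:
        for name, amounts in (("daily", self.daily), ("weekly", self.weekly)):
            for group, amount in amounts.items():
                if amount < 0:
                    raise ValidationError(
                        f"negative {name} amount for {group}: {amount}")
        if self.oils_g < 0 or self.discretionary_kcal < 0:
            raise ValidationError("oils and discretionary kcal must be >= 0")
        unknown = set(self.daily) - set(DAILY_GROUPS)
        if unknown:
            raise SchemaError(f"unknown daily group rows: {sorted(unknown)}")
        unknown = set(self.weekly) - set(WEEKLY_VEG_GROUPS) - \
            set(WEEKLY_PROTEIN_GROUPS)
        if unknown:
            raise SchemaError(f"unknown weekly group rows: {sorted(unknown)}")
        tol = self.PROTEIN_CONSISTENCY_TOL if protein_tol is None else protein_tol
        if "protein_foods" in self.daily:
            implied = round_half_up(self.protein_weekly_sum() / 7.0, 2)
            printed = round_half_up(self.daily["protein_foods"], 2)
            if abs(printed - implied) > tol + 1e-9:
                raise ValidationError(
                    f"protein-foods daily total {printed} inconsistent with "
                    f"weekly subgroup sum/7 = {implied} (tol {tol})")

    def copy(self) -> "PatternComposition":
        return PatternComposition(
            pattern_id=self.pattern_id,
            energy_level=self.energy_level,
            daily=dict(self.daily),
            weekly=dict(self.weekly),
            oils_g=self.oils_g,
            discretionary_kcal=self.discretionary_kcal,
        )


def weekly_to_daily(amount: float) -> float:
    """Convert a per-week serving amount to per-day (full precision)."""
    if amount < 0:
        raise ValidationError(f"negative weekly amount: {amount}")
    return amount / 7.0


# --------------------------------------------------------------------------
# Dietary Reference Intakes
# --------------------------------------------------------------------------

POPULATIONS: Tuple[str, ...] = ("F19-30", "F31-50", "M19-30", "M31-50", "M51+")

#: Which population groups each energy level is deemed appropriate for.
POPULATIONS_BY_ENERGY: Dict[int, Tuple[str, ...]] = {
    1800: ("F31-50",),
    2000: ("F19-30", "M51+"),
    2200: ("M31-50",),
    2400: ("M19-30",),
}

#: Acceptable Macronutrient Distribution Ranges for adults 19+, % of kcal.
AMDR_BOUNDS: Dict[str, Tuple[float, float]] = {
    "protein": (10.0, 35.0),
    "carbohydrate": (45.0, 65.0),
    "fat": (20.0, 35.0),
}

#: Reference-value kinds.  "rda_ai" values are adequacy goals; "cdrr" is the
#: sodium Chronic Disease Risk Reduction ceiling (treated as an adequacy
#: denominator in paper-compatibility mode); "limit"/"range"/"none" rows
#: have no single adequacy denominator.
DRI_KINDS = ("rda_ai", "cdrr", "limit", "range", "none", "energy")


@dataclass(frozen=True)
class DRIEntry:
    value: float
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in DRI_KINDS:
            raise ValidationError(f"unknown DRI kind: {self.kind!r}")
        if self.kind == "rda_ai" and not self.value > 0:
            raise ValidationError("RDA/AI reference values must be positive")


@dataclass
class DRITable:
    """Per-population nutrient reference values with kind tags."""

    entries: Dict[Tuple[str, str], DRIEntry] = field(default_factory=dict)
    amdr: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(AMDR_BOUNDS))

    def set(self, population: str, nutrient: str, value: float,
            kind: str) -> None:
        if population not in POPULATIONS:
            raise ValidationError(f"unknown population group: {population!r}")
        if nutrient not in NUTRIENT_UNITS:
            raise ValidationError(f"unknown nutrient id: {nutrient!r}")
        self.entries[(population, nutrient)] = DRIEntry(value, kind)

    def entry(self, population: str, nutrient: str) -> Optional[DRIEntry]:
        return self.entries.get((population, nutrient))

    def value(self, population: str, nutrient: str) -> Optional[float]:
        e = self.entry(population, nutrient)
        return None if e is None else e.value

    def populations(self) -> Tuple[str, ...]:
        return tuple(sorted({p for p, _ in self.entries}))

    def nutrients(self, population: str) -> Tuple[str, ...]:
        return tuple(n for n in NUTRIENTS
                     if (population, n) in self.entries)
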