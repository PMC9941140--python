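"""Nutrient totalization and adequacy statistics.

A pattern's nutrient total is the additive food-pattern-modeling sum:
daily serving amounts times per-serving profiles, weekly subgroup amounts
contributing at 1/7 per day, oils per gram, and the discretionary-calorie
allowance added to energy only.  Adequacy is expressed as percent of the
DRI, percent change from a baseline pattern, macronutrient energy shares
against the AMDRs, and the saturated-fat share of energy.

Two totalization views are carried side by side: full precision, and a
paper-compatibility view in which percent-of-DRI is computed from totals
rounded to table display precision (the convention the source adequacy
tables follow), while percent change always uses full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Set, Tuple

import pandas as pd

from .core import (
    AMDR_BOUNDS, DISPLAY_DECIMALS, GROUP_UNITS, NUTRIENT_UNITS, NUTRIENTS,
    PROFILE_GROUPS, POPULATIONS_BY_ENERGY,
    AtwaterFactors, ConfigurationError, DRITable, FoodGroupProfile,
    NutrientVector, PatternComposition, ValidationError,
    display_amount, round_half_up,
)

#: Saturated-fat limits as % of kcal: the DGA planning limit and the
#: tighter bound the modeled patterns were all observed to satisfy.
SATFAT_DGA_LIMIT_PCT = 10.0
SATFAT_OBSERVED_BOUND_PCT = 5.0


def total_nutrients(comp: PatternComposition,
                    profiles: Mapping[str, FoodGroupProfile]
                    ) -> NutrientVector:
    """Total daily nutrients of a composition under the given profiles.

    Raises :class:`ConfigurationError` naming the group if a consumed
    group has no profile.
    """
    total = NutrientVector.zero()
    for group in PROFILE_GROUPS:
        amount = comp.daily_amount(group)
        if amount == 0:
            continue
        profile = profiles.get(group)
        if profile is None:
            raise ConfigurationError(
                f"no nutrient profile for consumed group {group!r}")
        if profile.serving_unit != GROUP_UNITS[group]:
            raise ValidationError(
                f"profile unit {profile.serving_unit!r} does not match "
                f"{group} ({GROUP_UNITS[group]})")
        total = total + amount * profile.nutrients
    if comp.discretionary_kcal:
        total = total + NutrientVector({"energy": comp.discretionary_kcal})
    return total


def percent_of_dri(total: float, dri: float) -> float:
    """100 * total / dri at full precision; caller rounds for display."""
    if not dri > 0:
        raise ValidationError(f"DRI reference must be positive, got {dri}")
    if total < 0:
        raise ValidationError("nutrient total must be >= 0")
    return 100.0 * total / dri


def percent_change(baseline: float, model: float) -> float:
    """Percent change from baseline at full precision.

    A zero baseline with a nonzero model value has no defined percent
    change and yields NaN (rendered as "n/a"); zero to zero is 0.
    """
    if baseline < 0:
        raise ValidationError("baseline must be >= 0")
    if baseline == 0:
        return 0.0 if model == 0 else math.nan
    return 100.0 * (model - baseline) / baseline


@dataclass(frozen=True)
class AmdrShares:
    protein: float
    carbohydrate: float
    fat: float
    within: Dict[str, bool]

    def as_dict(self) -> Dict[str, float]:
        return {"protein": self.protein, "carbohydrate": self.carbohydrate,
                "fat": self.fat}

    @property
    def all_within(self) -> bool:
        return all(self.within.values())


def amdr_shares(protein_g: float, carbohydrate_g: float, fat_g: float,
                total_kcal: float,
                factors: AtwaterFactors = AtwaterFactors(),
                bounds: Optional[Mapping[str, Tuple[float, float]]] = None
                ) -> AmdrShares:
    """Macronutrient energy shares (% of kcal) and AMDR verdicts.

    The denominator is the pattern's total energy (which includes oils and
    discretionary calories), not the Atwater sum of the three grams.
    """
    if not total_kcal > 0:
        raise ValidationError("total kcal must be positive")
    if min(protein_g, carbohydrate_g, fat_g) < 0:
        raise ValidationError("macronutrient grams must be >= 0")
    bounds = dict(AMDR_BOUNDS if bounds is None else bounds)
    shares = {
        "protein": 100.0 * protein_g * factors.protein / total_kcal,
        "carbohydrate":
            100.0 * carbohydrate_g * factors.carbohydrate / total_kcal,
        "fat": 100.0 * fat_g * factors.fat / total_kcal,
    }
    within = {m: bounds[m][0] <= shares[m] <= bounds[m][1] for m in shares}
    return AmdrShares(within=within, **shares)


@dataclass(frozen=True)
class SatFatShare:
    share_pct: float
    within_dga_limit: bool      # < 10% of kcal
    within_observed_bound: bool  # <= 5% of kcal


def saturated_fat_share(satfat_g: float, total_kcal: float,
                        factors: AtwaterFactors = AtwaterFactors()
                        ) -> SatFatShare:
    """Saturated-fat share of energy with both limit verdicts."""
    if not total_kcal > 0:
        raise ValidationError("total kcal must be positive")
    if satfat_g < 0:
        raise ValidationError("saturated fat grams must be >= 0")
    share = 100.0 * satfat_g * factors.fat / total_kcal
    return SatFatShare(
        share_pct=share,
        within_dga_limit=share < SATFAT_DGA_LIMIT_PCT,
        within_observed_bound=share <= SATFAT_OBSERVED_BOUND_PCT)


@dataclass
class AdequacyReport:
    """Per-nutrient adequacy of one pattern for one population group."""

    pattern_id: str
    energy_level: int
    population: str
    table: pd.DataFrame            # index: nutrient id
    amdr: AmdrShares
    satfat: SatFatShare
    below_100: Set[str] = field(default_factory=set)
    below_50: Set[str] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        """Rounded view mirroring the source table column order."""
        df = self.table.copy()
        for col in ("dri", "baseline", "total", "pct_change", "pct_dri"):
            df[col] = df[col].map(
                lambda v: round_half_up(v, 2) if pd.notna(v) else v)
        df["total_display"] = [
            display_amount(n, v) if pd.notna(v) else v
            for n, v in zip(df.index, self.table["total"])]
        return df[["unit", "dri", "dri_kind", "baseline", "total",
                   "total_display", "pct_change", "pct_dri"]]

    def to_markdown(self) -> str:
        header = (f"# {self.pattern_id} at {self.energy_level} kcal "
                  f"({self.population})\n\n")
        lines = [
            "| Nutrient | Unit | DRI | Baseline | Model | "
            "Change from baseline, % | % of DRI |",
            "| --- | --- | --- | --- | --- | --- | --- |",
        ]

        def cell(value, nd=2):
            if value is None or (isinstance(value, float)
                                 and math.isnan(value)):
                return "n/a"
            return f"{round_half_up(float(value), nd):g}"

        for nutrient, row in self.table.iterrows():
            model_disp = display_amount(nutrient, row["total"])
            base_disp = (display_amount(nutrient, row["baseline"])
                         if pd.notna(row["baseline"]) else math.nan)
            lines.append(
                f"| {nutrient} | {row['unit']} | {cell(row['dri'])} | "
                f"{cell(base_disp)} | {cell(model_disp)} | "
                f"{cell(row['pct_change'])} | {cell(row['pct_dri'])} |")
        amdr = self.amdr
        footer = (
            f"\nAMDR shares (% kcal): protein {amdr.protein:.1f}, "
            f"carbohydrate {amdr.carbohydrate:.1f}, fat {amdr.fat:.1f} "
            f"({'all within range' if amdr.all_within else 'OUT OF RANGE'})."
            f"\nSaturated fat: {self.satfat.share_pct:.2f}% of kcal."
            f"\nBelow 100% of DRI: {sorted(self.below_100)}"
            f"\nBelow 50% of DRI: {sorted(self.below_50)}\n")
        return header + "\n".join(lines) + "\n" + footer


def evaluate_pattern(comp: PatternComposition,
                     profiles: Mapping[str, FoodGroupProfile],
                     dri_table: DRITable,
                     population: str,
                     baseline: Optional[PatternComposition] = None,
                     *,
                     paper_mode: bool = True,
                     enforce_mapping: bool = True,
                     sodium_as_target: bool = True,
                     factors: AtwaterFactors = AtwaterFactors()
                     ) -> AdequacyReport:
    """Full adequacy evaluation of one pattern.

    ``paper_mode`` computes percent-of-DRI from display-rounded totals
    (the source tables' convention); percent change from the baseline
    always uses full-precision totals.  ``sodium_as_target`` treats the
    sodium CDRR ceiling as an adequacy denominator, replicating the
    source tables; disable it to exclude sodium from shortfall sets.
    """
    allowed = POPULATIONS_BY_ENERGY.get(comp.energy_level, ())
    if enforce_mapping and population not in allowed:
        raise ValidationError(
            f"population {population!r} is not mapped to the "
            f"{comp.energy_level} kcal level (expected one of {allowed}); "
            f"pass enforce_mapping=False to override")

    totals = total_nutrients(comp, profiles)
    base_totals = (total_nutrients(baseline, profiles)
                   if baseline is not None else None)

    records = []
    below_100: Set[str] = set()
    below_50: Set[str] = set()
    for nutrient in NUTRIENTS:
        total = totals.get(nutrient)
        entry = dri_table.entry(population, nutrient)
        if nutrient == "energy":
            dri_value: Optional[float] = float(comp.energy_level)
            kind = "energy"
        elif entry is None:
            dri_value, kind = None, "none"
        else:
            dri_value, kind = entry.value, entry.kind

        counts_for_adequacy = (
            kind == "rda_ai" or (kind == "cdrr" and sodium_as_target))
        pct: float = math.nan
        if (kind == "energy" or counts_for_adequacy) and dri_value:
            numer = display_amount(nutrient, total) if paper_mode else total
            pct = percent_of_dri(numer, dri_value)
            if counts_for_adequacy:
                if pct < 100.0:
                    below_100.add(nutrient)
                if pct < 50.0:
                    below_50.add(nutrient)

        change = math.nan
        base_value = math.nan
        if base_totals is not None:
            base_value = base_totals.get(nutrient)
            change = percent_change(base_value, total)

        records.append({
            "nutrient": nutrient, "unit": NUTRIENT_UNITS[nutrient],
            "dri": math.nan if dri_value is None else dri_value,
            "dri_kind": kind, "baseline": base_value, "total": total,
            "pct_change": change, "pct_dri": pct,
        })

    table = pd.DataFrame(records).set_index("nutrient")
    energy = totals.get("energy")
    shares = amdr_shares(totals.get("protein"), totals.get("carbohydrate"),
                         totals.get("total_fat"), energy, factors,
                         dri_table.amdr)
    satfat = saturated_fat_share(totals.get("saturated_fat"), energy,
                                 factors)
    return AdequacyReport(
        pattern_id=comp.pattern_id, energy_level=comp.energy_level,
        population=population, table=table, amdr=shares, satfat=satfat,
        below_100=below_100, below_50=below_50)
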