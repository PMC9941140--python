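"""Readers and writers for pattern-composition, profile, and DRI tables.

All formats are plain text (CSV or JSON).  The pattern-table CSV schema is
the packaged fixture schema (``food_group,unit,<pattern>...``); the reader
additionally understands source-style row labels such as
``"Seafood (oz eq/day)"``.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from .core import (
    DAILY_GROUPS, GROUP_UNITS, NUTRIENT_UNITS, PROFILE_GROUPS,
    WEEKLY_PROTEIN_GROUPS, WEEKLY_VEG_GROUPS,
    DRITable, FoodGroupProfile, NutrientVector, PatternComposition,
    SchemaError, ValidationError,
)

PathLike = Union[str, Path]

#: Canonical row ids of a pattern table.
PATTERN_ROWS = (
    "vegetables", "dark_green", "red_orange", "beans_peas_lentils_veg",
    "starchy_veg", "other_veg", "fruits", "grains", "whole_grains",
    "refined_grains", "dairy", "dairy_alt", "protein_foods",
    "eggs", "beans_peas_lentils", "soy_products", "nuts_seeds", "seafood",
    "oils", "discretionary",
)

#: Rows that must be present for a composition to be constructed.  The
#: aggregate "grains" row is optional (derivable from whole + refined).
REQUIRED_ROWS = tuple(r for r in PATTERN_ROWS if r != "grains")

_LABEL_ALIASES = {
    "vegetables": "vegetables",
    "dark green": "dark_green",
    "red and orange": "red_orange",
    "starchy vegetables": "starchy_veg",
    "starchy": "starchy_veg",
    "other vegetables": "other_veg",
    "other": "other_veg",
    "fruits": "fruits",
    "grains": "grains",
    "whole grains": "whole_grains",
    "refined grains": "refined_grains",
    "dairy": "dairy",
    "dairyalt": "dairy_alt",
    "dairy alt": "dairy_alt",
    "dairy_alt": "dairy_alt",
    "protein foods": "protein_foods",
    "protein_foods": "protein_foods",
    "eggs": "eggs",
    "soy products": "soy_products",
    "soy_products": "soy_products",
    "nuts seeds": "nuts_seeds",
    "nuts, seeds": "nuts_seeds",
    "nuts_seeds": "nuts_seeds",
    "seafood": "seafood",
    "oils": "oils",
    "discretionary": "discretionary",
    "discretionary calories": "discretionary",
}


def _canonical_row(label: str, unit_hint: str = "") -> str:
    """Map a row label (canonical or source-style) to its canonical id."""
    raw = str(label).strip()
    if raw in PATTERN_ROWS:
        return raw
    text = raw.lower()
    # pull a unit hint out of the label, e.g. "Seafood (oz eq/day)"
    m = re.search(r"[,(]\s*(cup|oz|g|kcal)[^)]*\)?\s*$", text)
    if m:
        unit_hint = unit_hint or m.group(1)
        text = text[:m.start()]
    text = re.sub(r"[().]", "", text).strip().strip(",").strip()
    if text in ("beans peas lentils", "beans, peas, lentils"):
        # appears twice in the source table: cup-eq row is the vegetable
        # subgroup, oz-eq row the protein subgroup
        return ("beans_peas_lentils_veg" if "cup" in unit_hint
                else "beans_peas_lentils")
    if text in ("beans_peas_lentils_veg", "beans_peas_lentils"):
        return text
    alias = _LABEL_ALIASES.get(text) or _LABEL_ALIASES.get(
        text.replace(",", ""))
    if alias is None:
        raise SchemaError(f"unknown food-group row label: {label!r}")
    return alias


def _composition_from_rows(pattern_id: str, energy_level: int,
                           rows: Dict[str, float]) -> PatternComposition:
    missing = [r for r in REQUIRED_ROWS if r not in rows]
    if missing:
        raise SchemaError(
            f"pattern table missing required rows: {missing}")
    if "grains" in rows:
        total = rows["whole_grains"] + rows["refined_grains"]
        if abs(rows["grains"] - total) > 0.011:
            # the source table keeps a stale 6.5 aggregate for the
            # seafood models whose refined grains drop to 2.5; the
            # subgroup rows are authoritative
            logging.getLogger(__name__).warning(
                "pattern %s: grains aggregate %s != whole + refined = %s;"
                " using the subgroup rows", pattern_id, rows["grains"],
                total)
    daily = {g: rows[g] for g in DAILY_GROUPS}
    weekly = {g: rows[g]
              for g in (*WEEKLY_VEG_GROUPS, *WEEKLY_PROTEIN_GROUPS)}
    return PatternComposition(
        pattern_id=pattern_id, energy_level=energy_level,
        daily=daily, weekly=weekly,
        oils_g=rows["oils"], discretionary_kcal=rows["discretionary"])


def read_pattern_table(path: PathLike, fmt: Optional[str] = None,
                       energy_level: int = 2000
                       ) -> List[PatternComposition]:
    """Read a pattern-composition table (CSV or JSON).

    CSV: one row per food group (``food_group`` column, optional ``unit``
    column) and one column per pattern.  JSON: the structure written by
    :func:`write_pattern_table`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        payload = json.loads(path.read_text())
        return [_composition_from_dict(d) for d in payload["patterns"]]
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty pattern table: {path}") from exc
    if "food_group" not in df.columns:
        raise SchemaError("pattern table lacks a 'food_group' column")
    unit_col = df["unit"] if "unit" in df.columns else [""] * len(df)
    pattern_cols = [c for c in df.columns if c not in ("food_group", "unit")]
    if not pattern_cols:
        raise SchemaError("pattern table has no pattern columns")
    out = []
    for pid in pattern_cols:
        rows: Dict[str, float] = {}
        for label, unit, value in zip(df["food_group"], unit_col, df[pid]):
            key = _canonical_row(label, str(unit))
            amount = float(value)
            if amount < 0:
                raise ValidationError(
                    f"negative amount for {key} in pattern {pid}: {amount}")
            rows[key] = amount
        out.append(_composition_from_rows(pid, energy_level, rows))
    return out


def _composition_to_dict(comp: PatternComposition) -> dict:
    return {
        "pattern_id": comp.pattern_id,
        "energy_level": comp.energy_level,
        "daily": dict(comp.daily),
        "weekly": dict(comp.weekly),
        "oils_g": comp.oils_g,
        "discretionary_kcal": comp.discretionary_kcal,
    }


def _composition_from_dict(d: dict) -> PatternComposition:
    return PatternComposition(
        pattern_id=d["pattern_id"], energy_level=int(d["energy_level"]),
        daily={k: float(v) for k, v in d["daily"].items()},
        weekly={k: float(v) for k, v in d["weekly"].items()},
        oils_g=float(d["oils_g"]),
        discretionary_kcal=float(d["discretionary_kcal"]))


def write_pattern_table(comps: Sequence[PatternComposition], path: PathLike,
                        fmt: Optional[str] = None) -> Path:
    """Write compositions as CSV (fixture schema) or JSON."""
    path = Path(path)
    fmt = fmt or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        payload = {"patterns": [_composition_to_dict(c) for c in comps]}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path
    records = []
    unit_by_row = {
        "vegetables": "cup_eq_day", "fruits": "cup_eq_day",
        "grains": "oz_eq_day", "whole_grains": "oz_eq_day",
        "refined_grains": "oz_eq_day", "dairy": "cup_eq_day",
        "dairy_alt": "cup_eq_day", "protein_foods": "oz_eq_day",
        "oils": "g_day", "discretionary": "kcal_day",
        **{g: "cup_eq_week" for g in WEEKLY_VEG_GROUPS},
        **{g: "oz_eq_week" for g in WEEKLY_PROTEIN_GROUPS},
    }
    for row in PATTERN_ROWS:
        rec = {"food_group": row, "unit": unit_by_row[row]}
        for comp in comps:
            if row == "grains":
                value = comp.grains_total
            elif row == "oils":
                value = comp.oils_g
            elif row == "discretionary":
                value = comp.discretionary_kcal
            elif row in comp.daily:
                value = comp.daily[row]
            else:
                value = comp.weekly.get(row, 0.0)
            rec[comp.pattern_id] = round(value, 6)
        records.append(rec)
    pd.DataFrame(records).to_csv(path, index=False)
    return path


# --------------------------------------------------------------------------
# Profiles
# --------------------------------------------------------------------------

def write_profiles(profiles: Dict[str, FoodGroupProfile],
                   path: PathLike) -> Path:
    """Write profiles as a CSV with one row per group, one column per
    nutrient (amount per serving unit)."""
    path = Path(path)
    records = []
    for group in PROFILE_GROUPS:
        if group not in profiles:
            continue
        prof = profiles[group]
        rec = {"group": group, "serving_unit": prof.serving_unit}
        for nutrient in NUTRIENT_UNITS:
            rec[nutrient] = repr(prof.nutrients.get(nutrient))
        records.append(rec)
    pd.DataFrame(records).to_csv(path, index=False)
    return path


def read_profiles(path: PathLike) -> Dict[str, FoodGroupProfile]:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty profile table: {path}") from exc
    if "group" not in df.columns:
        raise SchemaError("profile table lacks a 'group' column")
    out: Dict[str, FoodGroupProfile] = {}
    for _, row in df.iterrows():
        group = row["group"]
        nutrients = {n: float(row[n]) for n in NUTRIENT_UNITS
                     if n in df.columns and pd.notna(row[n])}
        out[group] = FoodGroupProfile(
            group=group, serving_unit=row.get("serving_unit",
                                              GROUP_UNITS.get(group, "")),
            nutrients=NutrientVector(nutrients))
    return out


# --------------------------------------------------------------------------
# DRI tables
# --------------------------------------------------------------------------

def read_dri_table(path: PathLike) -> DRITable:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty DRI table: {path}") from exc
    required = {"population", "nutrient", "value", "kind"}
    if not required.issubset(df.columns):
        raise SchemaError(
            f"DRI table needs columns {sorted(required)}")
    table = DRITable()
    for row in df.itertuples(index=False):
        table.set(row.population, row.nutrient, float(row.value), row.kind)
    return table


def write_dri_table(table: DRITable, path: PathLike) -> Path:
    path = Path(path)
    records = [
        {"population": pop, "nutrient": nut,
         "value": entry.value, "kind": entry.kind}
        for (pop, nut), entry in sorted(table.entries.items())
    ]
    pd.DataFrame(records).to_csv(path, index=False)
    return path


# --------------------------------------------------------------------------
# Adequacy reports (delegates; see adequacy.AdequacyReport)
# --------------------------------------------------------------------------

def write_report(report, path: PathLike, fmt: Optional[str] = None) -> Path:
    """Write an :class:`~foodpatterns.adequacy.AdequacyReport` as CSV or
    Markdown mirroring the source table column order."""
    path = Path(path)
    fmt = fmt or ("markdown" if path.suffix.lower() in (".md", ".markdown")
                  else "csv")
    if fmt == "markdown":
        path.write_text(report.to_markdown())
    elif fmt == "csv":
        report.to_frame().to_csv(path, index=True)
    else:
        raise ValidationError(f"unknown report format: {fmt!r}")
    return path


def read_report_frame(path: PathLike) -> pd.DataFrame:
    """Read back a CSV report written by :func:`write_report`."""
    return pd.read_csv(path, index_col=0)
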