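"""Synthetic food-group nutrient profiles and their calibration.

The per-serving nutrient profiles behind USDA food pattern modeling are
not shipped with this package.  This module generates synthetic profiles
with the same arithmetic structure: every printed per-serving anchor value
is pinned exactly, unanchored entries are drawn log-uniformly from
configured plausible per-serving ranges, and the result is calibrated per
nutrient by bounded least squares so that the four 2,000-kcal pattern
totals reproduce the printed adequacy-table columns.

Calibration is per-nutrient independent non-negative least squares
(nutrients do not couple in an additive totalization), regularized toward
the generated profiles so the heavily under-determined system stays
plausible while fitting the printed targets.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import lsq_linear

from . import fixtures, io as fpio
from .core import (
    GROUP_UNITS, NUTRIENTS, PROFILE_GROUPS,
    BlendWeights, DRITable, FoodGroupProfile, NutrientVector,
    PatternComposition, ValidationError,
)
from .transform import blend_seafood_profile


class CalibrationError(ValidationError):
    """Calibration inputs are infeasible (e.g. a pin is negative)."""


# --------------------------------------------------------------------------
# Anchors
# --------------------------------------------------------------------------

#: Printed parent values the derived anchors are recomputed from.
PRINTED_PARENTS = {
    "seafood_vitamin_d_iu_per_oz_eq": 69.82,
    "dairy_alt_iron_mg_per_cup_eq": 0.94,
    "dairy_iron_mg_per_cup_eq": 0.08,
    "dairy_alt_choline_mg_per_cup_eq": 52.89,
    "dairy_milk_choline_mg_per_cup_eq": 25.67,
    "dairy_vitamin_d_iu_per_3_cup": 175.5,
    "dairy_alt_vitamin_d_iu_per_3_cup": 326.4,
    "seafood_choline_mg_at_10_oz_wk": 27.9,
    "seafood_oz_wk_at_2400": 10.0,
    "dairy_share_milk": 0.496,
    "dairy_share_yogurt": 0.045,
    "dairy_share_cheese": 0.448,
    "dairy_share_soy_milk": 0.01,
}


@dataclass(frozen=True)
class AnchorSet:
    """Per-serving pins plus the printed reference scalars behind them."""

    pins: Dict[Tuple[str, str], float]
    references: Dict[str, float]

    def __post_init__(self) -> None:
        for (group, nutrient), value in self.pins.items():
            if group not in GROUP_UNITS or nutrient not in NUTRIENTS:
                raise ValidationError(
                    f"bad anchor key: ({group!r}, {nutrient!r})")
            if value < 0:
                raise CalibrationError(
                    f"anchor ({group}, {nutrient}) is negative: {value}")


def default_anchors() -> AnchorSet:
    """Anchor set from the printed per-serving values; derived pins are
    recomputed from their printed parents (3-cup totals, the 2,400-kcal
    seafood choline figure) rather than hard-coded."""
    refs = dict(PRINTED_PARENTS)
    pins = {
        ("seafood", "vitamin_d"): refs["seafood_vitamin_d_iu_per_oz_eq"],
        ("dairy_alt", "iron"): refs["dairy_alt_iron_mg_per_cup_eq"],
        ("dairy", "iron"): refs["dairy_iron_mg_per_cup_eq"],
        ("dairy_alt", "choline"): refs["dairy_alt_choline_mg_per_cup_eq"],
        ("dairy", "vitamin_d"): refs["dairy_vitamin_d_iu_per_3_cup"] / 3.0,
        ("dairy_alt", "vitamin_d"):
            refs["dairy_alt_vitamin_d_iu_per_3_cup"] / 3.0,
        ("seafood", "choline"):
            refs["seafood_choline_mg_at_10_oz_wk"] /
            (refs["seafood_oz_wk_at_2400"] / 7.0),
    }
    return AnchorSet(pins=pins, references=refs)


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------

def load_profile_ranges() -> dict:
    ref = resources.files("foodpatterns") / "data" / "profile_ranges.yaml"
    with resources.as_file(ref) as path:
        return yaml.safe_load(path.read_text())


def generate_profiles(seed: int,
                      anchors: Optional[AnchorSet] = None,
                      ranges: Optional[dict] = None
                      ) -> Dict[str, FoodGroupProfile]:
    """Draw synthetic per-serving profiles; anchored entries are exact.

    Deterministic given ``seed``: the same seed yields byte-identical
    profiles.  Unanchored entries are log-uniform within the configured
    per-serving range; a [0, 0] range (or, for oils, any unlisted
    nutrient) is zero.
    """
    anchors = anchors or default_anchors()
    config = ranges or load_profile_ranges()
    oils_sparse = bool(config.get("oils_zero_unless_listed", True))
    rng = np.random.default_rng(seed)
    profiles: Dict[str, FoodGroupProfile] = {}
    for group in PROFILE_GROUPS:
        entries: Dict[str, float] = {}
        for nutrient in NUTRIENTS:
            pin = anchors.pins.get((group, nutrient))
            spec = config["nutrients"].get(nutrient, {})
            overrides = spec.get("overrides", {})
            if group in overrides:
                lo, hi = overrides[group]
            elif group == "oils" and oils_sparse:
                lo, hi = 0.0, 0.0
            else:
                lo, hi = spec.get("default", [0.0, 0.0])
            # draw unconditionally so the stream, hence every other
            # entry, is unchanged whether or not this one is pinned
            if hi <= 0:
                drawn = 0.0
            else:
                lo = max(float(lo), float(hi) * 1e-3)
                drawn = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            entries[nutrient] = float(pin) if pin is not None else drawn
        profiles[group] = FoodGroupProfile(
            group=group, serving_unit=GROUP_UNITS[group],
            nutrients=NutrientVector(entries))
    return profiles


# --------------------------------------------------------------------------
# Calibration
# --------------------------------------------------------------------------

@dataclass
class CalibrationProblem:
    """Per-nutrient bounded least-squares problems sharing one matrix.

    ``A`` has one row per pattern observation and one column per food
    group (daily serving amounts); ``targets[n]`` is the vector of printed
    daily totals for nutrient ``n``; ``prior[n]`` seeds the regularization;
    ``pins`` fixes anchored entries exactly.
    """

    groups: Tuple[str, ...]
    A: np.ndarray
    targets: Dict[str, np.ndarray]
    prior: Dict[str, np.ndarray]
    pins: Dict[Tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or self.A.shape[1] != len(self.groups):
            raise ValidationError("composition matrix shape mismatch")
        for name, y in self.targets.items():
            if len(np.asarray(y)) != self.A.shape[0]:
                raise ValidationError(
                    f"target length mismatch for {name}")
        for (group, _), value in self.pins.items():
            if group not in self.groups:
                raise ValidationError(f"pin on unknown group {group!r}")
            if value < 0:
                raise CalibrationError(
                    f"pin violates non-negativity: {value}")


def solve_pinned_nnls(A: np.ndarray, y: np.ndarray, prior: np.ndarray,
                      pins: Mapping[int, float], lam: float = 1e-5
                      ) -> np.ndarray:
    """min ||A p - y||^2 + lam-weighted pull toward ``prior``, p >= 0,
    with ``pins`` (column index -> value) held exactly.

    Columns are rescaled by the prior so the regularization is relative;
    zero-prior columns get a small mobility scale so the data can lift
    them off zero when required.
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float)
    prior = np.asarray(prior, dtype=float)
    n = A.shape[1]
    free = np.array([j for j in range(n) if j not in pins], dtype=int)
    p = np.zeros(n)
    for j, v in pins.items():
        if v < 0:
            raise CalibrationError(f"pin violates non-negativity: {v}")
        p[j] = v
    resid_target = y - A @ p
    if free.size == 0:
        return p
    Af = A[:, free]
    p0 = prior[free]
    positive = p0[p0 > 0]
    fallback = 0.05 * float(np.median(positive)) if positive.size else 1.0
    scale = np.where(p0 > 0, p0, fallback)
    yscale = max(float(np.max(np.abs(resid_target))), 1e-9)
    An = (Af * scale) / yscale
    bn = resid_target / yscale
    q0 = p0 / scale
    k = free.size
    stacked_A = np.vstack([An, np.sqrt(lam) * np.eye(k)])
    stacked_b = np.concatenate([bn, np.sqrt(lam) * q0])
    sol = lsq_linear(stacked_A, stacked_b, bounds=(0.0, np.inf),
                     tol=1e-14)
    p[free] = sol.x * scale
    # snap numerically-zero entries (bound-active solutions) to zero
    top = float(np.max(p)) if np.any(p > 0) else 0.0
    if top > 0:
        p[p < 1e-9 * top] = 0.0
    return p


def calibrate_profiles(problem: CalibrationProblem, lam: float = 1e-5,
                       rel_tol: float = 0.02
                       ) -> Tuple[Dict[str, FoodGroupProfile],
                                  pd.DataFrame, List[str]]:
    """Solve every per-nutrient problem; returns (profiles, residual
    table, nutrients flagged as not reproducing their targets).

    A nutrient is flagged when some observation misses its printed target
    by more than ``rel_tol`` relative (small targets are judged against
    the largest target of that nutrient instead).
    """
    groups = problem.groups
    index = {g: j for j, g in enumerate(groups)}
    solutions: Dict[str, np.ndarray] = {}
    rows = []
    flagged: List[str] = []
    for nutrient in NUTRIENTS:
        if nutrient not in problem.targets:
            continue
        y = np.asarray(problem.targets[nutrient], dtype=float)
        prior = np.asarray(problem.prior[nutrient], dtype=float)
        pins = {index[g]: v for (g, n), v in problem.pins.items()
                if n == nutrient}
        p = solve_pinned_nnls(problem.A, y, prior, pins, lam=lam)
        solutions[nutrient] = p
        fitted = problem.A @ p
        ymax = float(np.max(np.abs(y))) if np.any(y) else 1.0
        denom = np.maximum(np.abs(y), 0.05 * ymax)
        rel = np.abs(fitted - y) / np.maximum(denom, 1e-12)
        rows.append({"nutrient": nutrient,
                     "max_rel_residual": float(np.max(rel)),
                     "rms_residual": float(np.sqrt(np.mean(
                         (fitted - y) ** 2)))})
        if float(np.max(rel)) > rel_tol:
            flagged.append(nutrient)
    residuals = pd.DataFrame(rows).set_index("nutrient")

    profiles: Dict[str, FoodGroupProfile] = {}
    for j, group in enumerate(groups):
        entries = {n: float(solutions[n][j]) for n in solutions}
        if "energy" not in entries:
            raise ValidationError("calibration targets must include energy")
        profiles[group] = FoodGroupProfile(
            group=group, serving_unit=GROUP_UNITS[group],
            nutrients=NutrientVector(entries))
    return profiles, residuals, flagged


def build_calibration_problem(
        compositions: Mapping[str, PatternComposition],
        printed: pd.DataFrame,
        prior_profiles: Mapping[str, FoodGroupProfile],
        anchors: Optional[AnchorSet] = None) -> CalibrationProblem:
    """Assemble the printed-table calibration problem.

    Observations are the four 2,000-kcal patterns; targets are the
    printed total columns (``hvdp``, ``model1``, ``model2``, ``model3``),
    with the discretionary-calorie allowance subtracted from the energy
    row since it is added outside the profile sum.
    """
    anchors = anchors or default_anchors()
    order = ("HVDP", "model1_lacto", "model2_pesca", "model3_pescavegan")
    cols = ("hvdp", "model1", "model2", "model3")
    A = np.array([[compositions[p].daily_amount(g) for g in PROFILE_GROUPS]
                  for p in order])
    targets: Dict[str, np.ndarray] = {}
    for nutrient in NUTRIENTS:
        if nutrient not in printed.index:
            continue
        row = printed.loc[nutrient]
        values = pd.to_numeric(row[list(cols)], errors="coerce")
        if values.isna().any():
            continue
        y = values.to_numpy(dtype=float)
        if nutrient == "energy":
            y = y - np.array([compositions[p].discretionary_kcal
                              for p in order])
        targets[nutrient] = y
    prior = {
        n: np.array([prior_profiles[g].nutrients.get(n)
                     for g in PROFILE_GROUPS])
        for n in targets
    }
    return CalibrationProblem(groups=PROFILE_GROUPS, A=A, targets=targets,
                              prior=prior, pins=dict(anchors.pins))


# --------------------------------------------------------------------------
# Fish-group split
# --------------------------------------------------------------------------

#: Relative enrichment of the high-omega-3 fish profile over the blended
#: seafood group, per nutrient (bounded above by 1/w_high).
HIGH_OMEGA3_ENRICHMENT = {
    "epa": 2.8, "dha": 2.8, "vitamin_d": 2.5, "vitamin_b12": 1.5,
    "total_fat": 1.8, "polyunsaturated_fat": 2.0, "linolenic_acid": 1.8,
}


def split_seafood_profile(seafood: FoodGroupProfile,
                          weights: BlendWeights = BlendWeights(),
                          enrichment: Optional[Mapping[str, float]] = None
                          ) -> Tuple[FoodGroupProfile, FoodGroupProfile]:
    """Derive high-/low-omega-3 fish profiles whose consumption-weighted
    blend reproduces the seafood group exactly."""
    enrichment = dict(HIGH_OMEGA3_ENRICHMENT if enrichment is None
                      else enrichment)
    high: Dict[str, float] = {}
    low: Dict[str, float] = {}
    limit = 1.0 / weights.w_high if weights.w_high > 0 else np.inf
    for nutrient in seafood.nutrients:
        value = seafood.nutrients.get(nutrient)
        factor = min(enrichment.get(nutrient, 1.0), 0.999 * limit)
        high[nutrient] = factor * value
        low[nutrient] = ((value - weights.w_high * high[nutrient]) /
                         weights.w_low)
    mk = lambda e: FoodGroupProfile(group="seafood", serving_unit="oz_eq",
                                    nutrients=NutrientVector(e))
    return mk(high), mk(low)


# --------------------------------------------------------------------------
# Fixture bundle
# --------------------------------------------------------------------------

@dataclass
class FixtureBundle:
    """One reproducible input set: compositions, DRIs, profiles, fish
    split, anchors, and the calibration diagnostics."""

    seed: int
    compositions: Dict[str, PatternComposition]
    dri: DRITable
    profiles: Dict[str, FoodGroupProfile]
    fish_high: FoodGroupProfile
    fish_low: FoodGroupProfile
    anchors: AnchorSet
    calibrated: bool
    residuals: Optional[pd.DataFrame]
    flagged: List[str]

    def manifest(self) -> dict:
        digest = hashlib.sha256()
        for group in PROFILE_GROUPS:
            for nutrient in NUTRIENTS:
                digest.update(
                    repr(self.profiles[group].nutrients.get(nutrient))
                    .encode())
        return {
            "seed": self.seed,
            "calibrated": self.calibrated,
            "flagged_nutrients": list(self.flagged),
            "profile_sha256": digest.hexdigest(),
            "fixture_annotations": fixtures.FIXTURE_ANNOTATIONS,
        }

    def save(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        fpio.write_pattern_table(list(self.compositions.values()),
                                 directory / "patterns.csv")
        fpio.write_profiles(self.profiles, directory / "profiles.csv")
        fpio.write_profiles({"seafood": self.fish_high},
                            directory / "fish_high.csv")
        fpio.write_profiles({"seafood": self.fish_low},
                            directory / "fish_low.csv")
        fpio.write_dri_table(self.dri, directory / "dri.csv")
        if self.residuals is not None:
            self.residuals.to_csv(directory / "calibration_residuals.csv")
        (directory / "manifest.json").write_text(
            json.dumps(self.manifest(), indent=2, sort_keys=True) + "\n")
        return directory


def fixture_bundle(seed: int = 0, calibrate: bool = True,
                   lam: float = 1e-5, rel_tol: float = 0.02
                   ) -> FixtureBundle:
    """Build the complete reproducible input set used by the tests and
    the CLI demo.  Deterministic given ``seed``."""
    anchors = default_anchors()
    compositions = fixtures.load_table2_compositions()
    dri = fixtures.load_dri_table()
    prior = generate_profiles(seed, anchors=anchors)
    residuals = None
    flagged: List[str] = []
    if calibrate:
        printed = fixtures.load_printed_nutrient_table()
        problem = build_calibration_problem(compositions, printed, prior,
                                            anchors)
        profiles, residuals, flagged = calibrate_profiles(
            problem, lam=lam, rel_tol=rel_tol)
        # groups/nutrients outside the calibration targets keep the prior
        for group, prof in prior.items():
            entries = profiles[group].nutrients.to_dict()
            for nutrient in NUTRIENTS:
                entries.setdefault(nutrient, prof.nutrients.get(nutrient))
            profiles[group] = FoodGroupProfile(
                group=group, serving_unit=GROUP_UNITS[group],
                nutrients=NutrientVector(entries))
    else:
        profiles = prior
    fish_high, fish_low = split_seafood_profile(profiles["seafood"])
    blend_check = blend_seafood_profile(fish_high, fish_low)
    if not blend_check.nutrients.isclose(profiles["seafood"].nutrients,
                                         rel=1e-9, abs_tol=1e-9):
        raise CalibrationError("fish split does not blend back to seafood")
    return FixtureBundle(
        seed=seed, compositions=compositions, dri=dri, profiles=profiles,
        fish_high=fish_high, fish_low=fish_low, anchors=anchors,
        calibrated=calibrate, residuals=residuals, flagged=flagged)
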