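"""Adequacy statistics: totalization, %DRI, %change, AMDR, shortfalls."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from foodpatterns import (
    AtwaterFactors, ConfigurationError, DRITable, NutrientVector,
    PatternComposition, ValidationError, amdr_shares, build_model,
    display_amount, evaluate_pattern, percent_change, percent_of_dri,
    round_half_up, saturated_fat_share, total_nutrients,
)


def empty_composition(**daily):
    base = {"vegetables": 0.0, "fruits": 0.0, "whole_grains": 0.0,
            "refined_grains": 0.0, "dairy": 0.0, "dairy_alt": 0.0,
            "protein_foods": 0.0}
    base.update(daily)
    return PatternComposition("HVDP", 2000, daily=base, weekly={},
                              oils_g=0.0, discretionary_kcal=0.0)


class TestTotalNutrients:
    def test_zero_composition_gives_zero_vector(self, bundle):
        total = total_nutrients(empty_composition(), bundle.profiles)
        assert total.isclose(NutrientVector.zero())

    def test_single_group_product(self, bundle):
        comp = empty_composition(dairy_alt=3.0)
        total = total_nutrients(comp, bundle.profiles)
        # dairyALT iron is anchored at 0.94 mg per cup-eq
        assert total["iron"] == pytest.approx(3 * 0.94, abs=1e-12)

    def test_discretionary_energy_added_to_energy_only(self, bundle):
        comp = empty_composition()
        comp.discretionary_kcal = 250.0
        total = total_nutrients(comp, bundle.profiles)
        assert total["energy"] == 250.0
        assert total["protein"] == 0.0

    def test_weekly_groups_contribute_at_one_seventh(self, bundle):
        comp = empty_composition()
        comp.weekly = {"seafood": 7.0}
        total = total_nutrients(comp, bundle.profiles)
        expected = bundle.profiles["seafood"].nutrients["vitamin_d"]
        assert total["vitamin_d"] == pytest.approx(expected)

    def test_missing_profile_names_group(self, bundle):
        profiles = dict(bundle.profiles)
        del profiles["dairy"]
        comp = empty_composition(dairy=1.0)
        with pytest.raises(ConfigurationError, match="dairy"):
            total_nutrients(comp, profiles)

    def test_doubling_amounts_doubles_totals(self, bundle, hvdp):
        base = total_nutrients(hvdp, bundle.profiles)
        doubled = hvdp.copy()
        doubled.daily = {k: 2 * v for k, v in hvdp.daily.items()}
        doubled.weekly = {k: 2 * v for k, v in hvdp.weekly.items()}
        doubled.oils_g = 2 * hvdp.oils_g
        doubled.discretionary_kcal = 0.0  # excluded from scaling
        total = total_nutrients(doubled, bundle.profiles)
        for nutrient in base:
            food_only = base[nutrient]
            if nutrient == "energy":
                food_only -= hvdp.discretionary_kcal
            assert total[nutrient] == pytest.approx(2 * food_only,
                                                    rel=1e-9)

    def test_hvdp_totals_match_calibration_targets(self, bundle, hvdp):
        total = total_nutrients(hvdp, bundle.profiles)
        assert total["calcium"] == pytest.approx(1341, rel=0.02)
        assert total["energy"] == pytest.approx(1998, rel=0.02)


class TestPercentOfDri:
    @pytest.mark.parametrize("total,dri,expected", [
        (80, 56, 142.86), (243, 425, 57.18), (100, 100, 100.0),
        (251, 130, 193.08), (202, 600, 33.67)])
    def test_printed_examples(self, total, dri, expected):
        assert round_half_up(percent_of_dri(total, dri), 2) == expected

    def test_linear_in_total(self):
        assert percent_of_dri(50, 200) * 2 == percent_of_dri(100, 200)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValidationError, match="positive"):
            percent_of_dri(10, 0)


class TestPercentChange:
    def test_no_change_is_zero(self):
        assert percent_change(300, 300) == 0.0

    def test_full_precision(self):
        assert percent_change(300, 243) == pytest.approx(-19.0)

    def test_zero_baseline_nonzero_model_is_undefined(self):
        assert math.isnan(percent_change(0.0, 0.073))

    def test_zero_to_zero_is_zero(self):
        assert percent_change(0.0, 0.0) == 0.0

    @settings(max_examples=100, deadline=None)
    @given(b=st.floats(0.001, 1e5), m=st.floats(0, 1e5))
    def test_matches_hand_oracle(self, b, m):
        assert percent_change(b, m) == pytest.approx(
            (m - b) / b * 100.0, rel=1e-12)


class TestAmdrShares:
    def test_printed_2000_hvdp_block(self):
        shares = amdr_shares(80, 250, 54, 1998)
        assert round_half_up(shares.protein, 1) == 16.0
        assert shares.all_within

    def test_hand_arithmetic(self):
        shares = amdr_shares(100, 100, 100, 1700)
        assert shares.protein == pytest.approx(23.5294, abs=1e-3)
        assert shares.carbohydrate == pytest.approx(23.5294, abs=1e-3)
        assert shares.fat == pytest.approx(52.9412, abs=1e-3)

    def test_zero_grams_out_of_range(self):
        shares = amdr_shares(0, 0, 0, 2000)
        assert shares.as_dict() == {"protein": 0.0, "carbohydrate": 0.0,
                                    "fat": 0.0}
        assert not any(shares.within.values())

    def test_nonpositive_kcal_rejected(self):
        with pytest.raises(ValidationError):
            amdr_shares(80, 250, 54, 0)

    def test_custom_atwater_factors(self):
        shares = amdr_shares(100, 0, 0, 1000,
                             AtwaterFactors(protein=5, carbohydrate=4,
                                            fat=9))
        assert shares.protein == pytest.approx(50.0)


class TestSaturatedFat:
    @pytest.mark.parametrize("g,kcal,pct", [
        (10, 1998, 4.50), (0, 2000, 0.0), (11, 2000, 4.95)])
    def test_share(self, g, kcal, pct):
        result = saturated_fat_share(g, kcal)
        assert round_half_up(result.share_pct, 2) == pct
        assert result.within_dga_limit
        assert result.within_observed_bound

    def test_limit_flags(self):
        assert not saturated_fat_share(30, 2000).within_dga_limit
        assert not saturated_fat_share(12, 2000).within_observed_bound


class TestEvaluatePattern:
    def test_population_energy_mismatch_rejected(self, bundle, hvdp):
        with pytest.raises(ValidationError, match="not mapped"):
            evaluate_pattern(hvdp, bundle.profiles, bundle.dri, "F31-50")

    def test_mismatch_overridable(self, bundle, hvdp):
        report = evaluate_pattern(hvdp, bundle.profiles, bundle.dri,
                                  "F31-50", enforce_mapping=False)
        assert report.population == "F31-50"

    def test_below_50_is_subset_of_below_100(self, bundle, hvdp):
        for model in ("model1_lacto", "model2_pesca", "model3_pescavegan"):
            built = build_model(hvdp, model)
            report = evaluate_pattern(built, bundle.profiles, bundle.dri,
                                      "F19-30", baseline=hvdp)
            assert report.below_50 <= report.below_100

    def test_exactly_meeting_every_dri_gives_empty_sets(self, bundle,
                                                        hvdp):
        totals = total_nutrients(hvdp, bundle.profiles)
        dri = DRITable()
        for nutrient in bundle.dri.nutrients("F19-30"):
            rounded = display_amount(nutrient, totals[nutrient])
            if rounded > 0:
                dri.set("F19-30", nutrient, rounded, "rda_ai")
        report = evaluate_pattern(hvdp, bundle.profiles, dri, "F19-30")
        assert report.below_100 == set()
        assert report.below_50 == set()

    def test_sodium_toggle_drops_cdrr_shortfall(self, bundle, hvdp):
        built = build_model(hvdp, "model1_lacto")
        default = evaluate_pattern(built, bundle.profiles, bundle.dri,
                                   "F19-30")
        relaxed = evaluate_pattern(built, bundle.profiles, bundle.dri,
                                   "F19-30", sodium_as_target=False)
        assert "sodium" in default.below_100
        assert "sodium" not in relaxed.below_100

    def test_epa_change_from_zero_baseline_is_undefined(self, bundle,
                                                        hvdp):
        built = build_model(hvdp, "model2_pesca")
        report = evaluate_pattern(built, bundle.profiles, bundle.dri,
                                  "F19-30", baseline=hvdp)
        assert math.isnan(report.table.loc["epa", "pct_change"])
        assert report.table.loc["epa", "total"] > 0

    def test_paper_mode_uses_display_rounded_totals(self, bundle, hvdp):
        built = build_model(hvdp, "model1_lacto")
        paper = evaluate_pattern(built, bundle.profiles, bundle.dri,
                                 "F19-30", paper_mode=True)
        analysis = evaluate_pattern(built, bundle.profiles, bundle.dri,
                                    "F19-30", paper_mode=False)
        total = analysis.table.loc["choline", "total"]
        assert paper.table.loc["choline", "pct_dri"] == pytest.approx(
            100 * display_amount("choline", total) / 425)
        assert analysis.table.loc["choline", "pct_dri"] == pytest.approx(
            100 * total / 425)
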