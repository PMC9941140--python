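"""Pattern constructions: egg replacement, seafood addition with grain
offset, dairy swap, full model builds, and the fish-profile blend."""

import pytest
from hypothesis import given, settings, strategies as st

from foodpatterns import (
    BlendWeights, FoodGroupProfile, NutrientVector, PatternComposition,
    ValidationError, add_seafood_with_grain_offset, blend_seafood_profile,
    build_model, replace_eggs, round_half_up, swap_dairy_for_dairy_alt,
    weekly_to_daily,
)


def make_composition(eggs=3.0, beans=6.0, soy=8.0, nuts=7.0, seafood=0.0,
                     refined=3.0, dairy=3.0, energy=2000):
    weekly = {"eggs": eggs, "beans_peas_lentils": beans,
              "soy_products": soy, "nuts_seeds": nuts, "seafood": seafood}
    protein_daily = sum(weekly.values()) / 7.0
    return PatternComposition(
        "HVDP", energy,
        daily={"vegetables": 2.5, "fruits": 2.0, "whole_grains": 3.5,
               "refined_grains": refined, "dairy": dairy, "dairy_alt": 0.0,
               "protein_foods": protein_daily},
        weekly=weekly, oils_g=27.0, discretionary_kcal=250.0)


class TestReplaceEggs:
    def test_equal_three_way_split(self):
        out = replace_eggs(make_composition(eggs=3, beans=6, soy=8, nuts=7))
        assert out.weekly["eggs"] == 0.0
        assert out.weekly["beans_peas_lentils"] == 7.0
        assert out.weekly["soy_products"] == 9.0
        assert out.weekly["nuts_seeds"] == 8.0

    def test_no_eggs_is_identity(self):
        base = make_composition(eggs=0.0)
        out = replace_eggs(base)
        assert out.weekly == base.weekly and out.daily == base.daily

    def test_fractional_split(self):
        out = replace_eggs(make_composition(eggs=4.5))
        assert out.weekly["beans_peas_lentils"] == pytest.approx(7.5)
        assert out.weekly["soy_products"] == pytest.approx(9.5)
        assert out.weekly["nuts_seeds"] == pytest.approx(8.5)

    def test_missing_subgroup_rejected(self):
        comp = make_composition()
        del comp.weekly["soy_products"]
        with pytest.raises(ValidationError, match="soy_products"):
            replace_eggs(comp)

    def test_does_not_mutate_input(self):
        base = make_composition()
        replace_eggs(base)
        assert base.weekly["eggs"] == 3.0

    @settings(max_examples=100, deadline=None)
    @given(eggs=st.floats(0, 20), beans=st.floats(0, 20),
           soy=st.floats(0, 20), nuts=st.floats(0, 20))
    def test_conserves_weekly_protein_oz_eq(self, eggs, beans, soy, nuts):
        base = make_composition(eggs=eggs, beans=beans, soy=soy, nuts=nuts)
        out = replace_eggs(base)
        assert out.protein_weekly_sum() == pytest.approx(
            base.protein_weekly_sum(), rel=1e-12, abs=1e-12)


class TestAddSeafood:
    def test_grain_offset_and_protein_total(self):
        base = make_composition()
        base.daily["protein_foods"] = 3.5  # printed daily total
        out = add_seafood_with_grain_offset(base, 8.0)
        assert out.daily["refined_grains"] == 2.5
        assert out.weekly["seafood"] == 8.0
        assert round_half_up(out.daily["protein_foods"], 2) == 4.64

    def test_zero_seafood_is_identity(self):
        base = make_composition()
        out = add_seafood_with_grain_offset(base, 0.0)
        assert out.daily == base.daily and out.weekly == base.weekly

    def test_infeasible_offset_rejected(self):
        base = make_composition(refined=0.4)
        with pytest.raises(ValidationError, match="refined grains"):
            add_seafood_with_grain_offset(base, 8.0)

    def test_changes_exactly_two_groups_plus_protein_total(self):
        base = make_composition()
        out = add_seafood_with_grain_offset(base, 9.0)
        daily_diff = {k for k in base.daily
                      if base.daily[k] != out.daily[k]}
        weekly_diff = {k for k in base.weekly
                       if base.weekly[k] != out.weekly[k]}
        assert daily_diff == {"refined_grains", "protein_foods"}
        assert weekly_diff == {"seafood"}


class TestSwapDairy:
    def test_moves_amount_to_dairy_alt(self):
        out = swap_dairy_for_dairy_alt(make_composition(dairy=3.0))
        assert out.daily["dairy"] == 0.0
        assert out.daily["dairy_alt"] == 3.0

    def test_zero_dairy_is_identity(self):
        base = make_composition(dairy=0.0)
        out = swap_dairy_for_dairy_alt(base)
        assert out.daily == base.daily


class TestBuildModel:
    def test_pescavegan_composition(self, bundle, hvdp):
        out = build_model(hvdp, "pescavegan")
        assert out.weekly["beans_peas_lentils"] == 7.0
        assert out.weekly["soy_products"] == 9.0
        assert out.weekly["nuts_seeds"] == 8.0
        assert out.weekly["eggs"] == 0.0
        assert out.daily["dairy"] == 0.0
        assert out.daily["dairy_alt"] == 3.0
        assert out.weekly["seafood"] == 8.0
        assert out.daily["refined_grains"] == 2.5

    def test_seafood_schedule_at_2400(self):
        base = make_composition(energy=2400)
        base.daily["protein_foods"] = 3.5
        out = build_model(base, "pescatarian")
        assert out.weekly["seafood"] == 10.0
        daily = weekly_to_daily(out.weekly["seafood"])
        assert round_half_up(daily, 2) == 1.43

    def test_lacto_build_is_idempotent(self, hvdp):
        once = build_model(hvdp, "model1")
        twice = build_model(once, "model1")
        assert twice.daily == once.daily and twice.weekly == once.weekly

    def test_pescavegan_operations_commute(self, hvdp):
        import itertools
        from foodpatterns.transform import SEAFOOD_WEEKLY_BY_ENERGY
        ops = {
            "eggs": replace_eggs,
            "dairy": swap_dairy_for_dairy_alt,
            "seafood": lambda c: add_seafood_with_grain_offset(
                c, SEAFOOD_WEEKLY_BY_ENERGY[c.energy_level]),
        }
        results = []
        for order in itertools.permutations(ops):
            comp = hvdp
            for name in order:
                comp = ops[name](comp)
            results.append((comp.daily, comp.weekly))
        assert all(r == results[0] for r in results)

    def test_unknown_model_rejected(self, hvdp):
        with pytest.raises(ValidationError, match="unknown model"):
            build_model(hvdp, "carnivore")

    def test_unscheduled_energy_level_rejected(self):
        base = make_composition(energy=1900)
        with pytest.raises(ValidationError, match="schedule"):
            build_model(base, "pescatarian")


def _profile(values):
    return FoodGroupProfile("seafood", "oz_eq",
                            NutrientVector({"energy": values[0],
                                            "vitamin_d": values[1]}))


class TestBlend:
    def test_equal_inputs_identity(self):
        v = _profile([40.0, 70.0])
        out = blend_seafood_profile(v, v)
        assert out.nutrients == v.nutrients

    def test_weighted_average(self):
        out = blend_seafood_profile(_profile([40, 100]), _profile([40, 50]),
                                    BlendWeights(0.31, 0.69))
        assert out.nutrients["vitamin_d"] == pytest.approx(65.5)

    def test_mismatched_keys_rejected(self):
        a = _profile([40, 70])
        b = FoodGroupProfile("seafood", "oz_eq",
                             NutrientVector({"energy": 40.0}))
        with pytest.raises(ValidationError, match="identical nutrient"):
            blend_seafood_profile(a, b)

    def test_bad_weights_rejected(self):
        with pytest.raises(ValidationError):
            BlendWeights(0.4, 0.4)

    @settings(max_examples=50, deadline=None)
    @given(e=st.floats(1, 100), d=st.floats(0, 200),
           scale=st.floats(0.01, 10))
    def test_blend_is_linear(self, e, d, scale):
        high, low = _profile([e, d]), _profile([2 * e, 0.5 * d + 1])
        base = blend_seafood_profile(high, low)
        scaled = blend_seafood_profile(
            _profile([scale * e, scale * d]),
            _profile([scale * 2 * e, scale * (0.5 * d + 1)]))
        assert scaled.nutrients.isclose(scale * base.nutrients,
                                        rel=1e-9, abs_tol=1e-9)

    def test_calibrated_fixture_blend_hits_printed_vitamin_d(self, bundle):
        out = blend_seafood_profile(bundle.fish_high, bundle.fish_low)
        assert out.nutrients["vitamin_d"] == pytest.approx(69.82, abs=1e-9)
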