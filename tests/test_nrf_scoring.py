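import numpy as np
import pandas as pd
import pytest

from nrfindex.errors import DomainError, UndefinedRatioError, ZeroEnergyError
from nrfindex.intake_mar import DailyIntake
from nrfindex.nrf_scoring import (
    ENCOURAGE_9,
    PRESETS,
    FoodComposition,
    NutrientProfileConfig,
    amounts_per_reference,
    lim_subscore,
    nr_subscore,
    nrf_score,
    score_cohort,
    score_diet,
    score_food,
    variant_grid,
)

NRF92 = PRESETS["nrf9.2"]


def make_food(energy=100.0, **nutrients):
    return FoodComposition("F1", "test food", "other", energy, nutrients)


def random_foods(rng, n):
    from nrfindex.synthetic_cohort import ALL_NUTRIENTS

    foods = []
    for i in range(n):
        foods.append(
            FoodComposition(
                f"F{i}", f"food {i}", "other",
                energy_kcal_per_100g=float(rng.uniform(20, 600)),
                nutrients={nt: float(rng.gamma(1.5, 20.0)) for nt in ALL_NUTRIENTS},
            )
        )
    return foods


def oracle_total(food, config, dv, mrv):
    """Straight-line recomputation of the three published formulas."""
    if config.reference_amount == "per_100kcal":
        amounts = {k: v * 100.0 / food.energy_kcal_per_100g for k, v in food.nutrients.items()}
    else:
        amounts = dict(food.nutrients)
    nr = sum(
        min(amounts.get(n, 0.0) / dv[n], config.cap_percent_dv / 100.0) * 100.0
        for n in config.encourage
    )
    lim = sum(amounts.get(n, 0.0) / mrv[n] * 100.0 for n in config.limit)
    if config.algorithm == "sum":
        return nr - lim
    if config.algorithm == "mean":
        return nr / len(config.encourage) - lim / len(config.limit)
    return nr / lim


class TestAmountsPerReference:
    def test_per_100kcal_rescales_by_energy_density(self):
        food = make_food(energy=500.0, protein=10.0)
        assert amounts_per_reference(food, "per_100kcal")["protein"] == pytest.approx(2.0)

    def test_100kcal_per_100g_food_is_fixed_point(self):
        food = make_food(energy=100.0, protein=7.0, sodium=120.0)
        assert amounts_per_reference(food, "per_100kcal") == pytest.approx(
            amounts_per_reference(food, "per_100g")
        )

    def test_zero_energy_food_cannot_be_scored_per_kcal(self):
        with pytest.raises(ZeroEnergyError, match="F1"):
            amounts_per_reference(make_food(energy=0.0, protein=1.0), "per_100kcal")


class TestSubscores:
    def test_every_nutrient_at_dv_gives_100_points_each(self, dri):
        dv = dri.resolve_dv_map(ENCOURAGE_9, "male", 30)
        assert nr_subscore(dv, NRF92, dv) == pytest.approx(900.0)

    def test_zero_amounts_give_zero(self, dri):
        dv = dri.resolve_dv_map(ENCOURAGE_9, "male", 30)
        assert nr_subscore({}, NRF92, dv) == 0.0

    def test_cap_forces_single_nutrient_to_100(self, dri):
        dv = dri.resolve_dv_map(ENCOURAGE_9, "male", 30)
        amounts = {"protein": 3 * dv["protein"]}
        assert nr_subscore(amounts, NRF92, dv) == pytest.approx(100.0)

    @pytest.mark.parametrize(
        "satfat_frac,na_frac,expected", [(0, 0, 0.0), (1, 1, 200.0), (0, 0.5, 50.0)]
    )
    def test_lim_percent_of_mrv(self, dri, satfat_frac, na_frac, expected):
        mrv = dri.resolve_limit_map("male", 30)
        amounts = {"sat_fat": satfat_frac * mrv["sat_fat"], "sodium": na_frac * mrv["sodium"]}
        assert lim_subscore(amounts, NRF92, mrv) == pytest.approx(expected)

    def test_lim_is_uncapped(self, dri):
        mrv = dri.resolve_limit_map("male", 30)
        amounts = {"sat_fat": 5 * mrv["sat_fat"], "sodium": 0.0}
        assert lim_subscore(amounts, NRF92, mrv) == pytest.approx(500.0)


class TestAlgorithms:
    def test_sum_is_nr_minus_lim(self):
        assert nrf_score(900.0, 0.0, NRF92).total == 900.0
        s = nrf_score(450.0, 150.0, NRF92)
        assert s.total == pytest.approx(s.nr_subscore - s.lim_subscore)

    def test_mean_divides_by_nutrient_counts(self):
        cfg = NutrientProfileConfig("NRF9.2", ENCOURAGE_9, algorithm="mean")
        assert nrf_score(450.0, 150.0, cfg).total == pytest.approx(450 / 9 - 150 / 2)  # -25

    def test_ratio_and_its_singularity(self):
        cfg = NutrientProfileConfig("NRF9.2", ENCOURAGE_9, algorithm="ratio")
        assert nrf_score(450.0, 150.0, cfg).total == pytest.approx(3.0)
        with pytest.raises(UndefinedRatioError):
            nrf_score(450.0, 0.0, cfg)


class TestScoreFood:
    def test_food_at_exact_dvs_scores_900(self, dri):
        dv = dri.resolve_dv_map(ENCOURAGE_9, "male", 30)
        food = make_food(energy=100.0, **dv)
        assert score_food(food, NRF92, dri, "male", 30).total == pytest.approx(900.0)

    def test_per_100g_equals_per_100kcal_at_100kcal_density(self, dri):
        rng = np.random.default_rng(0)
        food = random_foods(rng, 1)[0]
        food = FoodComposition(food.food_id, food.name, food.group, 100.0, food.nutrients)
        from dataclasses import replace

        a = score_food(food, replace(NRF92, reference_amount="per_100g"), dri, "male", 30)
        b = score_food(food, replace(NRF92, reference_amount="per_100kcal"), dri, "male", 30)
        assert a.total == pytest.approx(b.total)

    def test_matches_bruteforce_oracle_on_random_foods(self, dri):
        rng = np.random.default_rng(42)
        foods = random_foods(rng, 20)
        for cfg in variant_grid():
            dv = dri.resolve_dv_map(cfg.encourage, "female", 45)
            mrv = dri.resolve_limit_map("female", 45)
            for food in foods:
                got = score_food(food, cfg, dri, "female", 45).total
                assert got == pytest.approx(oracle_total(food, cfg, dv, mrv), abs=1e-9)


class TestMonotonicityAndScale:
    def test_raising_encourage_below_cap_raises_sum_and_mean(self, dri):
        rng = np.random.default_rng(1)
        dv = dri.resolve_dv_map(ENCOURAGE_9, "male", 30)
        for _ in range(50):
            food = random_foods(rng, 1)[0]
            nutrient = ENCOURAGE_9[rng.integers(9)]
            below_cap = dict(food.nutrients)
            below_cap[nutrient] = 0.5 * dv[nutrient] * food.energy_kcal_per_100g / 100
            f0 = FoodComposition("a", "a", "other", food.energy_kcal_per_100g, below_cap)
            bumped = dict(below_cap)
            bumped[nutrient] *= 1.2
            f1 = FoodComposition("b", "b", "other", food.energy_kcal_per_100g, bumped)
            for alg in ("sum", "mean"):
                from dataclasses import replace

                cfg = replace(NRF92, algorithm=alg)
                assert (
                    score_food(f1, cfg, dri, "male", 30).total
                    > score_food(f0, cfg, dri, "male", 30).total
                )

    def test_raising_limit_nutrient_lowers_score(self, dri):
        rng = np.random.default_rng(2)
        food = random_foods(rng, 1)[0]
        worse = dict(food.nutrients)
        worse["sodium"] *= 2.0
        f1 = FoodComposition("b", "b", "other", food.energy_kcal_per_100g, worse)
        assert score_food(f1, NRF92, dri, "male", 30).total < score_food(
            food, NRF92, dri, "male", 30
        ).total

    def test_cap_saturation(self, dri):
        dv = dri.resolve_dv_map(ENCOURAGE_9, "male", 30)
        base = {n: 5 * dv[n] for n in ENCOURAGE_9}
        more = {n: 50 * dv[n] for n in ENCOURAGE_9}
        f0 = make_food(energy=100.0, **base)
        f1 = make_food(energy=100.0, **more)
        assert score_food(f0, NRF92, dri, "male", 30).total == pytest.approx(
            score_food(f1, NRF92, dri, "male", 30).total
        )

    def test_precap_nr_scales_with_energy_density(self, dri):
        # tiny amounts so no cap binds: NR per 100 kcal = NR per 100 g x 100/E
        rng = np.random.default_rng(3)
        dv = dri.resolve_dv_map(ENCOURAGE_9, "male", 30)
        mrv = dri.resolve_limit_map("male", 30)
        for _ in range(20):
            energy = float(rng.uniform(50, 600))
            nutrients = {n: 1e-3 * dv[n] * rng.random() for n in ENCOURAGE_9}
            food = make_food(energy=energy, **nutrients)
            nr_g = nr_subscore(amounts_per_reference(food, "per_100g"), NRF92, dv)
            nr_kcal = nr_subscore(amounts_per_reference(food, "per_100kcal"), NRF92, dv)
            assert nr_kcal == pytest.approx(nr_g * 100.0 / energy, abs=1e-9)


class TestScoreDiet:
    def _daily_from_food(self, food, grams):
        scale = grams / 100.0
        return DailyIntake(
            participant_id="P1",
            energy_kcal=food.energy_kcal_per_100g * scale,
            total_grams=grams,
            nutrients={k: v * scale for k, v in food.nutrients.items()},
            foods={food.food_id: grams},
        )

    def test_single_food_diet_equals_food_score_both_modes(self, dri):
        food = random_foods(np.random.default_rng(4), 1)[0]
        daily = self._daily_from_food(food, 250.0)
        expected = score_food(food, NRF92, dri, "male", 30).total
        for mode in ("diet_level", "energy_weighted_mean"):
            got = score_diet(
                daily, NRF92, dri, "male", 30, mode=mode, food_table={food.food_id: food}
            ).total
            assert got == pytest.approx(expected)

    def test_two_identical_foods_behave_like_one(self, dri):
        food = random_foods(np.random.default_rng(5), 1)[0]
        twin = FoodComposition("F9", "twin", "other", food.energy_kcal_per_100g, food.nutrients)
        one = self._daily_from_food(food, 300.0)
        two = DailyIntake(
            "P1",
            energy_kcal=one.energy_kcal,
            total_grams=300.0,
            nutrients=dict(one.nutrients),
            foods={food.food_id: 150.0, "F9": 150.0},
        )
        table = {food.food_id: food, "F9": twin}
        for mode in ("diet_level", "energy_weighted_mean"):
            assert score_diet(two, NRF92, dri, "male", 30, mode=mode, food_table=table).total == pytest.approx(
                score_diet(one, NRF92, dri, "male", 30, mode=mode, food_table={food.food_id: food}).total
            )

    def test_diet_level_matches_naive_summation_oracle(self, dri):
        rng = np.random.default_rng(6)
        foods = random_foods(rng, 5)
        grams = rng.uniform(20, 400, 5)
        totals = {}
        energy = 0.0
        for f, g in zip(foods, grams):
            energy += f.energy_kcal_per_100g * g / 100.0
            for k, v in f.nutrients.items():
                totals[k] = totals.get(k, 0.0) + v * g / 100.0
        daily = DailyIntake("P1", energy, float(grams.sum()), totals)
        # oracle: formulas applied to per-100kcal amounts of the pooled diet
        dv = dri.resolve_dv_map(ENCOURAGE_9, "male", 30)
        mrv = dri.resolve_limit_map("male", 30)
        amounts = {k: v * 100.0 / energy for k, v in totals.items()}
        nr = sum(min(amounts[n] / dv[n], 1.0) * 100 for n in ENCOURAGE_9)
        lim = sum(amounts[n] / mrv[n] * 100 for n in ("sat_fat", "sodium"))
        assert score_diet(daily, NRF92, dri, "male", 30).total == pytest.approx(nr - lim, abs=1e-9)

    def test_zero_energy_diet_rejected(self, dri):
        daily = DailyIntake("P1", 0.0, 100.0, {"protein": 1.0})
        with pytest.raises(ZeroEnergyError):
            score_diet(daily, NRF92, dri, "male", 30)


class TestScoreCohort:
    def test_vectorised_scores_match_scalar_path(self, small_cohort, dri):
        retained, part, _ = small_cohort
        vec = score_cohort(retained, part, NRF92, dri)
        meta = part.set_index("participant_id")
        for pid in retained.index[:10]:
            row = retained.loc[pid]
            nutrients = {
                c: float(row[c])
                for c in retained.columns
                if c not in ("energy_kcal", "total_grams") and not c.startswith("group_")
            }
            daily = DailyIntake(pid, float(row["energy_kcal"]), float(row["total_grams"]), nutrients)
            scalar = score_diet(
                daily, NRF92, dri, meta.loc[pid, "sex"], float(meta.loc[pid, "age"])
            ).total
            assert vec.loc[pid] == pytest.approx(scalar, abs=1e-9)
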