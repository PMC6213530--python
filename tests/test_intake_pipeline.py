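import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from starchsugar import intake_pipeline as ip
from starchsugar.composition_model import SaccharideProfile
from starchsugar.errors import EmptySetError, InvariantError, UnknownFoodError

from conftest import make_item


def tiny_frame():
    """Three-item nutrient frame assembled by hand."""
    rows = {
        "A": dict(energy=100.0, available_carbohydrate=20.0, starch=30.0,
                  glucose=0.0, fructose=0.0, galactose=0.0, sucrose=5.0,
                  maltose=0.0, lactose=0.0, trehalose=0.0, total_sugar=5.0,
                  free_sugar=5.0, naturally_occurring_sugar=0.0,
                  food_group="rice and grains"),
        "B": dict(energy=50.0, available_carbohydrate=10.0, starch=0.0,
                  glucose=1.0, fructose=0.5, galactose=0.0, sucrose=2.5,
                  maltose=0.0, lactose=0.0, trehalose=0.0, total_sugar=4.0,
                  free_sugar=0.0, naturally_occurring_sugar=4.0,
                  food_group="fruits"),
    }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "food_code"
    return frame


class TestComputeDailyIntake:
    def test_single_item(self):
        out = ip.compute_daily_intake([("A", 150.0)], tiny_frame())
        assert out["starch"] == pytest.approx(45.0)

    def test_empty_day_all_zero(self):
        out = ip.compute_daily_intake([], tiny_frame())
        assert (out == 0.0).all()

    def test_additivity_across_items(self):
        out = ip.compute_daily_intake([("A", 100.0), ("B", 200.0)], tiny_frame())
        assert out["sucrose"] == pytest.approx(10.0)

    def test_unknown_code(self):
        with pytest.raises(UnknownFoodError, match="ZZZ"):
            ip.compute_daily_intake([("ZZZ", 10.0)], tiny_frame())

    def test_person_day_matches_scalar_path(self):
        records = pd.DataFrame(
            {
                "person_id": ["p1", "p1", "p1"],
                "day": [1, 1, 2],
                "food_code": ["A", "B", "B"],
                "amount_g": [100.0, 200.0, 50.0],
            }
        )
        table = ip.person_day_intakes(records, tiny_frame())
        day1 = ip.compute_daily_intake([("A", 100.0), ("B", 200.0)], tiny_frame())
        for col in table.columns:
            assert table.loc[("p1", 1), col] == pytest.approx(day1[col])

    def test_day_averaging_equals_mean_of_daily_vectors(self):
        records = pd.DataFrame(
            {
                "person_id": ["p1"] * 2,
                "day": [1, 2],
                "food_code": ["A", "A"],
                "amount_g": [100.0, 300.0],
            }
        )
        days = ip.person_day_intakes(records, tiny_frame())
        means = ip.person_mean_intakes(days)
        assert means.loc["p1", "starch"] == pytest.approx((30.0 + 90.0) / 2)


class TestPercentEnergy:
    def test_ten_percent(self):
        assert ip.percent_energy(50.0, 2000.0) == pytest.approx(10.0)

    def test_zero_grams(self):
        assert ip.percent_energy(0.0, 1500.0) == 0.0

    def test_quarter(self):
        assert ip.percent_energy(100.0, 1600.0) == pytest.approx(25.0)

    def test_non_positive_energy_raises(self):
        with pytest.raises(InvariantError):
            ip.percent_energy(10.0, 0.0)


class TestEiEer:
    def test_unity(self):
        assert ip.ei_eer(2000.0, 2000.0) == pytest.approx(1.0)

    def test_overreporting_magnitude(self):
        assert ip.ei_eer(1220.0, 1000.0) == pytest.approx(1.22)

    def test_zero_intake(self):
        assert ip.ei_eer(0.0, 1800.0) == 0.0

    def test_bad_eer(self):
        with pytest.raises(InvariantError):
            ip.ei_eer(2000.0, 0.0)


class TestWhoAdherence:
    def test_mixed_group(self):
        out = ip.who_adherence([4.0, 6.0, 11.0])
        assert out[10.0] == 33.3
        assert out[5.0] == 66.7

    def test_strict_boundary_below(self):
        out = ip.who_adherence([4.9, 4.9, 4.9])
        assert out[10.0] == 0.0 and out[5.0] == 0.0

    def test_closed_threshold_at_ten(self):
        out = ip.who_adherence([10.0])
        assert out[10.0] == 100.0

    def test_empty_group(self):
        with pytest.raises(EmptySetError):
            ip.who_adherence([])


class TestCompareSexes:
    def test_identical_groups(self):
        t, p = ip.compare_sexes([1.0, 1.0, 1.0], [1.0, 1.0, 1.0], "mean")
        assert t == 0.0 and p == 1.0

    def test_flat_2x2(self):
        chi2, p = ip.compare_sexes((50, 50), (50, 50), "prevalence")
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        # pooled variance s2 = 1, se = sqrt(2/3), t = -3/se, df = 4
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        expected_t = -3.0 / math.sqrt(2.0 / 3.0)
        expected_p = 2.0 * stats.t.sf(abs(expected_t), df=4)
        t, p = ip.compare_sexes(a, b, "mean")
        assert t == pytest.approx(expected_t, abs=1e-3)
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(expected_p, rel=1e-9)
        assert p == pytest.approx(0.0214, abs=5e-4)

    def test_chi_square_without_continuity_correction(self):
        # hand calculation: chi2 = N(ad-bc)^2 / (row/col products)
        a, b, c, d = 30.0, 10.0, 20.0, 20.0
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        chi2, _ = ip.compare_sexes((a, b), (c, d), "prevalence")
        assert chi2 == pytest.approx(expected, rel=1e-12)

    def test_direction_agrees_with_permutation_test(self):
        rng = np.random.default_rng(5)
        a = rng.normal(10.0, 1.0, size=12)
        b = rng.normal(11.0, 1.0, size=12)
        t, p = ip.compare_sexes(a, b, "mean")
        # brute-force permutation distribution of the mean difference
        pooled = np.concatenate([a, b])
        observed = a.mean() - b.mean()
        count = 0
        n_perm = 2000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            diff = pooled[:12].mean() - pooled[12:].mean()
            if abs(diff) >= abs(observed):
                count += 1
        p_perm = count / n_perm
        assert (t < 0) == (observed < 0)
        assert (p < 0.05) == (p_perm < 0.05)


class TestContributions:
    def test_single_person_single_group(self):
        records = pd.DataFrame(
            {"person_id": ["p1"], "day": [1], "food_code": ["A"], "amount_g": [100.0]}
        )
        shares = ip.contribution_by_group(records, tiny_frame(), "starch")
        assert shares["rice and grains"] == pytest.approx(100.0)

    def test_mean_of_ratios_not_ratio_of_means(self):
        # person 1 eats only A (big), person 2 only B (small): mean of the
        # per-person shares must be 50/50 regardless of amounts
        records = pd.DataFrame(
            {
                "person_id": ["p1", "p2"],
                "day": [1, 1],
                "food_code": ["A", "B"],
                "amount_g": [1000.0, 10.0],
            }
        )
        shares = ip.contribution_by_group(records, tiny_frame(), "total_sugar")
        assert shares["rice and grains"] == pytest.approx(50.0)
        assert shares["fruits"] == pytest.approx(50.0)

    def test_population_ratio_alternative(self):
        records = pd.DataFrame(
            {
                "person_id": ["p1", "p2"],
                "day": [1, 1],
                "food_code": ["A", "B"],
                "amount_g": [100.0, 100.0],
            }
        )
        shares = ip.contribution_by_group(
            records, tiny_frame(), "total_sugar", method="population_ratio"
        )
        assert shares["rice and grains"] == pytest.approx(100.0 * 5.0 / 9.0)

    def test_rows_sum_to_100(self, classified_table):
        from starchsugar.synthetic_data import GeneratorConfig, generate_dietary_records

        cfg = GeneratorConfig(
            seed=9, n_items=200,
            n_persons={"adult": 10, "schoolchild": 10},
        )
        persons, records, _ = generate_dietary_records(cfg, classified_table.db)
        frame = ip.nutrient_frame(classified_table.db)
        for nutrient in ("starch", "total_sugar", "free_sugar"):
            shares = ip.contribution_by_group(records, frame, nutrient)
            assert shares.sum() == pytest.approx(100.0, abs=1e-9)

    def test_zero_population_raises(self):
        records = pd.DataFrame(
            {"person_id": ["p1"], "day": [1], "food_code": ["A"], "amount_g": [0.0]}
        )
        with pytest.raises(EmptySetError):
            ip.contribution_by_group(records, tiny_frame(), "starch")

    def test_collapse_minor_groups(self):
        table = pd.DataFrame(
            {"toddler": [60.0, 35.0, 3.0, 2.0], "adult": [55.0, 38.0, 4.0, 3.0]},
            index=["rice", "veg", "tiny1", "tiny2"],
        )
        out = ip.collapse_minor_groups(table, threshold=7.0)
        assert "others" in out.index
        assert out.loc["others", "toddler"] == pytest.approx(5.0)
        assert out["adult"].sum() == pytest.approx(100.0)


class TestConservationOnSyntheticTable:
    def test_total_equals_component_sum_and_split(self, classified_table):
        from starchsugar.synthetic_data import GeneratorConfig, generate_dietary_records

        cfg = GeneratorConfig(seed=13, n_items=200,
                              n_persons={"adult": 6, "preschool": 6})
        persons, records, _ = generate_dietary_records(cfg, classified_table.db)
        frame = ip.nutrient_frame(classified_table.db)
        days = ip.person_day_intakes(records, frame)
        component_sum = days[list(ip.SACCHARIDES_COLUMNS)].sum(axis=1)
        assert np.allclose(component_sum, days["total_sugar"], atol=1e-9)
        assert np.allclose(
            days["free_sugar"] + days["naturally_occurring_sugar"],
            days["total_sugar"],
            atol=1e-9,
        )
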