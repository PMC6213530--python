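import copy

import pytest

from starchsugar import value_assignment as va
from starchsugar.composition_model import (
    MISSING,
    SACCHARIDES,
    SaccharideProfile,
)
from starchsugar.errors import CycleError, DivisionError, EmptySetError
from starchsugar.synthetic_data import (
    GeneratorConfig,
    generate_composition_table,
    labelled_provenance_db,
)
from starchsugar.value_assignment import (
    AssignmentSource,
    LiteratureValueSet,
    OverseasEntry,
    Recipe,
    SimilarityLink,
    aggregate_representative,
    compute_from_recipe,
    convert_overseas,
    provenance_summary,
    scale_to_form,
)

from conftest import make_item


class TestAggregateRepresentative:
    def test_mean(self):
        assert aggregate_representative([1, 2, 3], "mean") == pytest.approx(2.0)

    def test_median(self):
        assert aggregate_representative([1, 2, 10], "median") == pytest.approx(2.0)

    @pytest.mark.parametrize("method", ["mean", "median"])
    def test_singleton(self, method):
        assert aggregate_representative([4.2], method) == pytest.approx(4.2)

    def test_empty_raises(self):
        with pytest.raises(EmptySetError):
            aggregate_representative([], "mean")


class TestScaleToForm:
    def test_formula(self):
        assert scale_to_form(4.0, 10.0, 20.0) == pytest.approx(8.0)

    def test_identity_when_equal_dry_weights(self):
        assert scale_to_form(7.0, 33.0, 33.0) == pytest.approx(7.0)

    def test_zero_value(self):
        assert scale_to_form(0.0, 10.0, 55.0) == 0.0

    def test_zero_reference_dry_weight_raises(self):
        with pytest.raises(DivisionError):
            scale_to_form(4.0, 0.0, 20.0)


class TestConvertOverseas:
    def test_uk_disaccharide_converted(self):
        entry = OverseasEntry("X", "UK", {"sucrose": 10.0}, True)
        assert convert_overseas(entry).sucrose == pytest.approx(9.5)

    def test_us_disaccharide_unchanged(self):
        entry = OverseasEntry("X", "US", {"sucrose": 10.0}, False)
        assert convert_overseas(entry).sucrose == pytest.approx(10.0)

    def test_uk_monosaccharide_unchanged(self):
        entry = OverseasEntry("X", "UK", {"glucose": 10.0}, True)
        assert convert_overseas(entry).glucose == pytest.approx(10.0)

    def test_unreported_components_are_zero(self):
        profile = convert_overseas(OverseasEntry("X", "AU", {"lactose": 3.0}, False))
        assert profile.is_complete()
        assert profile.glucose == 0.0


class TestComputeFromRecipe:
    def _db_with(self, contents):
        db = {}
        for code, sucrose in contents.items():
            p = SaccharideProfile.zero()
            p.sucrose = sucrose
            db[code] = make_item(code=code, saccharides=p)
        return db

    def test_single_ingredient_identity(self):
        db = self._db_with({"A": 10.0})
        recipe = Recipe("P", [("A", 100.0)], 100.0)
        assert compute_from_recipe(recipe, db)["sucrose"] == pytest.approx(10.0)

    def test_mixture(self):
        db = self._db_with({"A": 10.0, "B": 0.0})
        recipe = Recipe("P", [("A", 50.0), ("B", 50.0)], 100.0)
        assert compute_from_recipe(recipe, db)["sucrose"] == pytest.approx(5.0)

    def test_concentration_by_yield(self):
        db = self._db_with({"A": 10.0})
        recipe = Recipe("P", [("A", 100.0)], 50.0)
        assert compute_from_recipe(recipe, db)["sucrose"] == pytest.approx(20.0)

    def test_self_reference_rejected(self):
        with pytest.raises(CycleError):
            Recipe("P", [("P", 100.0)], 100.0)

    def test_cycle_detection(self):
        recipes = [
            Recipe("A", [("B", 50.0)], 50.0),
            Recipe("B", [("C", 50.0)], 50.0),
            Recipe("C", [("A", 50.0)], 50.0),
        ]
        with pytest.raises(CycleError):
            va.check_recipes_acyclic(recipes)


class TestCascade:
    def test_analytical_item_unchanged(self, assigned_table):
        truth = assigned_table.truth
        for code, sources in truth.sources.items():
            if sources["saccharides"] == "STFCJ_ANALYTICAL":
                item = assigned_table.db[code]
                assert item.provenance["saccharides"] == AssignmentSource.STFCJ_ANALYTICAL
                for comp in SACCHARIDES:
                    assert getattr(item.saccharides, comp) == pytest.approx(
                        truth.contents[code][comp], abs=1e-9
                    )

    def test_zero_carb_items_get_zero_profile(self, assigned_table):
        for code, sources in assigned_table.truth.sources.items():
            if sources["saccharides"] == "CARB_DIFFERENCE":
                item = assigned_table.db[code]
                assert item.total_sugar == 0.0

    def test_provenance_matches_generator_ground_truth(self, assigned_table):
        """Construction oracle: the generator records every true source."""
        for code, sources in assigned_table.truth.sources.items():
            item = assigned_table.db[code]
            assert item.provenance["saccharides"].value == sources["saccharides"], code
            assert item.provenance["starch"].value == sources["starch"], code

    def test_formula_recovery_exact(self, assigned_table):
        """Masked items resolvable by exact formulas reproduce truth to 1e-9."""
        for code, truth in assigned_table.truth.contents.items():
            item = assigned_table.db[code]
            for comp in SACCHARIDES:
                assert getattr(item.saccharides, comp) == pytest.approx(
                    truth[comp], abs=1e-9
                ), (code, comp)
            assert item.starch == pytest.approx(truth["starch"], abs=1e-9), code

    def test_deterministic(self):
        def build():
            t = generate_composition_table(GeneratorConfig(seed=11, n_items=120))
            va.assign_saccharides(t.db, t.literature, t.links, t.recipes, t.overseas)
            va.assign_starch(t.db, t.literature, t.links, t.recipes, t.overseas)
            return {
                code: (item.saccharides.components(), item.starch,
                       item.provenance["saccharides"].value)
                for code, item in t.db.items()
            }

        assert build() == build()

    def test_step_monotonicity_no_overwrite(self, small_table):
        """An item resolved at an earlier step keeps its value afterwards."""
        table = copy.deepcopy(small_table)
        snapshots = {}

        # run with a truncated cascade, then with the full one
        short = va.AssignmentConfig(cascade=("analytical", "zero_carb", "literature"))
        va.assign_saccharides(
            table.db, table.literature, table.links, table.recipes,
            table.overseas, short,
        )
        for code, item in table.db.items():
            if item.saccharides.is_complete():
                snapshots[code] = (item.saccharides.components(),
                                   item.provenance.get("saccharides"))
        va.assign_saccharides(
            table.db, table.literature, table.links, table.recipes, table.overseas
        )
        for code, (components, prov) in snapshots.items():
            assert table.db[code].saccharides.components() == components
            assert table.db[code].provenance["saccharides"] == prov

    def test_unresolvable_items_reported_not_silent(self):
        db = {"LONE": make_item(code="LONE", water=50.0)}
        result = va.assign_saccharides(db)
        assert [c for c, _ in result.exceptions] == ["LONE"]
        assert db["LONE"].provenance["saccharides"] == AssignmentSource.ZERO_FALLBACK
        assert db["LONE"].total_sugar == 0.0

    def test_starch_by_subtraction(self):
        p = SaccharideProfile.zero()
        p.sucrose = 10.0
        # available carbohydrate = 100 - 30 - 5 - 2 - 1 - 12 = 50
        item = make_item(code="S1", water=30, protein=5, lipid=2, ash=1,
                         fiber=12, saccharides=p)
        db = {"S1": item}
        va.assign_starch(db)
        assert item.starch == pytest.approx(40.0)
        assert item.provenance["starch"] == AssignmentSource.CARB_DIFFERENCE

    def test_starch_subtraction_clamped(self):
        p = SaccharideProfile.zero()
        p.sucrose = 8.0
        # available carbohydrate = 5
        item = make_item(code="S2", water=90, protein=2, lipid=1, ash=1,
                         fiber=1, saccharides=p)
        db = {"S2": item}
        va.assign_starch(db)
        assert db["S2"].starch == 0.0

    def test_analytical_starch_kept(self):
        p = SaccharideProfile.zero()
        item = make_item(code="S3", water=30, protein=5, lipid=2, ash=1,
                         fiber=2, saccharides=p, starch=30.0)
        db = {"S3": item}
        va.assign_starch(db)
        assert db["S3"].starch == pytest.approx(30.0)
        assert db["S3"].provenance["starch"] == AssignmentSource.STFCJ_ANALYTICAL

    def test_overseas_priority_us_over_uk(self):
        item = make_item(code="O1", water=50, protein=2, lipid=1, ash=1, fiber=1)
        db = {"O1": item}
        overseas = [
            OverseasEntry("O1", "UK", {"sucrose": 20.0}, True),
            OverseasEntry("O1", "US", {"sucrose": 10.0}, False),
        ]
        va.assign_saccharides(db, overseas=overseas)
        assert item.saccharides.sucrose == pytest.approx(10.0)

    def test_component_capped_at_available_carbohydrate(self):
        # available carbohydrate = 5; literature reports 50
        item = make_item(code="C1", water=90, protein=2, lipid=1, ash=1, fiber=1)
        db = {"C1": item}
        lit = [LiteratureValueSet("C1", {"sucrose": [50.0]})]
        va.assign_saccharides(db, literature=lit)
        assert item.saccharides.sucrose == pytest.approx(5.0)

    def test_zero_dry_weight_reference_skipped_not_fatal(self):
        ref = make_item(code="R", water=100.0, saccharides=SaccharideProfile.zero())
        target = make_item(code="T", water=50.0)
        db = {"R": ref, "T": target}
        links = [SimilarityLink("T", "R", "similar_food")]
        result = va.assign_saccharides(db, links=links)
        # target falls through to the zero fallback instead of crashing
        assert db["T"].provenance["saccharides"] == AssignmentSource.ZERO_FALLBACK
        assert ("T", result.exceptions[0][1]) == result.exceptions[0]


class TestProvenanceSummary:
    def test_paper_count_fixture_info_share(self):
        db = labelled_provenance_db(
            {AssignmentSource.STFCJ_ANALYTICAL: 880}, n_total=2222
        )
        summary = provenance_summary(db)
        assert summary["STFCJ_ANALYTICAL"]["count"] == 880
        assert summary["STFCJ_ANALYTICAL"]["pct"] == 39.6
        assert summary["UNASSIGNED"]["count"] == 1342

    def test_paper_count_fixture_analytical_share(self):
        db = labelled_provenance_db(
            {
                AssignmentSource.STFCJ_ANALYTICAL: 396,
                AssignmentSource.SIMILAR_FOOD: 187,
                AssignmentSource.RECIPE: 144,
                AssignmentSource.OVERSEAS_DB: 153,
            },
            n_total=2222,
        )
        info = [c for c, item in db.items() if item.provenance.get("saccharides")]
        assert len(info) == 880
        summary = provenance_summary(db, denominator_codes=info)
        assert summary["STFCJ_ANALYTICAL"]["pct"] == 45.0
        assert summary["SIMILAR_FOOD"]["pct"] == 21.3
        assert summary["RECIPE"]["pct"] == 16.4
        assert summary["OVERSEAS_DB"]["pct"] == 17.4

    def test_counts_partition_table(self, assigned_table):
        summary = provenance_summary(assigned_table.db)
        assert sum(v["count"] for v in summary.values()) == len(assigned_table.db)

    def test_single_item_db(self):
        db = labelled_provenance_db({AssignmentSource.RECIPE: 1})
        assert provenance_summary(db)["RECIPE"]["pct"] == 100.0

    def test_round_half_up(self):
        assert va.round_half_up(21.25, 1) == 21.3
        assert va.round_half_up(21.24, 1) == 21.2
        assert va.round_half_up(-1.25, 1) == -1.3
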