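import logging

import pytest

from starchsugar import free_sugar_classifier as fsc
from starchsugar import value_assignment as va
from starchsugar.composition_model import FoodItem, Form, SaccharideProfile
from starchsugar.synthetic_data import GeneratorConfig, generate_composition_table

logging.getLogger("starchsugar").setLevel(logging.ERROR)


def make_item(code="X001", group="vegetables", form=Form.RAW, water=80.0,
              protein=2.0, lipid=0.5, ash=1.0, fiber=2.0, energy=60.0,
              saccharides=None, starch=None, name=None):
    item = FoodItem(
        code=code,
        name=name or f"{group} item {code}",
        food_group=group,
        form=form,
        water=water,
        protein=protein,
        lipid=lipid,
        ash=ash,
        dietary_fiber=fiber,
        energy=energy,
    )
    if saccharides is not None:
        item.saccharides = saccharides
    if starch is not None:
        item.starch = starch
    return item


@pytest.fixture(scope="session")
def small_table():
    """A 200-item synthetic table with auxiliary sources and ground truth."""
    return generate_composition_table(GeneratorConfig(seed=7, n_items=200))


@pytest.fixture()
def assigned_table():
    """Fresh 200-item table with both cascades already run."""
    table = generate_composition_table(GeneratorConfig(seed=7, n_items=200))
    va.assign_saccharides(
        table.db, table.literature, table.links, table.recipes, table.overseas
    )
    va.assign_starch(
        table.db, table.literature, table.links, table.recipes, table.overseas
    )
    return table


@pytest.fixture()
def classified_table(assigned_table):
    fsc.classify_db(assigned_table.db, fsc.default_rules(), assigned_table.recipes)
    return assigned_table
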