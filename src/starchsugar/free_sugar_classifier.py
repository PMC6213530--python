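"""Split each item's total sugar into free vs. naturally occurring sugar.

Free sugar follows the WHO definition: mono-/disaccharides added by the
manufacturer, cook or consumer, plus sugars naturally present in honey,
syrups, fruit juices and fruit-juice concentrate.  The split is decided by
an ordered rule list (first match wins); the rule tree is data, not code,
and ships as a YAML default that callers may replace.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Optional, Sequence

import yaml

from .composition_model import MISSING, CompositionDB, FoodItem
from .errors import DependencyError, InvariantError
from .value_assignment import Recipe

logger = logging.getLogger(__name__)


class RuleOutcome(str, Enum):
    NONE_FREE = "NONE_FREE"
    ALL_FREE = "ALL_FREE"
    FRACTION = "FRACTION"
    FROM_RECIPE = "FROM_RECIPE"


@dataclass
class FreeSugarRule:
    """One ordered classification rule.

    Predicates are conjunctive and evaluated food group first, then form,
    then name pattern; empty predicate fields match anything.
    """

    ordinal: int
    outcome: RuleOutcome
    groups: Optional[list[str]] = None
    forms: Optional[list[str]] = None
    name_regex: Optional[str] = None
    fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.outcome == RuleOutcome.FRACTION:
            if self.fraction is None or not 0.0 <= self.fraction <= 1.0:
                raise InvariantError(
                    f"rule {self.ordinal}: FRACTION requires 0 <= p <= 1"
                )

    def matches(self, item: FoodItem) -> bool:
        if self.groups is not None and item.food_group not in self.groups:
            return False
        if self.forms is not None and item.form.value not in self.forms:
            return False
        if self.name_regex is not None and not re.search(
            self.name_regex, item.name, flags=re.IGNORECASE
        ):
            return False
        return True


@dataclass
class SugarSplit:
    """Free/naturally-occurring split of one item's total sugar."""

    free_sugar: float
    naturally_occurring: float
    rule_id: Optional[int]

    def __post_init__(self) -> None:
        if self.free_sugar < -1e-12 or self.naturally_occurring < -1e-12:
            raise InvariantError("sugar split components must be non-negative")


#: Unmatched items fall to this fraction (flagged for review); mirrors the
#: 50% convention of published stepwise added-sugar methods.
DEFAULT_FALLBACK_FRACTION = 0.5


def naturally_occurring(total: float, free: float) -> float:
    """Total sugar minus free sugar."""
    if free < 0 or total < 0:
        raise InvariantError("sugar contents must be non-negative")
    if free > total + 1e-12:
        raise InvariantError(f"free sugar {free} exceeds total sugar {total}")
    return total - free


def classify_free_sugar(
    item: FoodItem,
    rules: Sequence[FreeSugarRule],
    db: Optional[CompositionDB] = None,
    recipes: Optional[dict[str, Recipe]] = None,
    fallback_fraction: float = DEFAULT_FALLBACK_FRACTION,
) -> SugarSplit:
    """Apply the first matching rule; conservation free + natural = total
    holds exactly for every outcome."""
    total = item.total_sugar
    if total is MISSING:
        raise InvariantError(f"item {item.code!r}: total sugar not assigned")
    for rule in sorted(rules, key=lambda r: r.ordinal):
        if not rule.matches(item):
            continue
        if rule.outcome == RuleOutcome.NONE_FREE:
            free = 0.0
        elif rule.outcome == RuleOutcome.ALL_FREE:
            free = total
        elif rule.outcome == RuleOutcome.FRACTION:
            free = rule.fraction * total
        else:  # FROM_RECIPE
            if not recipes or item.code not in recipes:
                continue  # no recipe on file: defer to later rules / fallback
            free = _free_from_recipe(item, db, recipes)
            free = min(free, total)  # conservation cap
        return SugarSplit(free, total - free, rule.ordinal)
    logger.warning(
        "item %r matched no free-sugar rule; fallback fraction %.2f applied",
        item.code,
        fallback_fraction,
    )
    free = fallback_fraction * total
    return SugarSplit(free, total - free, None)


def _free_from_recipe(
    item: FoodItem,
    db: Optional[CompositionDB],
    recipes: Optional[dict[str, Recipe]],
) -> float:
    if db is None:
        raise DependencyError(
            f"item {item.code!r}: FROM_RECIPE requires the database"
        )
    recipe = recipes[item.code]
    total = 0.0
    for code, weight in recipe.ingredients:
        if code not in db or db[code].free_sugar is MISSING:
            raise DependencyError(
                f"item {item.code!r}: ingredient {code!r} has no free sugar yet"
            )
        total += db[code].free_sugar * weight / 100.0
    return total * 100.0 / recipe.yield_g


def classify_db(
    db: CompositionDB,
    rules: Sequence[FreeSugarRule],
    recipes: Sequence[Recipe] = (),
    fallback_fraction: float = DEFAULT_FALLBACK_FRACTION,
) -> dict[str, SugarSplit]:
    """Classify every item; FROM_RECIPE items resolve once their
    ingredients have splits (fixpoint sweep over the database)."""
    recipe_map = {r.product: r for r in recipes}
    splits: dict[str, SugarSplit] = {}
    pending = list(db)
    while pending:
        progress = False
        still: list[str] = []
        for code in pending:
            try:
                split = classify_free_sugar(
                    db[code], rules, db, recipe_map, fallback_fraction
                )
            except DependencyError:
                still.append(code)
                continue
            item = db[code]
            item.free_sugar = split.free_sugar
            item.naturally_occurring_sugar = split.naturally_occurring
            splits[code] = split
            progress = True
        if not progress and still:
            raise DependencyError(
                f"unresolvable FROM_RECIPE items: {sorted(still)[:5]}"
            )
        pending = still
    return splits


def load_rules(path) -> list[FreeSugarRule]:
    """Load an ordered rule list from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return parse_rules(raw)


def parse_rules(raw: list[dict]) -> list[FreeSugarRule]:
    rules = []
    for entry in raw:
        match = entry.get("match", {}) or {}
        rules.append(
            FreeSugarRule(
                ordinal=int(entry["ordinal"]),
                outcome=RuleOutcome(entry["outcome"]),
                groups=match.get("groups"),
                forms=match.get("forms"),
                name_regex=match.get("name_regex"),
                fraction=entry.get("fraction"),
            )
        )
    ordinals = [r.ordinal for r in rules]
    if len(set(ordinals)) != len(ordinals):
        raise InvariantError("rule ordinals must be unique (total order)")
    return sorted(rules, key=lambda r: r.ordinal)


def default_rules() -> list[FreeSugarRule]:
    """The rule set shipped with the package (``data/free_sugar_rules.yaml``)."""
    text = (
        resources.files("starchsugar").joinpath("data/free_sugar_rules.yaml").read_text()
    )
    return parse_rules(yaml.safe_load(text))
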