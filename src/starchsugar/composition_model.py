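"""Core domain types and deterministic nutrient arithmetic.

All contents are expressed per 100 g edible portion.  ``None`` is the
explicit MISSING sentinel throughout: 0.0 always means a measured or
assigned value of zero, never absence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional

from .errors import IncompleteProfileError, InvariantError, MissingDataError

logger = logging.getLogger(__name__)

#: The explicit sentinel for an absent value (distinct from 0).
MISSING = None

#: Component names of the saccharide profile, in canonical column order.
SACCHARIDES: tuple[str, ...] = (
    "glucose",
    "fructose",
    "galactose",
    "sucrose",
    "maltose",
    "lactose",
    "trehalose",
)

#: Disaccharides, subject to the monosaccharide-equivalent conversion.
DISACCHARIDES: tuple[str, ...] = ("sucrose", "maltose", "lactose", "trehalose")

#: Proximate fields required for carbohydrate-by-difference.
PROXIMATES: tuple[str, ...] = ("water", "protein", "lipid", "ash")

#: Tolerance allowed for starch + total sugar exceeding available
#: carbohydrate (typical table rounding); violations are logged, not fatal.
CARB_TOLERANCE = 0.5


class Form(str, Enum):
    """Physical form of a food item as listed in the composition table."""

    RAW = "raw"
    COOKED = "cooked"
    PROCESSED = "processed"


@dataclass
class SaccharideProfile:
    """The seven mono-/disaccharides in g/100 g edible portion.

    Each component is a non-negative float or ``None`` (MISSING).
    """

    glucose: Optional[float] = MISSING
    fructose: Optional[float] = MISSING
    galactose: Optional[float] = MISSING
    sucrose: Optional[float] = MISSING
    maltose: Optional[float] = MISSING
    lactose: Optional[float] = MISSING
    trehalose: Optional[float] = MISSING

    def __post_init__(self) -> None:
        for name in SACCHARIDES:
            value = getattr(self, name)
            if value is MISSING:
                continue
            if not 0.0 <= value <= 100.0:
                raise InvariantError(
                    f"saccharide {name!r} = {value} outside [0, 100] g/100 g"
                )

    @classmethod
    def zero(cls) -> "SaccharideProfile":
        return cls(**{name: 0.0 for name in SACCHARIDES})

    def is_complete(self) -> bool:
        return all(getattr(self, name) is not MISSING for name in SACCHARIDES)

    def components(self) -> dict[str, Optional[float]]:
        return {name: getattr(self, name) for name in SACCHARIDES}

    def copy(self) -> "SaccharideProfile":
        return replace(self)


@dataclass
class FoodItem:
    """One composition-table row: proximates plus the saccharide/starch block.

    ``free_sugar`` and ``naturally_occurring_sugar`` stay MISSING until the
    free-sugar classifier runs; ``provenance`` records one
    :class:`~starchsugar.value_assignment.AssignmentSource` per nutrient
    family ("saccharides" and "starch").
    """

    code: str
    name: str
    food_group: str
    form: Form = Form.RAW
    water: Optional[float] = MISSING
    protein: Optional[float] = MISSING
    lipid: Optional[float] = MISSING
    ash: Optional[float] = MISSING
    dietary_fiber: Optional[float] = MISSING
    energy: Optional[float] = MISSING
    saccharides: SaccharideProfile = field(default_factory=SaccharideProfile)
    starch: Optional[float] = MISSING
    free_sugar: Optional[float] = MISSING
    naturally_occurring_sugar: Optional[float] = MISSING
    provenance: dict = field(default_factory=dict)

    @property
    def total_sugar(self) -> Optional[float]:
        """Sum of the seven saccharides, or MISSING if incomplete."""
        if not self.saccharides.is_complete():
            return MISSING
        return total_sugar(self.saccharides)

    def validate(self) -> list[str]:
        """Check soft invariants; returns (and logs) a list of violations."""
        problems: list[str] = []
        if all(getattr(self, p) is not MISSING for p in PROXIMATES):
            s = sum(getattr(self, p) for p in PROXIMATES)
            if s > 100.0 + 1e-9:
                problems.append(f"{self.code}: proximates sum {s:.4f} > 100")
        ts = self.total_sugar
        if ts is not MISSING and self.starch is not MISSING:
            try:
                avail = available_carbohydrate(self)
            except MissingDataError:
                avail = MISSING
            if avail is not MISSING and self.starch + ts > avail + CARB_TOLERANCE:
                problems.append(
                    f"{self.code}: starch {self.starch:.3f} + total sugar "
                    f"{ts:.3f} exceeds available carbohydrate {avail:.3f} "
                    f"by more than {CARB_TOLERANCE}"
                )
        if (
            self.free_sugar is not MISSING
            and ts is not MISSING
            and not -1e-9 <= self.free_sugar <= ts + 1e-9
        ):
            problems.append(
                f"{self.code}: free sugar {self.free_sugar} outside [0, total sugar]"
            )
        for msg in problems:
            logger.warning(msg)
        return problems


@dataclass
class FoodGroup:
    """A named food group and the item codes that belong to it."""

    name: str
    members: list[str] = field(default_factory=list)
    is_sugar_sweetened_beverage: bool = False
    is_fruit_juice: bool = False


#: The 24 default food groups (culinary-usage classification).
FOOD_GROUP_NAMES: tuple[str, ...] = (
    "rice and grains",
    "other grain products",
    "bread",
    "noodle",
    "potatoes",
    "sugars and jams",
    "pulses and nuts",
    "vegetables",
    "fruits",
    "fruit juices",
    "vegetable juices",
    "mushrooms",
    "seaweeds",
    "fish and shellfish",
    "meats",
    "eggs",
    "dairy products",
    "fat and oil",
    "confectionaries",
    "sugar-sweetened beverages",
    "alcoholic beverages",
    "tea and coffee",
    "seasonings",
    "other foods",
)


def default_food_groups() -> list[FoodGroup]:
    groups = []
    for name in FOOD_GROUP_NAMES:
        groups.append(
            FoodGroup(
                name=name,
                is_sugar_sweetened_beverage=(name == "sugar-sweetened beverages"),
                is_fruit_juice=(name == "fruit juices"),
            )
        )
    return groups


def check_group_partition(groups: Iterable[FoodGroup], codes: Iterable[str]) -> None:
    """Verify that the groups partition the codes (each code exactly once)."""
    seen: dict[str, str] = {}
    for g in groups:
        for code in g.members:
            if code in seen:
                raise InvariantError(
                    f"code {code!r} in both {seen[code]!r} and {g.name!r}"
                )
            seen[code] = g.name
    missing = set(codes) - set(seen)
    if missing:
        raise InvariantError(f"codes not in any group: {sorted(missing)[:5]} ...")


def available_carbohydrate(item: FoodItem) -> float:
    """Carbohydrate by difference minus dietary fiber, clamped at 0.

    ``max(0, (100 - water - protein - lipid - ash) - dietary_fiber)``;
    negatives (rounding artefacts in proximates) are clamped with a warning.
    """
    for name in (*PROXIMATES, "dietary_fiber"):
        if getattr(item, name) is MISSING:
            raise MissingDataError(
                f"item {item.code!r}: proximate {name!r} is MISSING"
            )
    carb = 100.0 - item.water - item.protein - item.lipid - item.ash
    avail = carb - item.dietary_fiber
    if avail < 0.0:
        if avail < -1e-9:  # genuine rounding artefact worth surfacing
            logger.warning(
                "item %r: available carbohydrate %.4f clamped to 0", item.code, avail
            )
        return 0.0
    return avail


def total_sugar(profile: SaccharideProfile) -> float:
    """Arithmetic sum of the seven mono- and disaccharides."""
    values = profile.components()
    missing = [k for k, v in values.items() if v is MISSING]
    if missing:
        raise IncompleteProfileError(f"MISSING component(s): {missing}")
    return float(sum(values.values()))


def dry_weight(item: FoodItem) -> float:
    """100 minus water content, g/100 g."""
    if item.water is MISSING:
        raise MissingDataError(f"item {item.code!r}: water is MISSING")
    if item.water > 100.0:
        raise InvariantError(f"item {item.code!r}: water {item.water} > 100")
    return 100.0 - item.water


#: A composition database: insertion-ordered mapping of code -> FoodItem.
CompositionDB = dict[str, FoodItem]
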