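"""Stepwise value assignment for saccharides and starch.

Items lacking analytical values are filled by a fixed-order cascade:
analytical table values, zero-assignment where available carbohydrate is
zero, literature values, same-food-other-form scaling, similar-food
scaling, recipe calculation, overseas-table conversion, and finally a
zero fallback recorded in an exceptions list.  Every assigned value
carries exactly one :class:`AssignmentSource`.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .composition_model import (
    DISACCHARIDES,
    MISSING,
    SACCHARIDES,
    CompositionDB,
    FoodItem,
    SaccharideProfile,
    available_carbohydrate,
    dry_weight,
)
from .errors import (
    CycleError,
    DependencyError,
    DivisionError,
    EmptySetError,
    MissingDataError,
)

logger = logging.getLogger(__name__)

#: Conversion factor from monosaccharide equivalents back to disaccharide mass.
MONOSACCHARIDE_EQUIVALENT_FACTOR = 0.95


class AssignmentSource(str, Enum):
    """Where an assigned nutrient-family value came from."""

    STFCJ_ANALYTICAL = "STFCJ_ANALYTICAL"
    LITERATURE = "LITERATURE"
    SAME_FOOD_OTHER_FORM = "SAME_FOOD_OTHER_FORM"
    SIMILAR_FOOD = "SIMILAR_FOOD"
    RECIPE = "RECIPE"
    OVERSEAS_DB = "OVERSEAS_DB"
    CARB_DIFFERENCE = "CARB_DIFFERENCE"
    ZERO_FALLBACK = "ZERO_FALLBACK"


@dataclass
class LiteratureValueSet:
    """Reported literature values for one food, per component."""

    code: str
    values: dict[str, list[float]]  # component -> reported values
    method: str = "median"  # "mean" | "median"

    def __post_init__(self) -> None:
        for comp, vals in self.values.items():
            if not vals:
                raise EmptySetError(
                    f"literature set for {self.code!r}/{comp!r} is empty"
                )


@dataclass
class OverseasEntry:
    """One food's values borrowed from a foreign composition table."""

    code: str
    country: str  # "US" | "UK" | "AU"
    values: dict[str, float]  # component (saccharide or "starch") -> g/100 g
    monosaccharide_equivalent: bool = False


@dataclass
class Recipe:
    """Ingredient list and cooked yield for one composite product."""

    product: str
    ingredients: list[tuple[str, float]]  # (ingredient code, raw weight g)
    yield_g: float

    def __post_init__(self) -> None:
        if self.yield_g <= 0:
            raise ValueError(f"recipe {self.product!r}: yield must be > 0")
        for code, w in self.ingredients:
            if w <= 0:
                raise ValueError(
                    f"recipe {self.product!r}: ingredient {code!r} weight must be > 0"
                )
            if code == self.product:
                raise CycleError(f"recipe {self.product!r} references itself")


@dataclass
class SimilarityLink:
    """Target item borrows from reference item via the dry-weight ratio."""

    target: str
    reference: str
    relation: str  # "same_food_other_form" | "similar_food"


#: Default cascade order (analytical > zero-carb > literature > same food >
#: similar food > recipe > overseas); configurable for alternative readings.
DEFAULT_CASCADE = (
    "analytical",
    "zero_carb",
    "literature",
    "same_food_other_form",
    "similar_food",
    "recipe",
    "overseas",
)

#: Country priority when several overseas tables carry the same item.
DEFAULT_OVERSEAS_PRIORITY = ("US", "UK", "AU")


@dataclass
class AssignmentConfig:
    cascade: Sequence[str] = DEFAULT_CASCADE
    aggregation: str = "median"  # default for literature sets without a method
    aggregation_overrides: dict[str, str] = field(default_factory=dict)
    overseas_priority: Sequence[str] = DEFAULT_OVERSEAS_PRIORITY
    cap_at_available_carbohydrate: bool = True


@dataclass
class AssignmentResult:
    """Outcome of a cascade run: the db is modified in place."""

    assigned: dict[str, AssignmentSource]
    exceptions: list[tuple[str, str]] = field(default_factory=list)


def aggregate_representative(
    values: Sequence[float], method: str = "median"
) -> float:
    """Representative value of a literature set (mean or median)."""
    if len(values) == 0:
        raise EmptySetError("no literature values to aggregate")
    if method == "mean":
        return float(statistics.fmean(values))
    if method == "median":
        return float(statistics.median(values))
    raise ValueError(f"unknown aggregation method {method!r}")


def scale_to_form(value_ref: float, dry_ref: float, dry_target: float) -> float:
    """Scale a per-100 g content by the dry-weight ratio target/reference."""
    if dry_ref <= 0:
        raise DivisionError(f"reference dry weight {dry_ref} must be > 0")
    return value_ref * dry_target / dry_ref


def convert_overseas(entry: OverseasEntry) -> SaccharideProfile:
    """Build a profile from an overseas entry, undoing monosaccharide
    equivalents (disaccharides x 0.95) where flagged; unreported components
    are taken as 0."""
    out: dict[str, float] = {}
    for comp in SACCHARIDES:
        value = entry.values.get(comp, 0.0)
        if entry.monosaccharide_equivalent and comp in DISACCHARIDES:
            value *= MONOSACCHARIDE_EQUIVALENT_FACTOR
        out[comp] = value
    return SaccharideProfile(**out)


def compute_from_recipe(
    recipe: Recipe,
    db: CompositionDB,
    components: Sequence[str] = SACCHARIDES,
    getter=None,
) -> dict[str, float]:
    """Per-100 g contents of a recipe product from its ingredients.

    For each component: sum(ingredient content x weight/100) x 100 / yield.
    ``getter(item, component)`` extracts an ingredient's content and may
    return MISSING, which raises :class:`DependencyError`.
    """
    if getter is None:
        getter = lambda item, comp: getattr(item.saccharides, comp)
    totals = {comp: 0.0 for comp in components}
    for code, weight in recipe.ingredients:
        if code not in db:
            raise DependencyError(
                f"recipe {recipe.product!r}: unknown ingredient {code!r}"
            )
        item = db[code]
        for comp in components:
            content = getter(item, comp)
            if content is MISSING:
                raise DependencyError(
                    f"recipe {recipe.product!r}: ingredient {code!r} has no "
                    f"assigned {comp!r}"
                )
            totals[comp] += content * weight / 100.0
    return {comp: g * 100.0 / recipe.yield_g for comp, g in totals.items()}


def check_recipes_acyclic(recipes: Sequence[Recipe]) -> None:
    """Raise :class:`CycleError` if recipe products reference each other
    cyclically (depth-first search over the product->ingredient graph)."""
    graph = {r.product: [c for c, _ in r.ingredients] for r in recipes}
    WHITE, GREY, BLACK = 0, 1, 2
    color = {node: WHITE for node in graph}

    def visit(node: str, path: list[str]) -> None:
        color[node] = GREY
        for child in graph.get(node, ()):
            if child not in graph:
                continue
            if color[child] == GREY:
                raise CycleError(f"recipe cycle: {' -> '.join(path + [child])}")
            if color[child] == WHITE:
                visit(child, path + [child])
        color[node] = BLACK

    for node in graph:
        if color[node] == WHITE:
            visit(node, [node])


def _safe_available_carb(item: FoodItem) -> Optional[float]:
    try:
        return available_carbohydrate(item)
    except MissingDataError:
        return MISSING


def _cap(value: float, ceiling: Optional[float], config: AssignmentConfig) -> float:
    if not config.cap_at_available_carbohydrate or ceiling is MISSING:
        return value
    return min(value, ceiling)


def _literature_by_code(
    literature: Sequence[LiteratureValueSet],
) -> dict[str, LiteratureValueSet]:
    return {ls.code: ls for ls in literature}


def _links_by_target(
    links: Sequence[SimilarityLink], relation: str
) -> dict[str, SimilarityLink]:
    return {l.target: l for l in links if l.relation == relation}


def _overseas_pick(
    entries: Sequence[OverseasEntry], priority: Sequence[str]
) -> dict[str, OverseasEntry]:
    """Pick one entry per code by country priority."""
    rank = {c: i for i, c in enumerate(priority)}
    chosen: dict[str, OverseasEntry] = {}
    for e in entries:
        if e.code not in chosen or rank.get(e.country, math.inf) < rank.get(
            chosen[e.code].country, math.inf
        ):
            chosen[e.code] = e
    return chosen


def _set_profile(
    item: FoodItem,
    values: dict[str, float],
    source: AssignmentSource,
    config: AssignmentConfig,
) -> None:
    ceiling = _safe_available_carb(item)
    capped = {
        comp: _cap(max(0.0, values.get(comp, 0.0)), ceiling, config)
        for comp in SACCHARIDES
    }
    item.saccharides = SaccharideProfile(**capped)
    item.provenance["saccharides"] = source


def assign_saccharides(
    db: CompositionDB,
    literature: Sequence[LiteratureValueSet] = (),
    links: Sequence[SimilarityLink] = (),
    recipes: Sequence[Recipe] = (),
    overseas: Sequence[OverseasEntry] = (),
    config: Optional[AssignmentConfig] = None,
) -> AssignmentResult:
    """Run the saccharide cascade; db is modified in place.

    Items assigned at an earlier step are never overwritten.  Items that no
    step resolves receive an all-zero profile with ZERO_FALLBACK provenance
    and an entry in ``result.exceptions``.
    """
    config = config or AssignmentConfig()
    check_recipes_acyclic(recipes)
    result = AssignmentResult(assigned={})
    lit = _literature_by_code(literature)
    same_links = _links_by_target(links, "same_food_other_form")
    similar_links = _links_by_target(links, "similar_food")
    ovs = _overseas_pick(overseas, config.overseas_priority)
    recipes_by_product = {r.product: r for r in recipes}

    def resolved(code: str) -> bool:
        return code in db and db[code].saccharides.is_complete()

    def mark(code: str, source: AssignmentSource) -> None:
        result.assigned[code] = source

    for step in config.cascade:
        if step == "analytical":
            for code, item in db.items():
                if code in result.assigned:
                    continue
                if item.saccharides.is_complete():
                    item.provenance.setdefault(
                        "saccharides", AssignmentSource.STFCJ_ANALYTICAL
                    )
                    mark(code, item.provenance["saccharides"])
        elif step == "zero_carb":
            for code, item in db.items():
                if code in result.assigned or resolved(code):
                    continue
                avail = _safe_available_carb(item)
                if avail is not MISSING and avail <= 1e-12:
                    item.saccharides = SaccharideProfile.zero()
                    item.provenance["saccharides"] = AssignmentSource.CARB_DIFFERENCE
                    mark(code, AssignmentSource.CARB_DIFFERENCE)
        elif step == "literature":
            for code, item in db.items():
                if code in result.assigned or resolved(code) or code not in lit:
                    continue
                ls = lit[code]
                method = config.aggregation_overrides.get(
                    code, ls.method or config.aggregation
                )
                reported = {
                    comp: aggregate_representative(vals, method)
                    for comp, vals in ls.values.items()
                    if comp in SACCHARIDES
                }
                if not reported:
                    continue
                _set_profile(item, reported, AssignmentSource.LITERATURE, config)
                mark(code, AssignmentSource.LITERATURE)
        elif step in ("same_food_other_form", "similar_food"):
            link_map = same_links if step == "same_food_other_form" else similar_links
            source = (
                AssignmentSource.SAME_FOOD_OTHER_FORM
                if step == "same_food_other_form"
                else AssignmentSource.SIMILAR_FOOD
            )
            progress = True
            while progress:  # chains: reference may itself resolve via a link
                progress = False
                for target, link in link_map.items():
                    if target not in db or target in result.assigned:
                        continue
                    if resolved(target) or not resolved(link.reference):
                        continue
                    ref = db[link.reference]
                    try:
                        dref, dtgt = dry_weight(ref), dry_weight(db[target])
                    except MissingDataError:
                        continue
                    if dref <= 0:
                        continue  # step aborts for this item, try later steps
                    scaled = {
                        comp: scale_to_form(val, dref, dtgt)
                        for comp, val in ref.saccharides.components().items()
                    }
                    _set_profile(db[target], scaled, source, config)
                    mark(target, source)
                    progress = True
        elif step == "recipe":
            progress = True
            while progress:  # nested recipes resolve over multiple sweeps
                progress = False
                for product, recipe in recipes_by_product.items():
                    if product not in db or product in result.assigned:
                        continue
                    if resolved(product):
                        continue
                    if not all(resolved(c) for c, _ in recipe.ingredients):
                        continue
                    values = compute_from_recipe(recipe, db)
                    _set_profile(db[product], values, AssignmentSource.RECIPE, config)
                    mark(product, AssignmentSource.RECIPE)
                    progress = True
        elif step == "overseas":
            for code, item in db.items():
                if code in result.assigned or resolved(code) or code not in ovs:
                    continue
                profile = convert_overseas(ovs[code])
                _set_profile(
                    item, profile.components(), AssignmentSource.OVERSEAS_DB, config
                )
                mark(code, AssignmentSource.OVERSEAS_DB)
        else:
            raise ValueError(f"unknown cascade step {step!r}")

    # capped fallback: zero profile, logged as an exception, never silent
    for code, item in db.items():
        if code not in result.assigned and not resolved(code):
            item.saccharides = SaccharideProfile.zero()
            item.provenance["saccharides"] = AssignmentSource.ZERO_FALLBACK
            result.assigned[code] = AssignmentSource.ZERO_FALLBACK
            result.exceptions.append(
                (code, "no cascade step resolved saccharides; zero profile assigned")
            )
            logger.warning("item %r: saccharides fell through to zero fallback", code)
    return result


def assign_starch(
    db: CompositionDB,
    literature: Sequence[LiteratureValueSet] = (),
    links: Sequence[SimilarityLink] = (),
    recipes: Sequence[Recipe] = (),
    overseas: Sequence[OverseasEntry] = (),
    config: Optional[AssignmentConfig] = None,
) -> AssignmentResult:
    """Run the starch cascade (requires completed saccharide profiles).

    Steps mirror the saccharide cascade; the two closing steps are
    starch-by-subtraction (available carbohydrate minus total sugar, clamped
    at 0) and a zero assignment for anything still unresolved.
    """
    config = config or AssignmentConfig()
    check_recipes_acyclic(recipes)
    result = AssignmentResult(assigned={})
    lit = _literature_by_code(literature)
    same_links = _links_by_target(links, "same_food_other_form")
    similar_links = _links_by_target(links, "similar_food")
    ovs = _overseas_pick(overseas, config.overseas_priority)
    recipes_by_product = {r.product: r for r in recipes}

    def resolved(code: str) -> bool:
        return code in db and db[code].starch is not MISSING

    def set_starch(item: FoodItem, value: float, source: AssignmentSource) -> None:
        ceiling = _safe_available_carb(item)
        item.starch = _cap(max(0.0, value), ceiling, config)
        item.provenance["starch"] = source
        result.assigned[item.code] = source

    for step in config.cascade:
        if step == "analytical":
            for code, item in db.items():
                if code in result.assigned:
                    continue
                if item.starch is not MISSING:
                    item.provenance.setdefault(
                        "starch", AssignmentSource.STFCJ_ANALYTICAL
                    )
                    result.assigned[code] = item.provenance["starch"]
        elif step == "zero_carb":
            for code, item in db.items():
                if code in result.assigned or resolved(code):
                    continue
                avail = _safe_available_carb(item)
                if avail is not MISSING and avail <= 1e-12:
                    set_starch(item, 0.0, AssignmentSource.CARB_DIFFERENCE)
        elif step == "literature":
            for code, item in db.items():
                if code in result.assigned or resolved(code) or code not in lit:
                    continue
                ls = lit[code]
                if "starch" not in ls.values:
                    continue
                method = config.aggregation_overrides.get(
                    code, ls.method or config.aggregation
                )
                set_starch(
                    item,
                    aggregate_representative(ls.values["starch"], method),
                    AssignmentSource.LITERATURE,
                )
        elif step in ("same_food_other_form", "similar_food"):
            link_map = same_links if step == "same_food_other_form" else similar_links
            source = (
                AssignmentSource.SAME_FOOD_OTHER_FORM
                if step == "same_food_other_form"
                else AssignmentSource.SIMILAR_FOOD
            )
            progress = True
            while progress:
                progress = False
                for target, link in link_map.items():
                    if target not in db or target in result.assigned:
                        continue
                    if resolved(target) or not resolved(link.reference):
                        continue
                    ref = db[link.reference]
                    try:
                        dref, dtgt = dry_weight(ref), dry_weight(db[target])
                    except MissingDataError:
                        continue
                    if dref <= 0:
                        continue
                    set_starch(
                        db[target], scale_to_form(ref.starch, dref, dtgt), source
                    )
                    progress = True
        elif step == "recipe":
            progress = True
            while progress:
                progress = False
                for product, recipe in recipes_by_product.items():
                    if product not in db or product in result.assigned:
                        continue
                    if resolved(product):
                        continue
                    if not all(resolved(c) for c, _ in recipe.ingredients):
                        continue
                    values = compute_from_recipe(
                        recipe,
                        db,
                        components=("starch",),
                        getter=lambda it, comp: it.starch,
                    )
                    set_starch(db[product], values["starch"], AssignmentSource.RECIPE)
                    progress = True
        elif step == "overseas":
            for code, item in db.items():
                if code in result.assigned or resolved(code) or code not in ovs:
                    continue
                if "starch" not in ovs[code].values:
                    continue
                set_starch(
                    item, ovs[code].values["starch"], AssignmentSource.OVERSEAS_DB
                )
        else:
            raise ValueError(f"unknown cascade step {step!r}")

    # closing steps: carbohydrate difference, then zero fallback
    for code, item in db.items():
        if code in result.assigned or resolved(code):
            continue
        avail = _safe_available_carb(item)
        total = item.total_sugar
        if avail is not MISSING and total is not MISSING:
            set_starch(item, avail - total, AssignmentSource.CARB_DIFFERENCE)
        else:
            set_starch(item, 0.0, AssignmentSource.ZERO_FALLBACK)
            result.exceptions.append(
                (code, "starch not computable from carbohydrate difference; zero assigned")
            )
            logger.warning("item %r: starch fell through to zero fallback", code)
    return result


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal rounding with ties away from zero (table convention)."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def provenance_summary(
    db: CompositionDB,
    family: str = "saccharides",
    denominator_codes: Optional[Sequence[str]] = None,
    ndigits: int = 1,
) -> dict[str, dict[str, float]]:
    """Counts and percentages per :class:`AssignmentSource`.

    ``denominator_codes`` restricts both counts and the percentage base to a
    subset (e.g. only the items that carried table information); by default
    the whole database is used.  Percentages are rounded half-up to
    ``ndigits`` decimals.
    """
    codes = list(db) if denominator_codes is None else list(denominator_codes)
    n = len(codes)
    counts: dict[str, int] = {}
    for code in codes:
        source = db[code].provenance.get(family)
        key = source.value if isinstance(source, AssignmentSource) else "UNASSIGNED"
        counts[key] = counts.get(key, 0) + 1
    return {
        key: {
            "count": c,
            "pct": round_half_up(100.0 * c / n, ndigits) if n else 0.0,
        }
        for key, c in sorted(counts.items())
    }
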