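"""Synthetic composition tables and dietary records with known ground truth.

The generator builds a composition table in which a configured fraction of
items carries analytical saccharide/starch values and the remainder is
masked but resolvable through auxiliary sources (literature sets,
same-food/similar-food links, recipes, overseas entries) constructed to
satisfy the cascade's formulas exactly.  Dietary records are drawn from a
between-/within-person lognormal intake model so the habitual-distribution
stage can be exercised against known variance components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .composition_model import (
    DISACCHARIDES,
    FOOD_GROUP_NAMES,
    MISSING,
    SACCHARIDES,
    CompositionDB,
    FoodItem,
    Form,
    SaccharideProfile,
    available_carbohydrate,
)
from .errors import ConfigError
from .value_assignment import (
    AssignmentSource,
    LiteratureValueSet,
    OverseasEntry,
    Recipe,
    SimilarityLink,
    round_half_up,
)

#: Groups whose available carbohydrate is mostly starch.
STARCHY_GROUPS = frozenset(
    {"rice and grains", "other grain products", "bread", "noodle", "potatoes"}
)

#: Groups whose sugar is dominated by particular components.
SUGAR_WEIGHTS = {
    "fruits": {"glucose": 3, "fructose": 4, "sucrose": 3},
    "fruit juices": {"glucose": 3, "fructose": 4, "sucrose": 3},
    "dairy products": {"lactose": 9, "glucose": 1},
    "sugars and jams": {"sucrose": 9, "glucose": 1},
    "confectionaries": {"sucrose": 6, "glucose": 2, "maltose": 2},
    "sugar-sweetened beverages": {"sucrose": 5, "glucose": 2, "fructose": 3},
    "vegetables": {"glucose": 4, "fructose": 4, "sucrose": 2},
    "seaweeds": {"glucose": 2, "trehalose": 2, "galactose": 1},
    "mushrooms": {"trehalose": 5, "glucose": 2},
}
DEFAULT_SUGAR_WEIGHT = {"glucose": 2, "fructose": 2, "sucrose": 3, "maltose": 1}

DEFAULT_TARGET_STARCH = {
    ("toddler", "male"): 61.1,
    ("toddler", "female"): 55.6,
    ("preschool", "male"): 116.4,
    ("preschool", "female"): 107.8,
    ("schoolchild", "male"): 206.0,
    ("schoolchild", "female"): 176.3,
    ("adult", "male"): 203.4,
    ("adult", "female"): 153.8,
}

DEFAULT_DAYS = {"toddler": 1, "preschool": 3, "schoolchild": 3, "adult": 4}

DEFAULT_EI_EER = {
    "toddler": 1.22,
    "preschool": 1.0,
    "schoolchild": 1.0,
    "adult": 1.0,
}


class GeneratorConfig(BaseModel):
    """Knobs for both the composition-table and dietary-record generators."""

    seed: int = 42
    n_items: int = 500
    fraction_with_analytical: float = 0.396
    source_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "zero_carb": 0.08,
            "literature": 0.17,
            "same_food_other_form": 0.20,
            "similar_food": 0.20,
            "recipe": 0.20,
            "overseas": 0.15,
        }
    )
    starch_carb_difference_fraction: float = 0.25
    n_persons: dict[str, int] = Field(
        default_factory=lambda: {
            "toddler": 20,
            "preschool": 20,
            "schoolchild": 30,
            "adult": 20,
        }
    )
    days: dict[str, int] = Field(default_factory=lambda: dict(DEFAULT_DAYS))
    between_cv: float = 0.25
    within_cv: float = 0.35
    target_starch: dict = Field(
        default_factory=lambda: dict(DEFAULT_TARGET_STARCH)
    )
    ei_eer_target: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_EI_EER)
    )
    foods_per_day_min: int = 4
    foods_per_day_max: int = 8

    @field_validator("fraction_with_analytical", "starch_carb_difference_fraction")
    @classmethod
    def _fraction_in_unit(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
        return v

    @field_validator("between_cv", "within_cv")
    @classmethod
    def _cv_positive(cls, v: float) -> float:
        if v < 0:
            raise ValueError("coefficients of variation must be >= 0")
        return v

    @model_validator(mode="after")
    def _mix_consistent(self) -> "GeneratorConfig":
        total = sum(self.source_mix.values())
        if self.source_mix and not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"source_mix fractions sum to {total}, expected 1")
        if any(v < 0 for v in self.source_mix.values()):
            raise ValueError("source_mix fractions must be non-negative")
        return self


@dataclass
class GroundTruth:
    """True values persisted alongside generated outputs for oracles."""

    contents: dict[str, dict] = field(default_factory=dict)  # code -> truth
    sources: dict[str, dict[str, str]] = field(default_factory=dict)
    habitual_starch: dict[str, float] = field(default_factory=dict)
    between_sd_log: float = 0.0
    within_sd_log: float = 0.0


@dataclass
class SyntheticTable:
    """A generated composition table plus the auxiliary sources that make
    the masked items resolvable."""

    db: CompositionDB
    literature: list[LiteratureValueSet]
    links: list[SimilarityLink]
    recipes: list[Recipe]
    overseas: list[OverseasEntry]
    truth: GroundTruth


def _count(fraction: float, n: int) -> int:
    """Round-half-up count (table convention: 0.396 x 2222 -> 880)."""
    return int(math.floor(fraction * n + 0.5))


def _floor1(x: float) -> float:
    """Floor to one decimal; keeps generated contents under their caps."""
    return math.floor(x * 10.0) / 10.0


def _draw_proximates(rng: np.random.Generator, group: str) -> dict[str, float]:
    if group in ("sugars and jams", "confectionaries"):
        water = rng.uniform(3.0, 30.0)
    elif group in ("sugar-sweetened beverages", "fruit juices", "vegetable juices"):
        water = rng.uniform(85.0, 92.0)
    else:
        water = rng.uniform(8.0, 85.0)
    rest = 100.0 - water
    shares = rng.dirichlet([1.2, 0.8, 0.4, 6.0]) * rest
    protein, lipid, ash, carb_block = shares
    fiber = carb_block * rng.uniform(0.0, 0.2)
    return {
        "water": water,
        "protein": protein,
        "lipid": lipid,
        "ash": ash,
        "dietary_fiber": fiber,
        "avail": carb_block - fiber,
    }


def _draw_contents(
    rng: np.random.Generator, group: str, avail: float, exact_carb_diff: bool
) -> dict[str, float]:
    """Ground-truth saccharides + starch bounded by available carbohydrate."""
    if group in ("sugars and jams", "sugar-sweetened beverages", "fruit juices"):
        sugar_frac = rng.uniform(0.75, 0.85)
    elif group in ("fruits", "confectionaries", "dairy products"):
        sugar_frac = rng.uniform(0.5, 0.8)
    elif group in STARCHY_GROUPS:
        sugar_frac = rng.uniform(0.01, 0.1)
    else:
        sugar_frac = rng.uniform(0.05, 0.5)
    sugar_total = avail * sugar_frac
    weights = SUGAR_WEIGHTS.get(group, DEFAULT_SUGAR_WEIGHT)
    alphas = np.array([weights.get(c, 0.05) for c in SACCHARIDES], dtype=float)
    shares = rng.dirichlet(alphas)
    raw = {c: sugar_total * s for c, s in zip(SACCHARIDES, shares)}
    contents = {c: _floor1(v) for c, v in raw.items()}
    total = sum(contents.values())
    if exact_carb_diff:
        starch = max(0.0, avail - total)
    else:
        frac = rng.uniform(0.7, 0.95) if group in STARCHY_GROUPS else rng.uniform(0.0, 0.3)
        starch = _floor1(max(0.0, (avail - total)) * frac)
    contents["starch"] = starch
    return contents


def _energy(prox: dict[str, float]) -> float:
    return 4.0 * prox["protein"] + 9.0 * prox["lipid"] + 4.0 * prox["avail"]


def generate_composition_table(config: GeneratorConfig) -> SyntheticTable:
    """Build a table with MISSING entries plus the sources that resolve them.

    Deterministic under ``config.seed``; the ground truth records each
    masked item's true contents and true assignment source so recovery can
    be asserted exactly for formula-resolvable sources.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_items
    n_analytical = _count(config.fraction_with_analytical, n)
    n_rest = n - n_analytical
    source_counts: dict[str, int] = {}
    remaining = n_rest
    mix = list(config.source_mix.items())
    for i, (name, frac) in enumerate(mix):
        c = _count(frac, n_rest) if i < len(mix) - 1 else remaining
        c = min(c, remaining)
        source_counts[name] = c
        remaining -= c
    if remaining > 0:  # rounding remainder goes to the last class
        source_counts[mix[-1][0]] += remaining
    if source_counts.get("recipe", 0) > 0 and n_analytical < 2:
        raise ConfigError(
            "recipe items need at least 2 analytical ingredients; "
            "increase n_items or fraction_with_analytical"
        )
    if (
        source_counts.get("same_food_other_form", 0)
        or source_counts.get("similar_food", 0)
    ) and n_analytical < 1:
        raise ConfigError("link items need at least one analytical reference")

    truth = GroundTruth()
    db: CompositionDB = {}
    literature: list[LiteratureValueSet] = []
    links: list[SimilarityLink] = []
    recipes: list[Recipe] = []
    overseas: list[OverseasEntry] = []

    groups = list(FOOD_GROUP_NAMES)
    codes = [f"F{i:04d}" for i in range(n)]
    group_of = {
        code: groups[i] if i < len(groups) else groups[rng.integers(len(groups))]
        for i, code in enumerate(codes)
    }
    forms = list(Form)

    analytical_codes = codes[:n_analytical]
    rest_codes = codes[n_analytical:]
    assigned_class: dict[str, str] = {}
    cursor = 0
    for name, count in source_counts.items():
        for code in rest_codes[cursor : cursor + count]:
            assigned_class[code] = name
        cursor += count

    n_carb_diff = _count(
        config.starch_carb_difference_fraction,
        source_counts.get("literature", 0) + source_counts.get("overseas", 0),
    )
    carb_diff_pool = [
        c for c in rest_codes if assigned_class.get(c) in ("literature", "overseas")
    ]
    carb_diff_starch = set(carb_diff_pool[:n_carb_diff])

    def new_item(code: str, prox: dict[str, float]) -> FoodItem:
        return FoodItem(
            code=code,
            name=f"{group_of[code]} item {code}",
            food_group=group_of[code],
            form=forms[int(rng.integers(len(forms)))],
            water=prox["water"],
            protein=prox["protein"],
            lipid=prox["lipid"],
            ash=prox["ash"],
            dietary_fiber=prox["dietary_fiber"],
            energy=_energy(prox),
        )

    # analytical items: contents stay in the table
    for code in analytical_codes:
        prox = _draw_proximates(rng, group_of[code])
        contents = _draw_contents(rng, group_of[code], prox["avail"], False)
        item = new_item(code, prox)
        item.saccharides = SaccharideProfile(
            **{c: contents[c] for c in SACCHARIDES}
        )
        item.starch = contents["starch"]
        db[code] = item
        truth.contents[code] = contents
        truth.sources[code] = {
            "saccharides": AssignmentSource.STFCJ_ANALYTICAL.value,
            "starch": AssignmentSource.STFCJ_ANALYTICAL.value,
        }

    for code in rest_codes:
        cls = assigned_class[code]
        if cls == "zero_carb":
            water = rng.uniform(90.0, 99.0)
            protein = (100.0 - water) * 0.4
            # ash closes the proximates exactly so available carbohydrate is 0
            ash = 100.0 - water - protein - 0.0
            prox = {
                "water": water,
                "protein": protein,
                "lipid": 0.0,
                "ash": ash,
                "dietary_fiber": 0.0,
                "avail": 0.0,
            }
            item = new_item(code, prox)
            db[code] = item
            truth.contents[code] = {c: 0.0 for c in (*SACCHARIDES, "starch")}
            truth.sources[code] = {
                "saccharides": AssignmentSource.CARB_DIFFERENCE.value,
                "starch": AssignmentSource.CARB_DIFFERENCE.value,
            }
            continue

        if cls in ("same_food_other_form", "similar_food"):
            ref = analytical_codes[int(rng.integers(n_analytical))]
            ref_item = db[ref]
            dry_ref = 100.0 - ref_item.water
            r_max = min(1.8, 95.0 / dry_ref)
            r = rng.uniform(0.3, max(0.35, r_max))
            prox = {
                "water": 100.0 - r * dry_ref,
                "protein": r * ref_item.protein,
                "lipid": r * ref_item.lipid,
                "ash": r * ref_item.ash,
                "dietary_fiber": r * ref_item.dietary_fiber,
                "avail": 0.0,
            }
            prox["avail"] = (
                100.0
                - prox["water"]
                - prox["protein"]
                - prox["lipid"]
                - prox["ash"]
                - prox["dietary_fiber"]
            )
            item = new_item(code, prox)
            item.form = Form.COOKED if cls == "same_food_other_form" else item.form
            db[code] = item
            ref_contents = truth.contents[ref]
            dry_t = 100.0 - prox["water"]
            scaled = {
                c: ref_contents[c] * dry_t / dry_ref
                for c in (*SACCHARIDES, "starch")
            }
            truth.contents[code] = scaled
            source = (
                AssignmentSource.SAME_FOOD_OTHER_FORM
                if cls == "same_food_other_form"
                else AssignmentSource.SIMILAR_FOOD
            )
            truth.sources[code] = {
                "saccharides": source.value,
                "starch": source.value,
            }
            links.append(SimilarityLink(target=code, reference=ref, relation=cls))
            continue

        if cls == "recipe":
            k = int(rng.integers(2, min(4, n_analytical) + 1))
            chosen = rng.choice(n_analytical, size=k, replace=False)
            ingredients = [
                (analytical_codes[int(i)], float(rng.uniform(30.0, 200.0)))
                for i in chosen
            ]
            total_w = sum(w for _, w in ingredients)
            yield_g = total_w * float(rng.uniform(0.85, 1.15))
            # non-water components follow the recipe formula; water absorbs
            # the residual (cooking loss), so available carbohydrate stays
            # linear in the ingredients and physical (sum of proximates 100)
            for _ in range(50):
                scale = 100.0 / yield_g
                p = sum(db[c].protein * w / 100.0 for c, w in ingredients) * scale
                l = sum(db[c].lipid * w / 100.0 for c, w in ingredients) * scale
                a = sum(db[c].ash * w / 100.0 for c, w in ingredients) * scale
                fiber = (
                    sum(db[c].dietary_fiber * w / 100.0 for c, w in ingredients)
                    * scale
                )
                avail = (
                    sum(
                        available_carbohydrate(db[c]) * w / 100.0
                        for c, w in ingredients
                    )
                    * scale
                )
                water = 100.0 - p - l - a - fiber - avail
                if water >= 1.0:
                    break
                yield_g *= 1.05
            prox = {
                "water": water,
                "protein": p,
                "lipid": l,
                "ash": a,
                "dietary_fiber": fiber,
                "avail": avail,
            }
            item = new_item(code, prox)
            item.form = Form.PROCESSED
            db[code] = item
            contents = {
                comp: sum(
                    truth.contents[c][comp] * w / 100.0 for c, w in ingredients
                )
                * 100.0
                / yield_g
                for comp in (*SACCHARIDES, "starch")
            }
            truth.contents[code] = contents
            truth.sources[code] = {
                "saccharides": AssignmentSource.RECIPE.value,
                "starch": AssignmentSource.RECIPE.value,
            }
            recipes.append(
                Recipe(product=code, ingredients=ingredients, yield_g=yield_g)
            )
            continue

        # literature / overseas
        prox = _draw_proximates(rng, group_of[code])
        contents = _draw_contents(
            rng, group_of[code], prox["avail"], code in carb_diff_starch
        )
        item = new_item(code, prox)
        db[code] = item
        truth.contents[code] = contents
        starch_source = (
            AssignmentSource.CARB_DIFFERENCE.value
            if code in carb_diff_starch
            else None
        )
        if cls == "literature":
            values = {
                c: [contents[c] * 0.9, contents[c], contents[c] * 1.2]
                for c in SACCHARIDES
                if contents[c] > 0
            }
            if code not in carb_diff_starch:
                values["starch"] = [
                    contents["starch"] * 0.9,
                    contents["starch"],
                    contents["starch"] * 1.2,
                ]
            if not values:  # all-zero truth still needs one reported component
                values = {"glucose": [0.0]}
            literature.append(
                LiteratureValueSet(code=code, values=values, method="median")
            )
            truth.sources[code] = {
                "saccharides": AssignmentSource.LITERATURE.value,
                "starch": starch_source or AssignmentSource.LITERATURE.value,
            }
        else:  # overseas
            country = ("US", "UK", "AU")[int(rng.integers(3))]
            mono_equiv = country == "UK"
            stored = {}
            for c in SACCHARIDES:
                v = contents[c]
                if mono_equiv and c in DISACCHARIDES:
                    v = v / 0.95
                if v > 0:
                    stored[c] = v
            if code not in carb_diff_starch:
                stored["starch"] = contents["starch"]
            overseas.append(
                OverseasEntry(
                    code=code,
                    country=country,
                    values=stored,
                    monosaccharide_equivalent=mono_equiv,
                )
            )
            truth.sources[code] = {
                "saccharides": AssignmentSource.OVERSEAS_DB.value,
                "starch": starch_source or AssignmentSource.OVERSEAS_DB.value,
            }

    return SyntheticTable(
        db=db,
        literature=literature,
        links=links,
        recipes=recipes,
        overseas=overseas,
        truth=truth,
    )


def labelled_provenance_db(
    labels: dict[AssignmentSource, int],
    n_total: Optional[int] = None,
    family: str = "saccharides",
) -> CompositionDB:
    """A minimal fixture database with fixed provenance labels.

    The first ``sum(labels.values())`` items carry a complete profile and the
    requested source; any remainder up to ``n_total`` is left MISSING.
    Used to check provenance arithmetic against printed counts.
    """
    n_labelled = sum(labels.values())
    n = n_total if n_total is not None else n_labelled
    if n < n_labelled:
        raise ConfigError("n_total smaller than the sum of labels")
    db: CompositionDB = {}
    idx = 0
    for source, count in labels.items():
        for _ in range(count):
            code = f"P{idx:05d}"
            item = FoodItem(
                code=code,
                name=f"fixture {code}",
                food_group=FOOD_GROUP_NAMES[idx % len(FOOD_GROUP_NAMES)],
                water=80.0,
                protein=2.0,
                lipid=1.0,
                ash=1.0,
                dietary_fiber=1.0,
                energy=60.0,
            )
            item.saccharides = SaccharideProfile.zero()
            item.saccharides.glucose = 1.0
            item.starch = 1.0
            item.provenance[family] = source
            db[code] = item
            idx += 1
    for _ in range(n - n_labelled):
        code = f"P{idx:05d}"
        db[code] = FoodItem(
            code=code,
            name=f"fixture {code}",
            food_group=FOOD_GROUP_NAMES[idx % len(FOOD_GROUP_NAMES)],
            water=80.0,
            protein=2.0,
            lipid=1.0,
            ash=1.0,
            dietary_fiber=1.0,
            energy=60.0,
        )
        idx += 1
    return db


def generate_dietary_records(
    config: GeneratorConfig, db: CompositionDB
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw persons and multi-day records from the lognormal intake model.

    Returns (persons, records, truth): persons columns person_id, sex,
    age_group, age, eer_kcal; records columns person_id, day, food_code,
    amount_g.  Each person eats a fixed food basket whose amounts scale
    with the day's drawn starch total, so within-person variation follows
    the configured within CV exactly (and is zero when within_cv = 0).
    """
    rng = np.random.default_rng(config.seed + 1)
    pool = [
        (code, item)
        for code, item in db.items()
        if item.starch is not MISSING and item.starch > 1.0
    ]
    if len(pool) < config.foods_per_day_max:
        raise ConfigError(
            "not enough starch-bearing items in the table to compose records"
        )
    sd_b = math.sqrt(math.log(1.0 + config.between_cv**2))
    sd_w = math.sqrt(math.log(1.0 + config.within_cv**2))
    truth = GroundTruth(between_sd_log=sd_b, within_sd_log=sd_w)

    age_ranges = {
        "toddler": (1.5, 2.9),
        "preschool": (3.0, 6.9),
        "schoolchild": (8.0, 14.9),
        "adult": (20.0, 69.9),
    }
    persons_rows = []
    records_rows = []
    for age_group in sorted(config.n_persons):
        n_p = config.n_persons[age_group]
        days = config.days.get(age_group, DEFAULT_DAYS[age_group])
        lo, hi = age_ranges.get(age_group, (20.0, 69.0))
        for i in range(n_p):
            sex = "male" if i % 2 == 0 else "female"
            pid = f"{age_group}_{sex[0]}{i:03d}"
            target = config.target_starch.get(
                (age_group, sex),
                config.target_starch.get(f"{age_group},{sex}", 100.0),
            )
            habitual = target * math.exp(
                rng.normal(0.0, sd_b) - sd_b**2 / 2.0
            )
            truth.habitual_starch[pid] = habitual
            n_foods = int(
                rng.integers(config.foods_per_day_min, config.foods_per_day_max + 1)
            )
            basket_idx = rng.choice(len(pool), size=n_foods, replace=False)
            shares = rng.dirichlet(np.ones(n_foods))
            persons_rows.append(
                {
                    "person_id": pid,
                    "sex": sex,
                    "age_group": age_group,
                    "age": float(rng.uniform(lo, hi)),
                    "eer_kcal": 0.0,  # filled after records are drawn
                }
            )
            for day in range(1, days + 1):
                day_total = habitual * math.exp(
                    rng.normal(0.0, sd_w) - sd_w**2 / 2.0
                )
                for j, share in zip(basket_idx, shares):
                    code, item = pool[int(j)]
                    amount = share * day_total / (item.starch / 100.0)
                    records_rows.append(
                        {
                            "person_id": pid,
                            "day": day,
                            "food_code": code,
                            "amount_g": amount,
                        }
                    )
    persons = pd.DataFrame(persons_rows)
    records = pd.DataFrame(records_rows)

    # EER calibration: set each stratum's EER so mean EI/EER hits its target
    energy = {code: (item.energy or 0.0) for code, item in db.items()}
    records["kcal"] = [
        energy[c] * a / 100.0 for c, a in zip(records["food_code"], records["amount_g"])
    ]
    mean_daily = (
        records.groupby(["person_id", "day"])["kcal"].sum().groupby("person_id").mean()
    )
    persons = persons.set_index("person_id")
    for age_group, ratio in config.ei_eer_target.items():
        mask = persons["age_group"] == age_group
        if mask.any():
            stratum_mean = mean_daily.loc[persons.index[mask]].mean()
            persons.loc[mask, "eer_kcal"] = max(stratum_mean / ratio, 1.0)
    persons.loc[persons["eer_kcal"] <= 0, "eer_kcal"] = 1500.0
    persons = persons.reset_index()
    records = records.drop(columns=["kcal"])
    return persons, records, truth
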