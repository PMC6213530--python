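"""Apply the assigned database to dietary records.

Per-person absolute intakes (g/day, mean over recorded days), energy
adjustment (% of energy), EI/EER screening, adherence to the <10 %E and
<5 %E free-sugar recommendations, sex comparisons and food-group
contribution analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .composition_model import MISSING, SACCHARIDES, CompositionDB
from .errors import EmptySetError, InvariantError, UnknownFoodError
from .value_assignment import round_half_up

logger = logging.getLogger(__name__)

#: Energy conversion factor for carbohydrates (kcal per g), Atwater.
ENERGY_FACTOR_KCAL_PER_G = 4.0

#: Nutrients carried through the intake pipeline (per 100 g in the db,
#: per day after application to records).
NUTRIENTS: tuple[str, ...] = (
    "available_carbohydrate",
    "starch",
    *SACCHARIDES,
    "total_sugar",
    "free_sugar",
    "naturally_occurring_sugar",
)

#: The seven saccharide columns (exported for conservation checks).
SACCHARIDES_COLUMNS: tuple[str, ...] = SACCHARIDES

AGE_GROUPS: tuple[str, ...] = ("toddler", "preschool", "schoolchild", "adult")

#: Recording days per age group (one weekday for toddlers; three days for
#: pre-/schoolchildren; four days for adults).
DAYS_PER_AGE_GROUP: dict[str, int] = {
    "toddler": 1,
    "preschool": 3,
    "schoolchild": 3,
    "adult": 4,
}


@dataclass
class Person:
    id: str
    sex: str  # "male" | "female"
    age_group: str
    age: float
    eer_kcal: float

    def __post_init__(self) -> None:
        if self.eer_kcal <= 0:
            raise InvariantError(f"person {self.id!r}: EER must be > 0")


def nutrient_frame(db: CompositionDB) -> pd.DataFrame:
    """Per-100 g nutrient matrix (items x nutrients + energy) from a fully
    assigned and classified database."""
    from .composition_model import available_carbohydrate

    rows = {}
    for code, item in db.items():
        total = item.total_sugar
        if total is MISSING:
            raise InvariantError(f"item {code!r}: saccharides not assigned")
        if item.starch is MISSING:
            raise InvariantError(f"item {code!r}: starch not assigned")
        if item.free_sugar is MISSING:
            raise InvariantError(f"item {code!r}: free sugar not classified")
        row = {
            "energy": item.energy if item.energy is not MISSING else 0.0,
            "available_carbohydrate": available_carbohydrate(item),
            "starch": item.starch,
            "total_sugar": total,
            "free_sugar": item.free_sugar,
            "naturally_occurring_sugar": item.naturally_occurring_sugar,
            "food_group": item.food_group,
        }
        row.update(item.saccharides.components())
        rows[code] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "food_code"
    return frame


def compute_daily_intake(
    entries: Sequence[tuple[str, float]], db_frame: pd.DataFrame
) -> pd.Series:
    """Nutrient g/day vector (plus energy kcal/day) for one person-day.

    ``entries`` are (food_code, amount_g) pairs; intake of each nutrient is
    the sum over entries of amount/100 x content per 100 g.
    """
    cols = ["energy", *NUTRIENTS]
    total = pd.Series(0.0, index=cols)
    for code, amount in entries:
        if code not in db_frame.index:
            raise UnknownFoodError(f"unknown food code {code!r}")
        total += db_frame.loc[code, cols].astype(float) * (amount / 100.0)
    return total


def person_day_intakes(
    records: pd.DataFrame, db_frame: pd.DataFrame
) -> pd.DataFrame:
    """Vectorised person-day nutrient totals.

    ``records`` columns: person_id, day, food_code, amount_g (net of
    leftovers).  Returns one row per (person_id, day).
    """
    unknown = set(records["food_code"]) - set(db_frame.index)
    if unknown:
        raise UnknownFoodError(f"unknown food codes: {sorted(unknown)[:5]}")
    cols = ["energy", *NUTRIENTS]
    merged = records.merge(
        db_frame[cols], left_on="food_code", right_index=True, how="left"
    )
    for col in cols:
        merged[col] = merged[col] * merged["amount_g"] / 100.0
    out = merged.groupby(["person_id", "day"], sort=True)[cols].sum()
    return out


def person_mean_intakes(person_days: pd.DataFrame) -> pd.DataFrame:
    """Mean daily intake per person (multi-day mean of daily vectors)."""
    return person_days.groupby(level="person_id", sort=True).mean()


def percent_energy(
    grams: float, energy_kcal: float, factor: float = ENERGY_FACTOR_KCAL_PER_G
) -> float:
    """%E contributed by ``grams`` of a carbohydrate at ``factor`` kcal/g."""
    if energy_kcal <= 0:
        raise InvariantError(f"energy {energy_kcal} must be > 0")
    return grams * factor / energy_kcal * 100.0


def add_percent_energy(
    intakes: pd.DataFrame, factor: float = ENERGY_FACTOR_KCAL_PER_G
) -> pd.DataFrame:
    """Append ``<nutrient>_pctE`` columns to a person-intake frame."""
    if (intakes["energy"] <= 0).any():
        bad = intakes.index[intakes["energy"] <= 0].tolist()
        raise InvariantError(f"non-positive energy for: {bad[:5]}")
    out = intakes.copy()
    for nutrient in NUTRIENTS:
        out[f"{nutrient}_pctE"] = (
            out[nutrient] * factor / out["energy"] * 100.0
        )
    return out


def ei_eer(energy_intake: float, eer: float) -> float:
    """Ratio of reported energy intake to estimated energy requirement."""
    if eer <= 0:
        raise InvariantError(f"EER {eer} must be > 0")
    return energy_intake / eer


def who_adherence(
    pct_energy_values: Sequence[float],
    thresholds: Sequence[float] = (10.0, 5.0),
    ndigits: int = 1,
) -> dict[float, float]:
    """Prevalence (%) of members at or above each %E threshold (closed
    thresholds: a member exactly at 10.0 counts as >=10 %E)."""
    values = np.asarray(list(pct_energy_values), dtype=float)
    if values.size == 0:
        raise EmptySetError("adherence requested for an empty group")
    return {
        float(t): round_half_up(100.0 * np.mean(values >= t), ndigits)
        for t in thresholds
    }


def compare_sexes(
    group_a,
    group_b,
    kind: str = "mean",
) -> tuple[float, float]:
    """Two-sided sex comparison.

    ``kind="mean"``: Student two-sample t-test with pooled variance on the
    two value sequences.  ``kind="prevalence"``: Pearson chi-square without
    continuity correction on two (count_at_or_above, count_below) pairs.
    Returns (statistic, p).
    """
    if kind == "mean":
        a = np.asarray(list(group_a), dtype=float)
        b = np.asarray(list(group_b), dtype=float)
        if a.size < 2 or b.size < 2:
            raise EmptySetError("t-test needs >= 2 observations per group")
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
            return 0.0, 1.0  # degenerate: identical constant groups
        t, p = stats.ttest_ind(a, b, equal_var=True)
        return float(t), float(p)
    if kind == "prevalence":
        table = np.asarray([list(group_a), list(group_b)], dtype=float)
        if table.shape != (2, 2) or not np.isfinite(table).all():
            raise InvariantError("prevalence comparison needs a finite 2x2 table")
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            return 0.0, 1.0
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(chi2), float(p)
    raise ValueError(f"unknown comparison kind {kind!r}")


def significance_tier(p: float) -> str:
    """Footnote marker tiers: *, **, *** at 0.05 / 0.01 / 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def contribution_by_group(
    records: pd.DataFrame,
    db_frame: pd.DataFrame,
    nutrient: str,
    method: str = "mean_of_ratios",
) -> pd.Series:
    """Mean percentage contribution of each food group to a nutrient.

    Per person, the share of each group is the group's intake divided by the
    person's total intake over all recorded days; the table is the mean of
    the per-person shares (``method="mean_of_ratios"``, default) or the
    population ratio of sums (``method="population_ratio"``).  Persons with
    zero total intake are excluded and logged.
    """
    if nutrient not in db_frame.columns:
        raise InvariantError(f"unknown nutrient {nutrient!r}")
    merged = records.merge(
        db_frame[[nutrient, "food_group"]],
        left_on="food_code",
        right_index=True,
        how="left",
    )
    if merged[nutrient].isna().any():
        bad = sorted(set(merged.loc[merged[nutrient].isna(), "food_code"]))
        raise UnknownFoodError(f"unknown food codes: {bad[:5]}")
    merged["intake"] = merged[nutrient] * merged["amount_g"] / 100.0
    groups = sorted(db_frame["food_group"].unique())
    per_person = (
        merged.pivot_table(
            index="person_id",
            columns="food_group",
            values="intake",
            aggfunc="sum",
            fill_value=0.0,
        )
        .reindex(columns=groups, fill_value=0.0)
    )
    totals = per_person.sum(axis=1)
    zero = totals <= 0
    if zero.all():
        raise EmptySetError(f"no person has positive {nutrient} intake")
    if zero.any():
        logger.info(
            "%d person(s) with zero %s intake excluded from contributions",
            int(zero.sum()),
            nutrient,
        )
        per_person = per_person.loc[~zero]
        totals = totals.loc[~zero]
    if method == "mean_of_ratios":
        shares = per_person.div(totals, axis=0).mean(axis=0) * 100.0
    elif method == "population_ratio":
        shares = per_person.sum(axis=0) / totals.sum() * 100.0
    else:
        raise ValueError(f"unknown contribution method {method!r}")
    shares.name = nutrient
    return shares


def collapse_minor_groups(
    table: pd.DataFrame, threshold: float = 7.0, others_label: str = "others"
) -> pd.DataFrame:
    """Combine groups below ``threshold`` % in every population column into
    a single 'others' row (display convention for contribution tables)."""
    minor = (table < threshold).all(axis=1)
    if not minor.any():
        return table
    kept = table.loc[~minor].copy()
    kept.loc[others_label] = table.loc[minor].sum(axis=0)
    return kept


def stratified_summary(
    person_intakes: pd.DataFrame,
    persons: pd.DataFrame,
    thresholds: Sequence[float] = (10.0, 5.0),
) -> dict:
    """Per age-group/sex means and SDs, EI/EER, WHO adherence and sex
    comparisons; ``persons`` columns: person_id, sex, age_group, eer_kcal."""
    meta = persons.set_index("person_id")
    joined = person_intakes.join(meta, how="inner")
    joined["ei_eer"] = joined["energy"] / joined["eer_kcal"]
    summary: dict = {}
    value_cols = [
        c
        for c in joined.columns
        if c == "energy" or c == "ei_eer" or c in NUTRIENTS or c.endswith("_pctE")
    ]
    for age_group, by_age in joined.groupby("age_group", sort=True):
        entry: dict = {"n": int(len(by_age)), "sexes": {}, "comparisons": {}}
        for sex, by_sex in by_age.groupby("sex", sort=True):
            stats_block = {
                col: {
                    "mean": float(by_sex[col].mean()),
                    "sd": float(by_sex[col].std(ddof=1)) if len(by_sex) > 1 else 0.0,
                }
                for col in value_cols
            }
            block = {"n": int(len(by_sex)), "stats": stats_block}
            if "free_sugar_pctE" in by_sex.columns:
                block["who_adherence"] = {
                    f">={t:g}%E": v
                    for t, v in who_adherence(
                        by_sex["free_sugar_pctE"], thresholds
                    ).items()
                }
            entry["sexes"][sex] = block
        males = by_age[by_age["sex"] == "male"]
        females = by_age[by_age["sex"] == "female"]
        if len(males) >= 2 and len(females) >= 2:
            for col in value_cols:
                t, p = compare_sexes(males[col], females[col], kind="mean")
                entry["comparisons"][col] = {
                    "t": t,
                    "p": p,
                    "tier": significance_tier(p),
                }
            if "free_sugar_pctE" in by_age.columns:
                for t_val in thresholds:
                    m_yes = int((males["free_sugar_pctE"] >= t_val).sum())
                    f_yes = int((females["free_sugar_pctE"] >= t_val).sum())
                    chi2, p = compare_sexes(
                        (m_yes, len(males) - m_yes),
                        (f_yes, len(females) - f_yes),
                        kind="prevalence",
                    )
                    entry["comparisons"][f"free_sugar>= {t_val:g}%E"] = {
                        "chi2": chi2,
                        "p": p,
                        "tier": significance_tier(p),
                    }
        summary[age_group] = entry
    return summary
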