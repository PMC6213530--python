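"""CSV readers and writers for every table the pipeline consumes or emits.

All files are UTF-8, RFC 4180 CSV with a required header.  An empty cell is
the MISSING sentinel; 0 is always a value.  ``read(write(x))`` round-trips
exactly, including MISSING entries and column order.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from ..composition_model import (
    MISSING,
    SACCHARIDES,
    CompositionDB,
    FoodItem,
    Form,
    SaccharideProfile,
)
from ..errors import ParseError, SchemaError
from ..value_assignment import (
    AssignmentSource,
    LiteratureValueSet,
    OverseasEntry,
    Recipe,
    SimilarityLink,
)

PathLike = Union[str, Path]

COMPOSITION_COLUMNS = [
    "code",
    "name",
    "food_group",
    "form",
    "water",
    "protein",
    "lipid",
    "ash",
    "dietary_fiber",
    "energy",
    *SACCHARIDES,
    "starch",
    "free_sugar",
    "naturally_occurring_sugar",
    "provenance",
]

_NUMERIC_COLUMNS = (
    "water",
    "protein",
    "lipid",
    "ash",
    "dietary_fiber",
    "energy",
    *SACCHARIDES,
    "starch",
    "free_sugar",
    "naturally_occurring_sugar",
)


def _require_columns(header: Sequence[str], required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _parse_float(cell: str, row: int, col: str, path) -> Optional[float]:
    if cell is None or cell == "":
        return MISSING
    try:
        return float(cell)
    except ValueError:
        raise ParseError(f"{path}: non-numeric cell at row {row}, column {col!r}: {cell!r}")


def _format(value) -> str:
    if value is MISSING:
        return ""
    return repr(float(value))


def _provenance_str(item: FoodItem) -> str:
    parts = []
    for family in ("saccharides", "starch"):
        src = item.provenance.get(family)
        if src is not None:
            parts.append(f"{family}={src.value if isinstance(src, AssignmentSource) else src}")
    return ";".join(parts)


def _parse_provenance(cell: str) -> dict:
    out = {}
    if not cell:
        return out
    for part in cell.split(";"):
        family, _, src = part.partition("=")
        out[family] = AssignmentSource(src)
    return out


def read_composition(path: PathLike) -> CompositionDB:
    path = Path(path)
    db: CompositionDB = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header required")
        _require_columns(reader.fieldnames, COMPOSITION_COLUMNS[:-3], path)
        for i, row in enumerate(reader, start=2):
            numeric = {
                col: _parse_float(row.get(col, ""), i, col, path)
                for col in _NUMERIC_COLUMNS
            }
            item = FoodItem(
                code=row["code"],
                name=row["name"],
                food_group=row["food_group"],
                form=Form(row["form"]) if row.get("form") else Form.RAW,
                water=numeric["water"],
                protein=numeric["protein"],
                lipid=numeric["lipid"],
                ash=numeric["ash"],
                dietary_fiber=numeric["dietary_fiber"],
                energy=numeric["energy"],
                saccharides=SaccharideProfile(
                    **{c: numeric[c] for c in SACCHARIDES}
                ),
                starch=numeric["starch"],
                free_sugar=numeric["free_sugar"],
                naturally_occurring_sugar=numeric["naturally_occurring_sugar"],
                provenance=_parse_provenance(row.get("provenance", "")),
            )
            db[item.code] = item
    return db


def write_composition(db: CompositionDB, path: PathLike) -> None:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COMPOSITION_COLUMNS)
        for item in db.values():
            comps = item.saccharides.components()
            writer.writerow(
                [
                    item.code,
                    item.name,
                    item.food_group,
                    item.form.value,
                    *(_format(getattr(item, c)) for c in (
                        "water", "protein", "lipid", "ash", "dietary_fiber", "energy"
                    )),
                    *(_format(comps[c]) for c in SACCHARIDES),
                    _format(item.starch),
                    _format(item.free_sugar),
                    _format(item.naturally_occurring_sugar),
                    _provenance_str(item),
                ]
            )


def read_literature(path: PathLike) -> list[LiteratureValueSet]:
    """Columns: code, component, value, source_id[, method]."""
    path = Path(path)
    by_code: dict[str, dict[str, list[float]]] = defaultdict(lambda: defaultdict(list))
    methods: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header required")
        _require_columns(reader.fieldnames, ["code", "component", "value"], path)
        for i, row in enumerate(reader, start=2):
            value = _parse_float(row["value"], i, "value", path)
            by_code[row["code"]][row["component"]].append(value)
            if row.get("method"):
                methods[row["code"]] = row["method"]
    return [
        LiteratureValueSet(
            code=code, values=dict(vals), method=methods.get(code, "median")
        )
        for code, vals in by_code.items()
    ]


def write_literature(sets: Sequence[LiteratureValueSet], path: PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["code", "component", "value", "source_id", "method"])
        for ls in sets:
            for comp, values in ls.values.items():
                for j, v in enumerate(values):
                    writer.writerow([ls.code, comp, repr(float(v)), f"S{j}", ls.method])


def read_links(path: PathLike) -> list[SimilarityLink]:
    """Columns: target, reference, relation."""
    path = Path(path)
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header required")
        _require_columns(reader.fieldnames, ["target", "reference", "relation"], path)
        for row in reader:
            out.append(
                SimilarityLink(
                    target=row["target"],
                    reference=row["reference"],
                    relation=row["relation"],
                )
            )
    return out


def write_links(links: Sequence[SimilarityLink], path: PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["target", "reference", "relation"])
        for l in links:
            writer.writerow([l.target, l.reference, l.relation])


def read_recipes(path: PathLike) -> list[Recipe]:
    """Columns: product, ingredient, weight_g, yield_g (yield repeated)."""
    path = Path(path)
    ingredients: dict[str, list[tuple[str, float]]] = defaultdict(list)
    yields: dict[str, float] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header required")
        _require_columns(
            reader.fieldnames, ["product", "ingredient", "weight_g", "yield_g"], path
        )
        for i, row in enumerate(reader, start=2):
            w = _parse_float(row["weight_g"], i, "weight_g", path)
            y = _parse_float(row["yield_g"], i, "yield_g", path)
            ingredients[row["product"]].append((row["ingredient"], w))
            yields[row["product"]] = y
    return [
        Recipe(product=p, ingredients=ing, yield_g=yields[p])
        for p, ing in ingredients.items()
    ]


def write_recipes(recipes: Sequence[Recipe], path: PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["product", "ingredient", "weight_g", "yield_g"])
        for r in recipes:
            for code, w in r.ingredients:
                writer.writerow([r.product, code, repr(float(w)), repr(float(r.yield_g))])


def read_overseas(path: PathLike) -> list[OverseasEntry]:
    """Columns: code, country, component, value, mono_equiv."""
    path = Path(path)
    values: dict[tuple[str, str], dict[str, float]] = defaultdict(dict)
    flags: dict[tuple[str, str], bool] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header required")
        _require_columns(
            reader.fieldnames, ["code", "country", "component", "value", "mono_equiv"], path
        )
        for i, row in enumerate(reader, start=2):
            key = (row["code"], row["country"])
            values[key][row["component"]] = _parse_float(row["value"], i, "value", path)
            flags[key] = row["mono_equiv"].strip().lower() in ("1", "true", "yes")
    return [
        OverseasEntry(
            code=code, country=country, values=vals, monosaccharide_equivalent=flags[(code, country)]
        )
        for (code, country), vals in values.items()
    ]


def write_overseas(entries: Sequence[OverseasEntry], path: PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["code", "country", "component", "value", "mono_equiv"])
        for e in entries:
            for comp, v in e.values.items():
                writer.writerow(
                    [e.code, e.country, comp, repr(float(v)),
                     "true" if e.monosaccharide_equivalent else "false"]
                )


def read_records(path: PathLike) -> pd.DataFrame:
    """Columns: person_id, day, food_code, amount_g."""
    path = Path(path)
    frame = pd.read_csv(path, dtype={"person_id": str, "food_code": str})
    _require_columns(frame.columns, ["person_id", "day", "food_code", "amount_g"], path)
    if (frame["amount_g"] < 0).any():
        raise ParseError(f"{path}: negative amount_g")
    return frame


def write_records(records: pd.DataFrame, path: PathLike) -> None:
    records.to_csv(path, index=False)


def read_persons(path: PathLike) -> pd.DataFrame:
    """Columns: person_id, sex, age_group, age, eer_kcal."""
    path = Path(path)
    frame = pd.read_csv(path, dtype={"person_id": str})
    _require_columns(
        frame.columns, ["person_id", "sex", "age_group", "age", "eer_kcal"], path
    )
    if (frame["eer_kcal"] <= 0).any():
        raise ParseError(f"{path}: non-positive eer_kcal")
    return frame


def write_persons(persons: pd.DataFrame, path: PathLike) -> None:
    persons.to_csv(path, index=False)
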