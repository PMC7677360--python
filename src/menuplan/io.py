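"""Readers and writers for every on-disk format the toolkit consumes.

Formats (all plain text, UTF-8):

* recipe table — CSV with columns ``id, name, portion_g``, one column per
  parameter, and ``use_groups`` / ``food_groups`` as semicolon-separated
  lists; or an equivalent JSON array of objects;
* plan config — YAML/JSON mapping with ``meals``, ``days``, ``weeks``;
* constraint config — YAML/JSON with sections ``quantity_bounds``,
  ``meal_shares``, ``rate_bounds``, ``composition``; round-trips
  losslessly;
* objective config — YAML/JSON list of ``{parameter, weight, direction}``;
* schedule — CSV with columns ``week, day, meal, dish_id, dish_name`` in
  week-major slot order, plus a JSON report of per-day quantities;
* Pareto front — CSV with columns ``epsilon, f1, f2, menu_id`` and a JSON
  summary of percent changes from the minimum-f1 point.

The CSV dialect is comma-separated with a mandatory header and decimal
point; a ``decimal=","`` flag accepts decimal-comma sources.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
import pandas as pd
import yaml

from .constraints import (
    CompositionRule,
    ConstraintSystem,
    MealShareBound,
    QuantityBound,
    RateBound,
)
from .objective import ObjectiveSpec
from .pareto import ParetoSet
from .plan_model import (
    Dish,
    InvalidConfigError,
    Menu,
    ParameterSpec,
    PlanGrid,
    RecipeTable,
    Scope,
    Slot,
    TableValidationError,
    aggregate_quantity,
)

_FIXED_COLUMNS = ("id", "name", "portion_g", "use_groups", "food_groups")

_UNIT_DEFAULTS = {
    "energy": "kcal", "protein": "g", "fat": "g", "carbohydrates": "g",
    "sugar": "g", "fiber": "g", "sodium": "mg", "calcium": "mg",
    "iron": "mg", "carbon_footprint": "kg CO2eq", "water_footprint": "m3",
    "price": "EUR",
}
_CATEGORY_DEFAULTS = {
    "carbon_footprint": "environmental", "water_footprint": "environmental",
    "land_footprint": "environmental", "price": "economic",
    "cost": "economic",
}


def _split_groups(cell) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return frozenset()
    return frozenset(g.strip() for g in str(cell).split(";") if g.strip())


def load_recipes(path: str | Path, decimal: str = ".") -> RecipeTable:
    """Load and validate a recipe table from CSV or JSON.

    Every problem (duplicate ids, missing or non-numeric parameter values,
    missing use groups) is collected with its line number before a single
    error reports them all.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidConfigError(f"recipe file {path} does not exist")
    if path.stat().st_size == 0:
        raise TableValidationError([f"{path}: file is empty"])
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text(encoding="utf-8"))
        if not records:
            raise TableValidationError([f"{path}: no dishes"])
        frame = pd.DataFrame.from_records(records)
        if "use_groups" in frame:
            frame["use_groups"] = frame["use_groups"].apply(
                lambda v: ";".join(v) if isinstance(v, list) else v
            )
        if "food_groups" in frame:
            frame["food_groups"] = frame["food_groups"].apply(
                lambda v: ";".join(v) if isinstance(v, list) else v
            )
        header_offset = 0  # JSON: report record numbers, not lines
    else:
        frame = pd.read_csv(path, decimal=decimal)
        header_offset = 1
    if frame.empty:
        raise TableValidationError([f"{path}: no dishes"])

    problems: list[str] = []
    for col in ("id", "name", "use_groups"):
        if col not in frame.columns:
            problems.append(f"{path}: missing required column {col!r}")
    if problems:
        raise TableValidationError(problems)

    param_cols = [c for c in frame.columns if c not in _FIXED_COLUMNS]

    def line(idx: int) -> str:
        return f"{path.name}:{idx + 1 + header_offset}"

    seen: dict[str, int] = {}
    dishes: list[Dish] = []
    for idx, row in frame.iterrows():
        dish_id = str(row["id"])
        if dish_id in seen:
            problems.append(
                f"duplicate dish id {dish_id!r} at {line(seen[dish_id])} "
                f"and {line(idx)}"
            )
        else:
            seen[dish_id] = idx
        use_groups = _split_groups(row.get("use_groups"))
        if not use_groups:
            problems.append(f"{line(idx)}: dish {dish_id!r} has no use group")
        params = {}
        for col in param_cols:
            v = row[col]
            try:
                v = float(v)
            except (TypeError, ValueError):
                problems.append(
                    f"{line(idx)}: parameter {col!r} is not numeric ({v!r})"
                )
                continue
            if math.isnan(v):
                problems.append(
                    f"{line(idx)}: parameter {col!r} missing for "
                    f"dish {dish_id!r}"
                )
                continue
            params[col] = v
        portion = row.get("portion_g", 0.0)
        try:
            portion = float(portion)
        except (TypeError, ValueError):
            problems.append(f"{line(idx)}: portion_g not numeric")
            portion = 0.0
        dishes.append(Dish(
            id=dish_id, name=str(row["name"]), portion_g=portion,
            params=params, use_groups=use_groups,
            food_groups=_split_groups(row.get("food_groups")),
        ))
    if problems:
        raise TableValidationError(problems)

    specs = tuple(
        ParameterSpec(
            name=c,
            unit=_UNIT_DEFAULTS.get(c, "unit"),
            category=_CATEGORY_DEFAULTS.get(c, "nutritional"),
        )
        for c in param_cols
    )
    return RecipeTable(dishes, specs)


def write_recipes(table: RecipeTable, path: str | Path) -> None:
    """Write a recipe table to CSV or JSON (chosen by file suffix)."""
    path = Path(path)
    rows = []
    for d in table.dishes:
        row = {
            "id": d.id, "name": d.name, "portion_g": d.portion_g,
            **{p: d.params[p] for p in table.parameters},
            "use_groups": ";".join(sorted(d.use_groups)),
            "food_groups": ";".join(sorted(d.food_groups)),
        }
        rows.append(row)
    frame = pd.DataFrame(rows)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=1), encoding="utf-8")
    else:
        frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Plan / constraint / objective configs
# ---------------------------------------------------------------------------

def _load_structured(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise InvalidConfigError(f"config file {path} does not exist")
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _dump_structured(obj, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(obj, indent=1), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(obj, sort_keys=False),
                        encoding="utf-8")


def load_plan(path: str | Path) -> PlanGrid:
    data = _load_structured(path)
    try:
        return PlanGrid(data["meals"], data["days"], int(data["weeks"]))
    except KeyError as exc:
        raise InvalidConfigError(f"plan config missing key {exc}") from None


def write_plan(grid: PlanGrid, path: str | Path) -> None:
    _dump_structured(
        {"meals": list(grid.meals), "days": list(grid.days),
         "weeks": grid.weeks},
        path,
    )


def load_constraints(path: str | Path) -> dict:
    """Load a constraint configuration into typed bound/rule objects."""
    data = _load_structured(path) or {}
    out = {"quantity_bounds": [], "meal_shares": [], "rate_bounds": [],
           "composition": []}
    for e in data.get("quantity_bounds", []):
        out["quantity_bounds"].append(QuantityBound(
            parameter=e["parameter"], scope_level=e["scope"],
            lower=e.get("lower"), upper=e.get("upper"),
            mode=e.get("mode", "hard"),
            soft_weight_lower=e.get("soft_weight_lower", 1.0),
            soft_weight_upper=e.get("soft_weight_upper", 1.0),
        ))
    for e in data.get("meal_shares", []):
        out["meal_shares"].append(MealShareBound(
            parameter=e["parameter"], meal_label=e["meal"],
            min_fraction=e["min_fraction"],
        ))
    for e in data.get("rate_bounds", []):
        out["rate_bounds"].append(RateBound(
            target=e["target"], scope_level=e["scope"],
            min_count=e.get("min"), max_count=e.get("max"),
        ))
    for e in data.get("composition", []):
        out["composition"].append(CompositionRule(
            use_group=e["use_group"], meal_label=e["meal"],
            exact_count=e.get("exact_count", 1),
        ))
    return out


def write_constraints(config: dict, path: str | Path) -> None:
    data = {
        "quantity_bounds": [
            {"parameter": b.parameter, "scope": b.scope_level,
             "lower": b.lower, "upper": b.upper, "mode": b.mode,
             "soft_weight_lower": b.soft_weight_lower,
             "soft_weight_upper": b.soft_weight_upper}
            for b in config.get("quantity_bounds", [])
        ],
        "meal_shares": [
            {"parameter": b.parameter, "meal": b.meal_label,
             "min_fraction": b.min_fraction}
            for b in config.get("meal_shares", [])
        ],
        "rate_bounds": [
            {"target": b.target, "scope": b.scope_level,
             "min": b.min_count, "max": b.max_count}
            for b in config.get("rate_bounds", [])
        ],
        "composition": [
            {"use_group": r.use_group, "meal": r.meal_label,
             "exact_count": r.exact_count}
            for r in config.get("composition", [])
        ],
    }
    _dump_structured(data, path)


def build_system(grid: PlanGrid, table: RecipeTable,
                 config: dict) -> ConstraintSystem:
    """Assemble a constraint system from a loaded constraint config."""
    system = ConstraintSystem(grid, table)
    system.add_composition(config.get("composition", []))
    for b in config.get("quantity_bounds", []):
        system.add_quantity_bound(b)
    for b in config.get("meal_shares", []):
        system.add_quantity_bound(b)
    for b in config.get("rate_bounds", []):
        system.add_rate_bound(b)
    return system


def load_objective(path: str | Path) -> ObjectiveSpec:
    data = _load_structured(path)
    if isinstance(data, dict):
        terms_data = data.get("terms", [])
        penalty = data.get("deviation_penalty", 0.0)
        name = data.get("name", "objective")
    else:
        terms_data, penalty, name = data, 0.0, "objective"
    terms = []
    for e in terms_data:
        weight = float(e.get("weight", 1.0))
        direction = e.get("direction", "minimize")
        if direction not in ("minimize", "maximize"):
            raise InvalidConfigError(f"bad direction {direction!r}")
        coeff = weight if direction == "minimize" else -weight
        terms.append((e["parameter"], coeff))
    return ObjectiveSpec(tuple(terms), deviation_penalty=penalty, name=name)


def write_objective(spec: ObjectiveSpec, path: str | Path) -> None:
    data = {
        "name": spec.name,
        "deviation_penalty": spec.deviation_penalty,
        "terms": [
            {"parameter": p,
             "weight": abs(c),
             "direction": "minimize" if c >= 0 else "maximize"}
            for p, c in spec.terms
        ],
    }
    _dump_structured(data, path)


# ---------------------------------------------------------------------------
# Schedules and reports
# ---------------------------------------------------------------------------

def write_schedule(menu: Menu, path: str | Path) -> None:
    """Write a menu as a week-major CSV schedule."""
    rows = []
    for slot in menu.grid.slots():
        for dish_id in sorted(menu.dishes_at(slot)):
            rows.append({
                "week": slot.week, "day": slot.day, "meal": slot.meal,
                "dish_id": dish_id,
                "dish_name": menu.table.dish(dish_id).name,
            })
    pd.DataFrame(
        rows, columns=["week", "day", "meal", "dish_id", "dish_name"]
    ).to_csv(path, index=False)


def read_schedule(path: str | Path, grid: PlanGrid,
                  table: RecipeTable) -> Menu:
    frame = pd.read_csv(Path(path))
    menu = Menu(grid, table)
    for _, row in frame.iterrows():
        slot = Slot(str(row["meal"]), str(row["day"]), int(row["week"]))
        menu.assign(slot, menu.dishes_at(slot) | {str(row["dish_id"])})
    return menu


def day_report(menu: Menu) -> dict:
    """Per-day quantities of every parameter, plus plan totals."""
    days = {}
    for sc in Scope.instances(menu.grid, "day"):
        key = f"week{sc.selector[1]}/{sc.selector[0]}"
        days[key] = {
            p: round(aggregate_quantity(menu, p, sc), 6)
            for p in menu.table.parameters
        }
    plan = {
        p: round(aggregate_quantity(menu, p, Scope.plan()), 6)
        for p in menu.table.parameters
    }
    return {"per_day": days, "plan_totals": plan}


def write_day_report(menu: Menu, path: str | Path) -> None:
    Path(path).write_text(json.dumps(day_report(menu), indent=1),
                          encoding="utf-8")


def write_front(front: ParetoSet, out_dir: str | Path,
                f1_name: str = "f1", f2_name: str = "f2") -> None:
    """Export a Pareto front: front.csv, one schedule per point, and a JSON
    summary with percent changes relative to the minimum-f1 point."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, point in enumerate(front):
        menu_id = f"menu_{k:03d}"
        f1, f2 = point.objectives
        rows.append({"epsilon": f2, "f1": f1, "f2": f2,
                     "menu_id": menu_id})
        write_schedule(point.menu, out / f"{menu_id}.csv")
    pd.DataFrame(
        rows, columns=["epsilon", "f1", "f2", "menu_id"]
    ).to_csv(out / "front.csv", index=False)
    summary = {"objectives": [f1_name, f2_name], "n_points": len(front)}
    if len(front):
        pct = front.percent_changes(reference=0)
        summary["reference"] = {
            "menu_id": "menu_000",
            f1_name: front.points[0].objectives[0],
            f2_name: front.points[0].objectives[1],
        }
        summary["percent_change_from_reference"] = [
            {f1_name: round(float(row[0]), 6),
             f2_name: round(float(row[1]), 6)}
            for row in pct
        ]
    (out / "summary.json").write_text(json.dumps(summary, indent=1),
                                      encoding="utf-8")
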