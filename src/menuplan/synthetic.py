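"""Synthetic recipe tables and plan/constraint configurations.

Real menu-design studies draw their dish tables from food-composition
databases, life-cycle-assessment databases and wholesaler price lists —
none of which ship with this package.  This module generates recipe tables
whose *structure* (use-group inventory and sizes, food groups, plan
dimensions, constraint families) emulates three published study templates,
with parameter values drawn from plausible distributions:

* ``school_lunch_es`` — a 20-day (5 x 4) school lunch plan, 1 meal/day,
  lunches composed of a starter, a main dish and a dessert drawn from
  20 / 20 / 7 dishes;
* ``school_lunch_it`` — a 20-day school lunch plan, lunches composed of a
  first course, second course and side dish (33 / 48 / 23) served with
  bread and fruit;
* ``nursing_home_it`` — a 14-day (7 x 2) full-board plan with breakfast
  (cereals 8, beverages 5, sweeteners 4), lunch and dinner (first 47,
  second 55, side 15, bread 2, fruit 9).

Values are right-skewed log-normals for price and footprints and
zero-truncated normals for nutrients, with group-specific means (red-meat
dishes carry higher carbon-footprint means than legume dishes).  Quantity
bounds are calibrated from random composition-valid menus so the feasible
set is nonempty, and the calibration is verified by one solve.  Identical
(spec, seed) pairs produce identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .constraints import (
    CompositionRule,
    ConstraintSystem,
    MealShareBound,
    QuantityBound,
    RateBound,
)
from .objective import ObjectiveSpec
from .plan_model import (
    Dish,
    InvalidConfigError,
    Menu,
    MenuPlanError,
    ParameterSpec,
    PlanGrid,
    RecipeTable,
    Scope,
    quantity_coefficients,
)
from .solver import solve

TEMPLATES = ("school_lunch_es", "school_lunch_it", "nursing_home_it",
             "custom")


class InfeasibleScenarioError(MenuPlanError):
    """Calibration could not produce a feasible scenario."""


@dataclass(frozen=True)
class ScenarioSpec:
    """Recipe for one synthetic scenario.

    ``use_group_sizes`` maps (meal label, use group) -> dish count;
    ``noise`` scales the spread of every parameter distribution.
    """

    template: str = "school_lunch_it"
    seed: int = 0
    use_group_sizes: tuple[tuple[tuple[str, str], int], ...] | None = None
    meals: tuple[str, ...] | None = None
    days: tuple[str, ...] | None = None
    weeks: int | None = None
    noise: float = 1.0

    def __post_init__(self):
        if self.template not in TEMPLATES:
            raise InvalidConfigError(
                f"template {self.template!r} not in {TEMPLATES}"
            )
        if self.noise < 0:
            raise InvalidConfigError("noise must be >= 0")
        if self.use_group_sizes is not None:
            sizes = tuple(
                (tuple(k), int(v)) for k, v in dict(
                    self.use_group_sizes).items()
            )
            object.__setattr__(self, "use_group_sizes", sizes)
            if any(v < 1 for _, v in sizes):
                raise InvalidConfigError("use group sizes must be >= 1")
        if self.meals is not None:
            object.__setattr__(self, "meals", tuple(self.meals))
        if self.days is not None:
            object.__setattr__(self, "days", tuple(self.days))
        if self.weeks is not None and self.weeks < 1:
            raise InvalidConfigError("weeks must be >= 1")

    def resolved(self) -> "_Resolved":
        base = _TEMPLATE_DEFAULTS[self.template]
        sizes = (dict(self.use_group_sizes)
                 if self.use_group_sizes is not None
                 else dict(base["use_group_sizes"]))
        return _Resolved(
            meals=self.meals or base["meals"],
            days=self.days or base["days"],
            weeks=self.weeks or base["weeks"],
            use_group_sizes=sizes,
            parameters=base["parameters"],
            food_groups=base["food_groups"],
            objectives=base["objectives"],
        )


@dataclass
class _Resolved:
    meals: tuple[str, ...]
    days: tuple[str, ...]
    weeks: int
    use_group_sizes: dict[tuple[str, str], int]
    parameters: tuple[ParameterSpec, ...]
    food_groups: tuple[str, ...]
    objectives: tuple[str, ...]


_WORKWEEK = ("mon", "tue", "wed", "thu", "fri")
_FULLWEEK = ("mon", "tue", "wed", "thu", "fri", "sat", "sun")

_NUTRI = lambda n, u: ParameterSpec(n, u, "nutritional")  # noqa: E731

_TEMPLATE_DEFAULTS: dict[str, dict] = {
    "school_lunch_es": {
        "meals": ("lunch",),
        "days": _WORKWEEK,
        "weeks": 4,
        "use_group_sizes": {
            ("lunch", "starter"): 20,
            ("lunch", "main"): 20,
            ("lunch", "dessert"): 7,
        },
        "parameters": (
            _NUTRI("energy", "kcal"), _NUTRI("protein", "g"),
            _NUTRI("fat", "g"), _NUTRI("carbohydrates", "g"),
            _NUTRI("fiber", "g"), _NUTRI("sodium", "mg"),
            ParameterSpec("carbon_footprint", "kg CO2eq", "environmental"),
            ParameterSpec("price", "EUR", "economic"),
        ),
        "food_groups": (),
        "objectives": ("price", "carbon_footprint"),
    },
    "school_lunch_it": {
        "meals": ("lunch",),
        "days": _WORKWEEK,
        "weeks": 4,
        "use_group_sizes": {
            ("lunch", "first"): 33,
            ("lunch", "second"): 48,
            ("lunch", "side"): 23,
            ("lunch", "bread"): 1,
            ("lunch", "fruit"): 1,
        },
        "parameters": (
            _NUTRI("energy", "kcal"), _NUTRI("protein", "g"),
            _NUTRI("fat", "g"), _NUTRI("carbohydrates", "g"),
            _NUTRI("sugar", "g"), _NUTRI("fiber", "g"),
            _NUTRI("sodium", "mg"),
            ParameterSpec("carbon_footprint", "kg CO2eq", "environmental"),
            ParameterSpec("water_footprint", "m3", "environmental"),
        ),
        "food_groups": (
            "pasta", "tomato pasta", "no tomato pasta", "rice", "meat",
            "fish", "eggs", "dairy", "potatoes", "legumes", "salads",
            "vegetables",
        ),
        "objectives": ("carbon_footprint", "water_footprint"),
    },
    "nursing_home_it": {
        "meals": ("breakfast", "lunch", "dinner"),
        "days": _FULLWEEK,
        "weeks": 2,
        "use_group_sizes": {
            ("breakfast", "cereals"): 8,
            ("breakfast", "beverages"): 5,
            ("breakfast", "sweeteners"): 4,
            ("lunch", "first"): 47,
            ("lunch", "second"): 55,
            ("lunch", "side"): 15,
            ("lunch", "bread"): 2,
            ("lunch", "fruit"): 9,
        },
        "parameters": (
            _NUTRI("energy", "kcal"), _NUTRI("protein", "g"),
            _NUTRI("fat", "g"), _NUTRI("carbohydrates", "g"),
            _NUTRI("sugar", "g"),
            ParameterSpec("carbon_footprint", "kg CO2eq", "environmental"),
            ParameterSpec("price", "EUR", "economic"),
        ),
        "food_groups": (
            "pasta", "rice", "soup", "red meat", "white meat",
            "processed meat", "fish", "eggs", "cheese", "potatoes",
            "legumes", "zucchini", "spinaches", "eggplants", "mushrooms",
            "artichokes", "tomatoes", "tuna fish",
        ),
        "objectives": ("price", "carbon_footprint"),
    },
    "custom": {
        "meals": ("lunch",),
        "days": ("mon", "tue"),
        "weeks": 1,
        "use_group_sizes": {
            ("lunch", "first"): 2,
            ("lunch", "second"): 2,
        },
        "parameters": (
            _NUTRI("energy", "kcal"), _NUTRI("protein", "g"),
            ParameterSpec("carbon_footprint", "kg CO2eq", "environmental"),
            ParameterSpec("price", "EUR", "economic"),
        ),
        "food_groups": ("meat", "fish", "legumes", "vegetables"),
        "objectives": ("price", "carbon_footprint"),
    },
}

# Per-portion distribution centres by use group: (energy kcal, protein g,
# fat g, carbohydrate g, sugar g, fiber g, sodium mg, CF kg, WF m3, EUR).
_GROUP_MEANS: dict[str, dict[str, float]] = {
    "starter":    dict(energy=180, protein=6, fat=5, carbohydrates=26,
                       sugar=4, fiber=2.5, sodium=120, carbon_footprint=0.35,
                       water_footprint=0.30, price=0.60),
    "first":      dict(energy=200, protein=7, fat=6, carbohydrates=30,
                       sugar=4, fiber=2.5, sodium=150, carbon_footprint=0.40,
                       water_footprint=0.35, price=0.70),
    "main":       dict(energy=250, protein=18, fat=12, carbohydrates=8,
                       sugar=2, fiber=1.5, sodium=300, carbon_footprint=1.20,
                       water_footprint=1.10, price=1.60),
    "second":     dict(energy=230, protein=17, fat=11, carbohydrates=6,
                       sugar=2, fiber=1.2, sodium=280, carbon_footprint=1.10,
                       water_footprint=1.00, price=1.50),
    "side":       dict(energy=80, protein=2.5, fat=3, carbohydrates=10,
                       sugar=3, fiber=3.0, sodium=60, carbon_footprint=0.20,
                       water_footprint=0.15, price=0.45),
    "dessert":    dict(energy=110, protein=2, fat=3, carbohydrates=18,
                       sugar=14, fiber=1.0, sodium=30, carbon_footprint=0.25,
                       water_footprint=0.35, price=0.50),
    "bread":      dict(energy=130, protein=4, fat=1, carbohydrates=26,
                       sugar=1, fiber=1.5, sodium=200, carbon_footprint=0.10,
                       water_footprint=0.15, price=0.20),
    "fruit":      dict(energy=70, protein=0.8, fat=0.3, carbohydrates=16,
                       sugar=13, fiber=2.5, sodium=3, carbon_footprint=0.08,
                       water_footprint=0.12, price=0.35),
    "cereals":    dict(energy=160, protein=4, fat=2, carbohydrates=32,
                       sugar=8, fiber=2.0, sodium=150, carbon_footprint=0.15,
                       water_footprint=0.20, price=0.30),
    "beverages":  dict(energy=80, protein=4, fat=3, carbohydrates=8,
                       sugar=8, fiber=0.0, sodium=50, carbon_footprint=0.20,
                       water_footprint=0.15, price=0.25),
    "sweeteners": dict(energy=40, protein=0.1, fat=0.0, carbohydrates=10,
                       sugar=10, fiber=0.0, sodium=1, carbon_footprint=0.03,
                       water_footprint=0.03, price=0.10),
}

# Carbon-footprint multipliers by food group, following the qualitative
# ordering of life-cycle assessments: ruminant meat far above plant foods.
_FOOD_GROUP_CF = {
    "red meat": 4.0, "processed meat": 3.0, "meat": 2.5, "white meat": 1.6,
    "cheese": 2.2, "dairy": 1.8, "fish": 1.8, "tuna fish": 1.8, "eggs": 1.2,
    "rice": 1.3, "pasta": 1.0, "tomato pasta": 1.0, "no tomato pasta": 1.0,
    "soup": 0.8, "potatoes": 0.6, "legumes": 0.4, "salads": 0.4,
    "vegetables": 0.5, "zucchini": 0.5, "spinaches": 0.5, "eggplants": 0.5,
    "mushrooms": 0.7, "artichokes": 0.5, "tomatoes": 0.5,
}

_PROTEIN_GROUPS = ("red meat", "white meat", "processed meat", "meat",
                   "fish", "tuna fish", "eggs", "cheese", "dairy", "legumes")
_VEG_GROUPS = ("potatoes", "salads", "vegetables", "zucchini", "spinaches",
               "eggplants", "mushrooms", "artichokes", "tomatoes", "soup")
_STARCH_GROUPS = ("pasta", "tomato pasta", "no tomato pasta", "rice")

_SPREAD = 0.25  # relative sd of nutrient distributions at noise=1
_CALIBRATION_MENUS = 200
_CALIBRATION_RETRIES = 3


@dataclass
class Scenario:
    """A generated scenario: table, grid, constraint configuration and the
    objectives the template exercises."""

    spec: ScenarioSpec
    table: RecipeTable
    grid: PlanGrid
    composition: list[CompositionRule]
    quantity_bounds: list[QuantityBound | MealShareBound]
    rate_bounds: list[RateBound]
    objectives: tuple[str, ...]

    def build_system(self) -> ConstraintSystem:
        system = ConstraintSystem(self.grid, self.table)
        system.add_composition(self.composition)
        for b in self.quantity_bounds:
            system.add_quantity_bound(b)
        for b in self.rate_bounds:
            system.add_rate_bound(b)
        return system


def _food_group_for(rng: np.random.Generator, use_group: str,
                    inventory: tuple[str, ...]) -> tuple[str, ...]:
    if not inventory:
        return ()
    if use_group in ("second", "main"):
        pool = [g for g in inventory if g in _PROTEIN_GROUPS] or inventory
    elif use_group == "side":
        pool = [g for g in inventory if g in _VEG_GROUPS] or inventory
    elif use_group in ("first", "starter"):
        pool = [g for g in inventory
                if g in _STARCH_GROUPS + ("soup", "legumes")] or inventory
    else:
        return ()
    return (pool[int(rng.integers(len(pool)))],)


def _draw_dish(rng: np.random.Generator, dish_id: str, meal: str,
               use_group: str, food_groups: tuple[str, ...],
               parameters: tuple[ParameterSpec, ...],
               noise: float) -> Dish:
    means = _GROUP_MEANS[use_group]
    cf_mult = max((_FOOD_GROUP_CF.get(g, 1.0) for g in food_groups),
                  default=1.0)
    params = {}
    for spec in parameters:
        mu = means[spec.name]
        if spec.name in ("carbon_footprint", "water_footprint", "price"):
            if spec.name == "carbon_footprint":
                mu = mu * cf_mult
            # log-normal: right-skewed, strictly positive
            sigma = 0.4 * noise
            val = float(rng.lognormal(math.log(max(mu, 1e-6)) - sigma ** 2 / 2,
                                      sigma))
        else:
            sd = _SPREAD * noise * mu
            val = max(0.0, float(rng.normal(mu, sd)))
        params[spec.name] = round(val, 4)
    portion = round(float(rng.normal(180, 40)), 1)
    return Dish(
        id=dish_id,
        name=f"{use_group} {dish_id.split('-')[-1]}",
        portion_g=max(portion, 30.0),
        params=params,
        use_groups=frozenset({use_group}),
        food_groups=frozenset(food_groups),
    )


def _random_menu(rng: np.random.Generator, grid: PlanGrid,
                 table: RecipeTable,
                 rules: list[CompositionRule]) -> Menu:
    """One uniform composition-valid menu, drawn rule by rule."""
    menu = Menu(grid, table)
    by_meal: dict[str, list[CompositionRule]] = {}
    for r in rules:
        by_meal.setdefault(r.meal_label, []).append(r)
    for slot in grid.slots():
        ids: set[str] = set()
        for rule in by_meal.get(slot.meal, []):
            members = table.use_groups[rule.use_group]
            picks = rng.choice(len(members), size=rule.exact_count,
                               replace=False)
            ids.update(members[int(k)] for k in picks)
        if ids:
            menu.assignment[slot] = frozenset(ids)
    return menu


def generate(spec: ScenarioSpec) -> Scenario:
    """Generate a scenario: recipe table, plan grid, and a constraint
    configuration calibrated to be feasible.

    Day-scope quantity bounds are set to the interquartile range of the
    per-day totals of random composition-valid menus, which places feasible
    points strictly inside the box; feasibility is then verified by one
    solve.  If verification fails the calibration is re-drawn a bounded
    number of times before an explicit error is raised.
    """
    resolved = spec.resolved()

    for attempt in range(_CALIBRATION_RETRIES):
        rng = np.random.default_rng(
            [spec.seed & 0x7FFFFFFF, 2718, attempt]
        )
        grid = PlanGrid(resolved.meals, resolved.days, resolved.weeks)

        dishes = []
        rules = []
        for (meal, group), size in sorted(resolved.use_group_sizes.items()):
            if meal not in grid.meals:
                continue
            for k in range(size):
                fg = _food_group_for(rng, group, resolved.food_groups)
                dishes.append(_draw_dish(
                    rng, f"{meal[:2]}-{group}-{k:02d}", meal, group, fg,
                    resolved.parameters, spec.noise,
                ))
            rules.append(CompositionRule(use_group=group, meal_label=meal,
                                         exact_count=1))
        # lunch/dinner share one dish pool in the full-board template
        if "dinner" in grid.meals and not any(
                m == "dinner" for (m, _g) in resolved.use_group_sizes):
            for (meal, group), size in sorted(
                    resolved.use_group_sizes.items()):
                if meal == "lunch":
                    rules.append(CompositionRule(
                        use_group=group, meal_label="dinner", exact_count=1,
                    ))
        table = RecipeTable(dishes, resolved.parameters)

        # calibrate day-scope boxes on random composition-valid menus:
        # pool the per-day totals of every sampled menu per parameter
        nutritional = [p.name for p in resolved.parameters
                       if p.category == "nutritional"]
        day_scopes = Scope.instances(grid, "day")
        coef = np.stack([
            quantity_coefficients(grid, table, pname, sc)
            for pname in nutritional for sc in day_scopes
        ])  # (n_params * n_days, n_binary)
        xs = np.stack([
            _random_menu(rng, grid, table, rules).to_vector()
            for _ in range(_CALIBRATION_MENUS)
        ])
        totals = xs @ coef.T  # (menus, n_params * n_days)
        n_days = len(day_scopes)

        quantity_bounds: list[QuantityBound | MealShareBound] = []
        for pi, pname in enumerate(nutritional):
            block = totals[:, pi * n_days:(pi + 1) * n_days].ravel()
            lo, hi = np.quantile(block, [0.25, 0.75])
            quantity_bounds.append(QuantityBound(
                parameter=pname, scope_level="day",
                lower=round(float(lo), 2), upper=round(float(hi), 2),
            ))
        if "breakfast" in grid.meals:
            quantity_bounds.append(MealShareBound(
                parameter="energy", meal_label="breakfast",
                min_fraction=0.10,
            ))

        rate_bounds: list[RateBound] = []
        if "red meat" in table.food_groups:
            rate_bounds.append(RateBound(target="red meat",
                                         scope_level="week", max_count=3))

        scenario = Scenario(spec=spec, table=table, grid=grid,
                            composition=rules,
                            quantity_bounds=quantity_bounds,
                            rate_bounds=rate_bounds,
                            objectives=resolved.objectives)
        full = scenario.build_system()
        # zero-objective probe: the backend stops at the first feasible
        # menu, so verification cost does not depend on objective hardness
        probe = ObjectiveSpec(((resolved.objectives[0], 0.0),))
        res = solve(full, probe, method="backend")
        if res.status == "optimal":
            return scenario

    raise InfeasibleScenarioError(
        f"could not calibrate a feasible scenario for template "
        f"{spec.template!r} with seed {spec.seed} after "
        f"{_CALIBRATION_RETRIES} attempts"
    )


def shrink(spec: ScenarioSpec, factor: float) -> ScenarioSpec:
    """Scale use-group sizes and weeks down by ``factor`` (ceil, floor 1),
    preserving the template structure; used to create exhaustively
    enumerable instances."""
    if not 0 < factor <= 1:
        raise InvalidConfigError(f"factor must be in (0,1], got {factor}")
    resolved = spec.resolved()
    sizes = tuple(
        (k, max(1, math.ceil(v * factor)))
        for k, v in sorted(resolved.use_group_sizes.items())
    )
    weeks = max(1, math.ceil(resolved.weeks * factor))
    return replace(spec, use_group_sizes=sizes, weeks=weeks,
                   meals=resolved.meals, days=resolved.days)
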