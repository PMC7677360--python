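"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's constraint-row and solver
machinery: feasibility is re-derived from the dish parameter dicts and
group memberships directly, and optimisation is exhaustive enumeration of
composition-valid menus.
"""

from __future__ import annotations

import itertools
from typing import Iterator

import pytest

from menuplan import (
    CompositionRule,
    ConstraintSystem,
    Dish,
    Menu,
    PlanGrid,
    QuantityBound,
    RateBound,
    RecipeTable,
)


@pytest.fixture
def toy_table() -> RecipeTable:
    """Six dishes: two first courses, two second courses, two sides."""
    rows = [
        ("d0", "penne al pomodoro", "first", "pasta", 200.0, 1.00, 0.40),
        ("d1", "risotto", "first", "rice", 250.0, 2.00, 0.55),
        ("d2", "beef stew", "second", "red meat", 300.0, 3.00, 2.50),
        ("d3", "baked cod", "second", "fish", 280.0, 1.50, 1.10),
        ("d4", "green salad", "side", "vegetables", 90.0, 0.50, 0.15),
        ("d5", "lentils", "side", "legumes", 80.0, 0.70, 0.10),
    ]
    dishes = [
        Dish(i, name, 150.0,
             {"energy": e, "price": p, "carbon_footprint": cf},
             {ug}, {fg})
        for i, name, ug, fg, e, p, cf in rows
    ]
    return RecipeTable(dishes)


@pytest.fixture
def toy_grid() -> PlanGrid:
    return PlanGrid(["lunch"], ["mon", "tue"], 1)


@pytest.fixture
def toy_rules() -> list[CompositionRule]:
    return [CompositionRule(g, "lunch") for g in ("first", "second", "side")]


@pytest.fixture
def toy_system(toy_grid, toy_table, toy_rules) -> ConstraintSystem:
    system = ConstraintSystem(toy_grid, toy_table)
    system.add_composition(toy_rules)
    return system


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def enumerate_composition_menus(grid: PlanGrid, table: RecipeTable,
                                rules: list[CompositionRule]
                                ) -> Iterator[Menu]:
    """Every menu that serves exactly the rule-required dishes per slot,
    enumerated by direct product over slots (no solver code involved)."""
    per_slot = []
    for slot in grid.slots():
        applicable = [r for r in rules if r.meal_label == slot.meal]
        if not applicable:
            per_slot.append([frozenset()])
            continue
        per_rule = [
            list(itertools.combinations(sorted(table.use_groups[r.use_group]),
                                        r.exact_count))
            for r in applicable
        ]
        cands = []
        for combo in itertools.product(*per_rule):
            ids = [d for part in combo for d in part]
            if len(set(ids)) == len(ids):
                cands.append(frozenset(ids))
        per_slot.append(cands)
    for choice in itertools.product(*per_slot):
        menu = Menu(grid, table)
        for slot, ids in zip(grid.slots(), choice):
            if ids:
                menu.assignment[slot] = ids
        yield menu


def direct_quantity(menu: Menu, parameter: str, slots) -> float:
    """Quantity oracle: plain sum over dish parameter dicts."""
    return sum(
        menu.table.dish(i).params[parameter]
        for slot in slots
        for i in menu.dishes_at(slot)
    )


def direct_rate(menu: Menu, target: str, slots) -> int:
    """Rate oracle: direct membership counting from the dish objects."""
    n = 0
    for slot in slots:
        for i in menu.dishes_at(slot):
            dish = menu.table.dish(i)
            if (i == target or target in dish.use_groups
                    or target in dish.food_groups):
                n += 1
    return n


def menu_satisfies(menu: Menu, quantity_bounds: list[QuantityBound],
                   rate_bounds: list[RateBound],
                   tol: float = 1e-9) -> bool:
    """Feasibility oracle evaluated straight from the definitions."""
    grid = menu.grid
    for b in quantity_bounds:
        for slots in _scope_slot_sets(grid, b.scope_level):
            q = direct_quantity(menu, b.parameter, slots)
            if b.lower is not None and q < b.lower - tol:
                return False
            if b.upper is not None and q > b.upper + tol:
                return False
    for b in rate_bounds:
        for slots in _scope_slot_sets(grid, b.scope_level):
            r = direct_rate(menu, b.target, slots)
            if b.min_count is not None and r < b.min_count:
                return False
            if b.max_count is not None and r > b.max_count:
                return False
    return True


def _scope_slot_sets(grid: PlanGrid, level: str):
    slots = grid.slots()
    if level == "plan":
        return [slots]
    if level == "week":
        return [
            [s for s in slots if s.week == w]
            for w in range(1, grid.weeks + 1)
        ]
    if level == "day":
        return [
            [s for s in slots if (s.day, s.week) == (d, w)]
            for w in range(1, grid.weeks + 1)
            for d in grid.days
        ]
    return [[s] for s in slots]
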