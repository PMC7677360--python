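"""Slot lattice, dishes, menus, and the linear aggregates they induce.

A meal plan assigns fixed-portion dishes to *slots*, where a slot is one
meal position identified by (meal, day, week).  Every dish carries a vector
of per-portion parameter values (energy, nutrients, footprints, price) and
belongs to *use groups* (its role in a meal: first course, dessert, ...)
and *food groups* (its ingredient category: pasta, red meat, ...).

Two linear aggregates are the building blocks of every constraint and
objective:

* the *quantity* ``Q^p`` of a parameter ``p`` over a scope — the sum of
  per-portion values of the dishes served inside that scope;
* the *rate* ``R`` of a dish or group over a scope — the number of servings
  of it inside that scope.

Both are linear in the 0/1 assignment vector, which is what makes the whole
design problem a binary integer linear program.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

MEAL_LABELS = (
    "breakfast",
    "mid-morning snack",
    "lunch",
    "mid-afternoon snack",
    "dinner",
)
DAY_LABELS = ("mon", "tue", "wed", "thu", "fri", "sat", "sun")

PARAMETER_CATEGORIES = ("nutritional", "environmental", "economic")


class MenuPlanError(Exception):
    """Base class for all errors raised by this package."""


class InvalidGridError(MenuPlanError):
    """Plan grid dimensions or labels are invalid."""


class InvalidConfigError(MenuPlanError):
    """A configuration object violates its invariants."""


class UndefinedParameterError(MenuPlanError):
    """A parameter name is not defined for the dishes of a table."""


class UndefinedGroupError(MenuPlanError):
    """A dish id / use group / food group is unknown to the table."""


class TableValidationError(MenuPlanError):
    """A recipe table failed validation; ``problems`` lists every issue."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            "recipe table invalid (%d problem%s):\n  %s"
            % (len(self.problems), "s" if len(self.problems) != 1 else "",
               "\n  ".join(self.problems))
        )


@dataclass(frozen=True, order=True)
class Slot:
    """One meal position: the meal *m* of the day *d* of the week *w*."""

    meal: str
    day: str
    week: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.meal}/{self.day}/w{self.week}"


class PlanGrid:
    """The slot lattice: meal set M, day set D, and number of weeks N_W.

    Iteration order is deterministic and week-major: week, then day, then
    meal.  Slot count is ``N_M * N_D * N_W``.
    """

    def __init__(self, meals: Sequence[str], days: Sequence[str], weeks: int):
        meals = tuple(meals)
        days = tuple(days)
        if not meals or not days or weeks < 1:
            raise InvalidGridError(
                f"grid needs >=1 meal, >=1 day, >=1 week; got "
                f"{len(meals)} meals, {len(days)} days, {weeks} weeks"
            )
        bad_meals = [m for m in meals if m not in MEAL_LABELS]
        if bad_meals:
            raise InvalidGridError(f"unknown meal labels: {bad_meals}")
        bad_days = [d for d in days if d not in DAY_LABELS]
        if bad_days:
            raise InvalidGridError(f"unknown day labels: {bad_days}")
        if len(set(meals)) != len(meals) or len(set(days)) != len(days):
            raise InvalidGridError("meal/day labels must be unique")
        self.meals = meals
        self.days = days
        self.weeks = int(weeks)
        self._slots = tuple(
            Slot(m, d, w)
            for w in range(1, self.weeks + 1)
            for d in self.days
            for m in self.meals
        )
        self._index = {s: i for i, s in enumerate(self._slots)}

    @property
    def n_meals(self) -> int:
        return len(self.meals)

    @property
    def n_days(self) -> int:
        return len(self.days)

    @property
    def n_weeks(self) -> int:
        return self.weeks

    @property
    def n_slots(self) -> int:
        return len(self._slots)

    def slots(self) -> tuple[Slot, ...]:
        return self._slots

    def slot_index(self, slot: Slot) -> int:
        try:
            return self._index[slot]
        except KeyError:
            raise InvalidGridError(f"slot {slot} not on grid") from None

    def __contains__(self, slot: Slot) -> bool:
        return slot in self._index

    def __iter__(self) -> Iterator[Slot]:
        return iter(self._slots)

    def __repr__(self) -> str:
        return (
            f"PlanGrid(meals={list(self.meals)}, days={list(self.days)}, "
            f"weeks={self.weeks})"
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PlanGrid)
            and self.meals == other.meals
            and self.days == other.days
            and self.weeks == other.weeks
        )

    def __hash__(self) -> int:
        return hash((self.meals, self.days, self.weeks))


@dataclass(frozen=True)
class ParameterSpec:
    """Declares a dish parameter: its name, unit, and category."""

    name: str
    unit: str
    category: str = "nutritional"

    def __post_init__(self):
        if not self.name:
            raise InvalidConfigError("parameter name must be non-empty")
        if not self.unit:
            raise InvalidConfigError(f"parameter {self.name!r}: unit empty")
        if self.category not in PARAMETER_CATEGORIES:
            raise InvalidConfigError(
                f"parameter {self.name!r}: category {self.category!r} not in "
                f"{PARAMETER_CATEGORIES}"
            )


@dataclass(frozen=True)
class Dish:
    """A fixed-portion recipe with its parameter vector and memberships."""

    id: str
    name: str
    portion_g: float
    params: Mapping[str, float]
    use_groups: frozenset[str]
    food_groups: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "params", dict(self.params))
        object.__setattr__(self, "use_groups", frozenset(self.use_groups))
        object.__setattr__(self, "food_groups", frozenset(self.food_groups))


class RecipeTable:
    """A validated collection of dishes sharing one parameter inventory.

    All dishes must define the same parameter names (units are fixed per
    parameter and never converted); every dish must have at least one use
    group; ids must be unique.  Validation collects *all* problems before
    raising, so a malformed file reports every offence at once.
    """

    def __init__(self, dishes: Sequence[Dish],
                 parameter_specs: Sequence[ParameterSpec] | None = None):
        dishes = list(dishes)
        problems: list[str] = []
        if not dishes:
            problems.append("table is empty")
        seen: dict[str, int] = {}
        for row, dish in enumerate(dishes):
            if dish.id in seen:
                problems.append(
                    f"duplicate dish id {dish.id!r} (rows {seen[dish.id]} "
                    f"and {row})"
                )
            else:
                seen[dish.id] = row
            if not dish.use_groups:
                problems.append(f"dish {dish.id!r}: no use group")
            for p, v in dish.params.items():
                if not math.isfinite(v):
                    problems.append(f"dish {dish.id!r}: parameter {p!r} "
                                    f"is not finite ({v})")
        if dishes:
            ref = set(dishes[0].params)
            for dish in dishes[1:]:
                if set(dish.params) != ref:
                    missing = ref - set(dish.params)
                    extra = set(dish.params) - ref
                    problems.append(
                        f"dish {dish.id!r}: parameter set differs from "
                        f"{dishes[0].id!r} (missing {sorted(missing)}, "
                        f"extra {sorted(extra)})"
                    )
        if parameter_specs is not None:
            names = [s.name for s in parameter_specs]
            if len(set(names)) != len(names):
                problems.append("duplicate parameter spec names")
            if dishes:
                declared = set(names)
                present = set(dishes[0].params)
                if declared - present:
                    problems.append(
                        f"declared parameters missing from dishes: "
                        f"{sorted(declared - present)}"
                    )
        if problems:
            raise TableValidationError(problems)

        self.dishes: tuple[Dish, ...] = tuple(dishes)
        self._by_id = {d.id: i for i, d in enumerate(self.dishes)}
        self.parameters: tuple[str, ...] = tuple(sorted(dishes[0].params))
        self.parameter_specs = tuple(parameter_specs or ())
        self.use_groups: dict[str, tuple[str, ...]] = {}
        self.food_groups: dict[str, tuple[str, ...]] = {}
        for d in self.dishes:
            for g in sorted(d.use_groups):
                self.use_groups.setdefault(g, ())
            for g in sorted(d.food_groups):
                self.food_groups.setdefault(g, ())
        for g in self.use_groups:
            self.use_groups[g] = tuple(
                d.id for d in self.dishes if g in d.use_groups
            )
        for g in self.food_groups:
            self.food_groups[g] = tuple(
                d.id for d in self.dishes if g in d.food_groups
            )

    @property
    def n_dishes(self) -> int:
        return len(self.dishes)

    def dish(self, dish_id: str) -> Dish:
        try:
            return self.dishes[self._by_id[dish_id]]
        except KeyError:
            raise UndefinedGroupError(f"unknown dish id {dish_id!r}") from None

    def dish_index(self, dish_id: str) -> int:
        try:
            return self._by_id[dish_id]
        except KeyError:
            raise UndefinedGroupError(f"unknown dish id {dish_id!r}") from None

    def __contains__(self, dish_id: str) -> bool:
        return dish_id in self._by_id

    def param_vector(self, parameter: str) -> np.ndarray:
        """Per-portion values of ``parameter`` in dish order (q_i^p)."""
        if parameter not in self.parameters:
            raise UndefinedParameterError(
                f"parameter {parameter!r} not defined; table has "
                f"{list(self.parameters)}"
            )
        return np.array([d.params[parameter] for d in self.dishes])

    def members(self, target: str) -> tuple[str, ...]:
        """Dish ids matching ``target``: a dish id, use group or food group."""
        if target in self._by_id:
            return (target,)
        if target in self.use_groups:
            return self.use_groups[target]
        if target in self.food_groups:
            return self.food_groups[target]
        raise UndefinedGroupError(
            f"{target!r} is not a dish id, use group or food group"
        )


@dataclass(frozen=True)
class Scope:
    """A slice of the plan: one meal, one day, one week, or the whole plan.

    ``selector`` fixes the indices the level requires: (meal, day, week)
    for level "meal", (day, week) for "day", (week,) for "week", and ()
    for "plan".
    """

    level: str
    selector: tuple = ()

    _ARITY = {"meal": 3, "day": 2, "week": 1, "plan": 0}

    def __post_init__(self):
        if self.level not in self._ARITY:
            raise InvalidConfigError(f"unknown scope level {self.level!r}")
        object.__setattr__(self, "selector", tuple(self.selector))
        if len(self.selector) != self._ARITY[self.level]:
            raise InvalidConfigError(
                f"scope level {self.level!r} needs "
                f"{self._ARITY[self.level]} selector indices, got "
                f"{len(self.selector)}"
            )

    @classmethod
    def meal(cls, meal: str, day: str, week: int) -> "Scope":
        return cls("meal", (meal, day, week))

    @classmethod
    def day(cls, day: str, week: int) -> "Scope":
        return cls("day", (day, week))

    @classmethod
    def week(cls, week: int) -> "Scope":
        return cls("week", (week,))

    @classmethod
    def plan(cls) -> "Scope":
        return cls("plan", ())

    def contains(self, slot: Slot) -> bool:
        if self.level == "plan":
            return True
        if self.level == "week":
            return slot.week == self.selector[0]
        if self.level == "day":
            return (slot.day, slot.week) == self.selector
        return (slot.meal, slot.day, slot.week) == self.selector

    @staticmethod
    def instances(grid: PlanGrid, level: str) -> list["Scope"]:
        """All scopes of ``level`` on ``grid``, in deterministic grid order."""
        if level == "plan":
            return [Scope.plan()]
        if level == "week":
            return [Scope.week(w) for w in range(1, grid.weeks + 1)]
        if level == "day":
            return [
                Scope.day(d, w)
                for w in range(1, grid.weeks + 1)
                for d in grid.days
            ]
        if level == "meal":
            return [Scope.meal(s.meal, s.day, s.week) for s in grid.slots()]
        raise InvalidConfigError(f"unknown scope level {level!r}")


class Menu:
    """A 0/1 assignment of dishes to slots — the decision object.

    A slot may hold any set of dishes; the one-dish-per-course structure is
    enforced by composition constraints, not by this type.  The menu is
    representable as a dense 0/1 vector of length ``n_slots * n_dishes``
    with flat index ``slot_index * n_dishes + dish_index`` (week-major slot
    order).
    """

    def __init__(self, grid: PlanGrid, table: RecipeTable,
                 assignment: Mapping[Slot, Iterable[str]] | None = None):
        self.grid = grid
        self.table = table
        self.assignment: dict[Slot, frozenset[str]] = {}
        if assignment:
            for slot, dish_ids in assignment.items():
                ids = frozenset(dish_ids)
                if slot not in grid:
                    raise InvalidGridError(f"slot {slot} not on grid")
                for i in ids:
                    if i not in table:
                        raise UndefinedGroupError(
                            f"dish {i!r} assigned but not in table"
                        )
                if ids:
                    self.assignment[slot] = ids

    def dishes_at(self, slot: Slot) -> frozenset[str]:
        return self.assignment.get(slot, frozenset())

    def assign(self, slot: Slot, dish_ids: Iterable[str]) -> None:
        ids = frozenset(dish_ids)
        if slot not in self.grid:
            raise InvalidGridError(f"slot {slot} not on grid")
        for i in ids:
            if i not in self.table:
                raise UndefinedGroupError(f"dish {i!r} not in table")
        if ids:
            self.assignment[slot] = ids
        else:
            self.assignment.pop(slot, None)

    def n_servings(self) -> int:
        return sum(len(v) for v in self.assignment.values())

    def to_vector(self) -> np.ndarray:
        n = self.table.n_dishes
        x = np.zeros(self.grid.n_slots * n)
        for slot, ids in self.assignment.items():
            base = self.grid.slot_index(slot) * n
            for i in ids:
                x[base + self.table.dish_index(i)] = 1.0
        return x

    @classmethod
    def from_vector(cls, grid: PlanGrid, table: RecipeTable,
                    x: np.ndarray) -> "Menu":
        n = table.n_dishes
        if len(x) != grid.n_slots * n:
            raise InvalidConfigError(
                f"vector length {len(x)} != {grid.n_slots * n}"
            )
        menu = cls(grid, table)
        for s_idx, slot in enumerate(grid.slots()):
            ids = [
                table.dishes[d].id
                for d in range(n)
                if x[s_idx * n + d] > 0.5
            ]
            if ids:
                menu.assignment[slot] = frozenset(ids)
        return menu

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Menu)
            and self.grid == other.grid
            and self.assignment == other.assignment
        )

    def __hash__(self) -> int:
        return hash((self.grid, frozenset(self.assignment.items())))


# ---------------------------------------------------------------------------
# Counting operations
# ---------------------------------------------------------------------------

def count_variables(grid: PlanGrid, n_dishes: int) -> int:
    """Number of binary decision variables: N * N_M * N_D * N_W."""
    if n_dishes < 1:
        raise InvalidGridError(f"need >=1 dish, got {n_dishes}")
    return n_dishes * grid.n_slots


def count_meal_combinations(use_group_sizes: Sequence[int]) -> int:
    """Distinct meals when exactly one dish is drawn from each use group."""
    sizes = list(use_group_sizes)
    if not sizes:
        raise InvalidConfigError("need at least one use group size")
    if any(s < 1 for s in sizes):
        raise InvalidConfigError(f"group sizes must be >=1, got {sizes}")
    return math.prod(sizes)


# ---------------------------------------------------------------------------
# Linear aggregates
# ---------------------------------------------------------------------------

def aggregate_quantity(menu: Menu, parameter: str, scope: Scope) -> float:
    """Quantity Q^p of ``parameter`` summed over all servings in ``scope``."""
    if parameter not in menu.table.parameters:
        raise UndefinedParameterError(
            f"parameter {parameter!r} not defined for this table"
        )
    total = 0.0
    for slot, ids in menu.assignment.items():
        if scope.contains(slot):
            for i in ids:
                total += menu.table.dish(i).params[parameter]
    return total


def aggregate_rate(menu: Menu, target: str, scope: Scope) -> int:
    """Rate R: servings of ``target`` (dish id or group) within ``scope``."""
    members = set(menu.table.members(target))
    count = 0
    for slot, ids in menu.assignment.items():
        if scope.contains(slot):
            count += len(ids & members)
    return count


def quantity_coefficients(grid: PlanGrid, table: RecipeTable,
                          parameter: str, scope: Scope) -> np.ndarray:
    """Coefficient vector c with Q^p(menu) = c . x for scoped quantity."""
    q = table.param_vector(parameter)
    n = table.n_dishes
    c = np.zeros(grid.n_slots * n)
    for s_idx, slot in enumerate(grid.slots()):
        if scope.contains(slot):
            c[s_idx * n:(s_idx + 1) * n] = q
    return c


def rate_coefficients(grid: PlanGrid, table: RecipeTable,
                      target: str, scope: Scope) -> np.ndarray:
    """Coefficient vector c with R(menu) = c . x for scoped rate."""
    members = [table.dish_index(i) for i in table.members(target)]
    n = table.n_dishes
    c = np.zeros(grid.n_slots * n)
    for s_idx, slot in enumerate(grid.slots()):
        if scope.contains(slot):
            for d in members:
                c[s_idx * n + d] = 1.0
    return c
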