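"""Linear constraint system defining the feasible set of menus.

Three constraint families mirror how dietary recommendations, cultural meal
structure and variety requirements are written in practice:

* **quantity bounds** — box constraints ``L_p <= Q^p <= U_p`` on a
  parameter aggregate at meal/day/week/plan scope (dietary reference
  intakes, footprint caps, budget caps);
* **rate bounds** — integer bounds on how often a dish or a food/use group
  may be served within a scope (e.g. red meat at most 3 times a week);
* **composition rules** — equalities forcing the cultural meal structure
  (exactly one first course, one second course, one side dish per lunch).

A daily energy *share* rule (e.g. breakfast must provide at least 10% of
the day's energy) is also linear once rearranged:
``Q_breakfast - frac * Q_day >= 0``.

Bounds may be *hard* (mandatory) or *soft*: a soft bound side is relaxed
with a nonnegative continuous deviation variable that measures by how much
the bound is missed and is penalised in the objective (goal-programming
style).  Softening never shrinks the feasible set: any menu feasible under
the hard bound is feasible under the softened form with zero deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .plan_model import (
    InvalidConfigError,
    Menu,
    PlanGrid,
    RecipeTable,
    Scope,
    UndefinedGroupError,
    quantity_coefficients,
    rate_coefficients,
)

SCOPE_LEVELS = ("meal", "day", "week", "plan")


@dataclass(frozen=True)
class QuantityBound:
    """Box constraint on a parameter quantity at some scope level."""

    parameter: str
    scope_level: str
    lower: float | None = None
    upper: float | None = None
    mode: str = "hard"
    soft_weight_lower: float = 1.0
    soft_weight_upper: float = 1.0

    def __post_init__(self):
        if self.scope_level not in SCOPE_LEVELS:
            raise InvalidConfigError(
                f"scope_level {self.scope_level!r} not in {SCOPE_LEVELS}"
            )
        if self.lower is None and self.upper is None:
            raise InvalidConfigError(
                f"quantity bound on {self.parameter!r}: neither side present"
            )
        if (self.lower is not None and self.upper is not None
                and self.lower > self.upper):
            raise InvalidConfigError(
                f"quantity bound on {self.parameter!r}: lower {self.lower} > "
                f"upper {self.upper}"
            )
        if self.mode not in ("hard", "soft"):
            raise InvalidConfigError(f"mode {self.mode!r} not hard/soft")
        if self.soft_weight_lower < 0 or self.soft_weight_upper < 0:
            raise InvalidConfigError("soft weights must be nonnegative")


@dataclass(frozen=True)
class MealShareBound:
    """Lower bound on one meal's share of the daily quantity of a parameter.

    Emits, per day, the linear row ``Q_meal - min_fraction * Q_day >= 0``.
    """

    parameter: str
    meal_label: str
    min_fraction: float

    def __post_init__(self):
        if not 0 < self.min_fraction < 1:
            raise InvalidConfigError(
                f"min_fraction must be in (0,1), got {self.min_fraction}"
            )


@dataclass(frozen=True)
class RateBound:
    """Bound on servings of a dish or group within each scope instance."""

    target: str
    scope_level: str
    min_count: int | None = None
    max_count: int | None = None

    def __post_init__(self):
        if self.scope_level not in SCOPE_LEVELS:
            raise InvalidConfigError(
                f"scope_level {self.scope_level!r} not in {SCOPE_LEVELS}"
            )
        if self.min_count is None and self.max_count is None:
            raise InvalidConfigError(
                f"rate bound on {self.target!r}: neither side present"
            )
        for side in (self.min_count, self.max_count):
            if side is not None and side < 0:
                raise InvalidConfigError("rate bounds must be nonnegative")
        if (self.min_count is not None and self.max_count is not None
                and self.min_count > self.max_count):
            raise InvalidConfigError(
                f"rate bound on {self.target!r}: min {self.min_count} > "
                f"max {self.max_count}"
            )


@dataclass(frozen=True)
class CompositionRule:
    """Exactly ``exact_count`` dishes of ``use_group`` in every slot of a
    meal type — the cultural meal-structure equality."""

    use_group: str
    meal_label: str
    exact_count: int = 1

    def __post_init__(self):
        if self.exact_count < 0:
            raise InvalidConfigError("exact_count must be >= 0")


@dataclass
class DeviationVariable:
    """Nonnegative continuous slack attached to one soft bound side."""

    provenance: str
    direction: str  # "below_lower" | "above_upper"
    weight: float = 1.0

    def __post_init__(self):
        if self.direction not in ("below_lower", "above_upper"):
            raise InvalidConfigError(f"bad direction {self.direction!r}")
        if self.weight < 0:
            raise InvalidConfigError("deviation weight must be >= 0")


@dataclass
class Row:
    """One scalar linear relation  coeffs . (x ⊕ dev)  <sense>  rhs."""

    coeffs: dict[int, float]
    sense: str  # "<=", ">=", "=="
    rhs: float
    provenance: str
    hard: bool = True

    def __post_init__(self):
        if self.sense not in ("<=", ">=", "=="):
            raise InvalidConfigError(f"bad sense {self.sense!r}")
        for v in self.coeffs.values():
            if not np.isfinite(v):
                raise InvalidConfigError(
                    f"row {self.provenance!r}: non-finite coefficient"
                )
        if not np.isfinite(self.rhs):
            raise InvalidConfigError(
                f"row {self.provenance!r}: non-finite rhs"
            )

    def value(self, extended: np.ndarray) -> float:
        return float(sum(extended[j] * c for j, c in self.coeffs.items()))


@dataclass
class Violation:
    """A hard row not satisfied by a menu, with its slack."""

    provenance: str
    sense: str
    rhs: float
    actual: float

    @property
    def slack(self) -> float:
        if self.sense == "<=":
            return self.rhs - self.actual
        if self.sense == ">=":
            return self.actual - self.rhs
        return -abs(self.actual - self.rhs)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (f"{self.provenance}: value {self.actual:g} violates "
                f"{self.sense} {self.rhs:g}")


def _scope_tag(scope: Scope) -> str:
    if scope.level == "plan":
        return "plan"
    return f"{scope.level}({','.join(str(s) for s in scope.selector)})"


def expand_quantity_bound(
    bound: QuantityBound | MealShareBound,
    grid: PlanGrid,
    table: RecipeTable,
    deviations: list[DeviationVariable] | None = None,
    n_binary: int | None = None,
) -> list[Row]:
    """Expand one quantity bound into scalar rows, one per present side per
    scope instance.  A two-sided hard bound at day scope over a 20-day plan
    therefore yields 40 rows.

    Soft mode emits one row per side carrying a fresh deviation variable
    (``Q + d >= L`` below, ``Q - d <= U`` above); the variables are
    appended to ``deviations`` and indexed after the ``n_binary`` binary
    block.
    """
    if isinstance(bound, MealShareBound):
        return _expand_meal_share(bound, grid, table)
    q = table.param_vector(bound.parameter)  # raises on unknown parameter
    n = table.n_dishes
    if n_binary is None:
        n_binary = grid.n_slots * n
    rows: list[Row] = []
    soft = bound.mode == "soft"
    if soft and deviations is None:
        raise InvalidConfigError(
            "soft bound expansion needs a deviation registry"
        )
    for scope in Scope.instances(grid, bound.scope_level):
        coeffs = {
            j: float(v)
            for j, v in enumerate(
                quantity_coefficients(grid, table, bound.parameter, scope)
            )
            if v != 0.0
        }
        tag = f"Q[{bound.parameter}]@{_scope_tag(scope)}"
        if bound.lower is not None:
            if soft:
                dev = DeviationVariable(
                    provenance=f"{tag}>={bound.lower:g}",
                    direction="below_lower",
                    weight=bound.soft_weight_lower,
                )
                idx = n_binary + len(deviations)
                deviations.append(dev)
                rows.append(Row(
                    {**coeffs, idx: 1.0}, ">=", float(bound.lower),
                    provenance=f"{tag} soft >= {bound.lower:g}", hard=False,
                ))
            else:
                rows.append(Row(
                    dict(coeffs), ">=", float(bound.lower),
                    provenance=f"{tag} >= {bound.lower:g}",
                ))
        if bound.upper is not None:
            if soft:
                dev = DeviationVariable(
                    provenance=f"{tag}<={bound.upper:g}",
                    direction="above_upper",
                    weight=bound.soft_weight_upper,
                )
                idx = n_binary + len(deviations)
                deviations.append(dev)
                rows.append(Row(
                    {**coeffs, idx: -1.0}, "<=", float(bound.upper),
                    provenance=f"{tag} soft <= {bound.upper:g}", hard=False,
                ))
            else:
                rows.append(Row(
                    dict(coeffs), "<=", float(bound.upper),
                    provenance=f"{tag} <= {bound.upper:g}",
                ))
    return rows


def _expand_meal_share(bound: MealShareBound, grid: PlanGrid,
                       table: RecipeTable) -> list[Row]:
    if bound.meal_label not in grid.meals:
        raise InvalidConfigError(
            f"meal {bound.meal_label!r} not on grid {list(grid.meals)}"
        )
    rows = []
    frac = bound.min_fraction
    for scope in Scope.instances(grid, "day"):
        day_c = quantity_coefficients(grid, table, bound.parameter, scope)
        meal_scope = Scope.meal(bound.meal_label, *scope.selector)
        meal_c = quantity_coefficients(grid, table, bound.parameter,
                                       meal_scope)
        c = meal_c - frac * day_c
        coeffs = {j: float(v) for j, v in enumerate(c) if v != 0.0}
        rows.append(Row(
            coeffs, ">=", 0.0,
            provenance=(f"Q[{bound.parameter}]@{bound.meal_label} >= "
                        f"{frac:g}*day @ {_scope_tag(scope)}"),
        ))
    return rows


def expand_composition(rules: Sequence[CompositionRule], grid: PlanGrid,
                       table: RecipeTable) -> list[Row]:
    """One equality per (rule, applicable slot):
    sum of the rule's use-group variables in that slot = exact_count."""
    rows = []
    n = table.n_dishes
    for rule in rules:
        if rule.use_group not in table.use_groups:
            raise UndefinedGroupError(
                f"use group {rule.use_group!r} not in table"
            )
        members = [table.dish_index(i)
                   for i in table.use_groups[rule.use_group]]
        if not members and rule.exact_count > 0:
            raise InvalidConfigError(
                f"composition rule on empty use group {rule.use_group!r} "
                f"would demand 0 = {rule.exact_count}"
            )
        for s_idx, slot in enumerate(grid.slots()):
            if slot.meal != rule.meal_label:
                continue
            coeffs = {s_idx * n + d: 1.0 for d in members}
            rows.append(Row(
                coeffs, "==", float(rule.exact_count),
                provenance=(f"R[{rule.use_group}]@meal({slot.meal},"
                            f"{slot.day},{slot.week}) == {rule.exact_count}"),
            ))
    return rows


def expand_rate_bound(bound: RateBound, grid: PlanGrid,
                      table: RecipeTable) -> list[Row]:
    """One inequality per present side per scope instance; min side emitted
    as >=, max side as <=.  Plan scope yields at most two rows."""
    table.members(bound.target)  # raises on unknown target
    rows = []
    for scope in Scope.instances(grid, bound.scope_level):
        coeffs = {
            j: float(v)
            for j, v in enumerate(
                rate_coefficients(grid, table, bound.target, scope)
            )
            if v != 0.0
        }
        tag = f"R[{bound.target}]@{_scope_tag(scope)}"
        if bound.min_count is not None:
            rows.append(Row(dict(coeffs), ">=", float(bound.min_count),
                            provenance=f"{tag} >= {bound.min_count}"))
        if bound.max_count is not None:
            rows.append(Row(dict(coeffs), "<=", float(bound.max_count),
                            provenance=f"{tag} <= {bound.max_count}"))
    return rows


def amdr_to_bounds(frac_low: float, frac_high: float, energy: float,
                   energy_density: float) -> tuple[float, float]:
    """Convert a macronutrient distribution range to gram bounds.

    The acceptable range is given as fractions of total energy; dividing by
    the macronutrient's energy density (4 kcal/g for carbohydrate and
    protein, 9 kcal/g for fat) yields gram bounds:
    L = frac_low * energy / density, U = frac_high * energy / density.
    """
    if not (0 <= frac_low <= frac_high <= 1):
        raise InvalidConfigError(
            f"need 0 <= frac_low <= frac_high <= 1, got "
            f"({frac_low}, {frac_high})"
        )
    if energy <= 0 or energy_density <= 0:
        raise InvalidConfigError("energy and density must be positive")
    return (frac_low * energy / energy_density,
            frac_high * energy / energy_density)


class ConstraintSystem:
    """The full linear system over (binary assignment ⊕ deviation) variables.

    Rows are appended via the ``add_*`` methods so deviation-variable
    indices stay consistent; every row is traceable to the bound or rule
    that generated it through its provenance tag.
    """

    def __init__(self, grid: PlanGrid, table: RecipeTable):
        self.grid = grid
        self.table = table
        self.rows: list[Row] = []
        self.deviations: list[DeviationVariable] = []
        self.composition_rules: list[CompositionRule] = []

    @property
    def n_binary(self) -> int:
        return self.grid.n_slots * self.table.n_dishes

    @property
    def n_deviations(self) -> int:
        return len(self.deviations)

    def add_quantity_bound(self, bound: QuantityBound | MealShareBound
                           ) -> list[Row]:
        rows = expand_quantity_bound(bound, self.grid, self.table,
                                     deviations=self.deviations,
                                     n_binary=self.n_binary)
        self.rows.extend(rows)
        return rows

    def add_rate_bound(self, bound: RateBound) -> list[Row]:
        rows = expand_rate_bound(bound, self.grid, self.table)
        self.rows.extend(rows)
        return rows

    def add_composition(self, rules: Sequence[CompositionRule]) -> list[Row]:
        rows = expand_composition(rules, self.grid, self.table)
        self.rows.extend(rows)
        self.composition_rules.extend(rules)
        return rows

    # -- evaluation --------------------------------------------------------

    def extended_vector(self, menu: Menu,
                        deviations: np.ndarray | None = None) -> np.ndarray:
        x = menu.to_vector()
        dev = (np.zeros(self.n_deviations) if deviations is None
               else np.asarray(deviations, dtype=float))
        if len(dev) != self.n_deviations:
            raise InvalidConfigError(
                f"expected {self.n_deviations} deviation values, "
                f"got {len(dev)}"
            )
        return np.concatenate([x, dev])

    def minimal_deviations(self, menu: Menu) -> np.ndarray:
        """Smallest nonnegative deviations making every soft row hold."""
        x = menu.to_vector()
        dev = np.zeros(self.n_deviations)
        nb = self.n_binary
        for row in self.rows:
            if row.hard:
                continue
            dev_idx = [j for j in row.coeffs if j >= nb]
            if len(dev_idx) != 1:  # pragma: no cover - construction invariant
                raise InvalidConfigError(
                    f"soft row {row.provenance!r} must carry exactly one "
                    f"deviation variable"
                )
            j = dev_idx[0]
            q = sum(row.coeffs[k] * x[k] for k in row.coeffs if k < nb)
            if row.sense == ">=":  # Q + d >= L  ->  d = max(0, L - Q)
                dev[j - nb] = max(0.0, row.rhs - q)
            else:  # Q - d <= U  ->  d = max(0, Q - U)
                dev[j - nb] = max(0.0, q - row.rhs)
        return dev

    def check_feasible(self, menu: Menu, tol: float = 1e-9
                       ) -> tuple[bool, list[Violation]]:
        """Verdict on hard-row satisfaction, with every violation listed."""
        ext = self.extended_vector(menu)
        violations = []
        for row in self.rows:
            if not row.hard:
                continue
            v = row.value(ext)
            ok = (
                v <= row.rhs + tol if row.sense == "<=" else
                v >= row.rhs - tol if row.sense == ">=" else
                abs(v - row.rhs) <= tol
            )
            if not ok:
                violations.append(Violation(row.provenance, row.sense,
                                            row.rhs, v))
        return (not violations), violations

    def family_counts(self) -> dict[str, int]:
        """Row counts by family, in the style of a model-structure summary."""
        counts = {"equality": 0, "inequality": 0, "soft": 0,
                  "quantity": 0, "rate": 0, "composition": 0}
        for row in self.rows:
            counts["equality" if row.sense == "==" else "inequality"] += 1
            if not row.hard:
                counts["soft"] += 1
            if row.provenance.startswith("Q["):
                counts["quantity"] += 1
            elif "@meal(" in row.provenance and row.sense == "==":
                counts["composition"] += 1
            else:
                counts["rate"] += 1
        return counts


def check_feasible(menu: Menu, system: ConstraintSystem,
                   tol: float = 1e-9) -> tuple[bool, list[Violation]]:
    """Module-level convenience wrapper around
    :meth:`ConstraintSystem.check_feasible`."""
    return system.check_feasible(menu, tol=tol)
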