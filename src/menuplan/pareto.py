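"""Multi-objective machinery: dominance, non-dominated filtering, and
Pareto-front generation by scalarization.

With two conflicting goals (say plan price and plan carbon footprint) no
single menu minimises both; the object of interest is the *Pareto optimal
set* — feasible menus not dominated by any other feasible menu.  Two
scalarization sweeps trace it:

* the **epsilon-constraint** sweep minimises f1 subject to ``f2 <= eps``
  for a grid of eps spanning [min f2, max f2] over the feasible set; it
  can reach every non-dominated point;
* the **weighted-sum** sweep minimises ``alpha*f1 + (1-alpha)*f2`` over a
  grid of weights; it reaches only the *supported* points (those on the
  convex hull of the front) and is therefore a subset of the
  epsilon-constraint front on the same instance.

A minimiser of f1 at fixed eps may still be weakly dominated (tied f1,
larger f2), so each epsilon solve is followed by a lexicographic second
solve minimising f2 subject to f1 at its optimum; dominated and duplicate
points are filtered before the front is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constraints import ConstraintSystem, Row
from .objective import (
    ObjectiveSpec,
    ObjectiveVector,
    evaluate,
    objective_coefficients,
    weighted_sum,
)
from .plan_model import InvalidConfigError, Menu
from .solver import EmptyFeasibleSetError, SolveResult, solve

_TOL = 1e-9


@dataclass(frozen=True)
class ParetoPoint:
    """One non-dominated menu with its objective vector."""

    menu: Menu
    objectives: ObjectiveVector


@dataclass(frozen=True)
class ParetoSet:
    """Non-dominated points sorted by the first objective.

    After duplicate collapse the sort is strict in f1, and along the front
    f2 strictly decreases as f1 increases (trade-off monotonicity).
    """

    points: tuple[ParetoPoint, ...]

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    def objective_array(self) -> np.ndarray:
        return np.array([list(p.objectives) for p in self.points])

    def percent_changes(self, reference: int = 0) -> np.ndarray:
        """Objective values as percent change from a reference point
        (default: the minimum-f1 point): 100 * (v - v_ref) / v_ref."""
        arr = self.objective_array()
        ref = arr[reference]
        if np.any(ref == 0):
            raise InvalidConfigError(
                "percent change undefined: reference objective is 0"
            )
        return 100.0 * (arr - ref) / ref


def dominates(a: ObjectiveVector, b: ObjectiveVector) -> bool:
    """True iff ``a`` is no worse than ``b`` in every objective and
    strictly better in at least one (minimisation throughout)."""
    if len(a) != len(b):
        raise InvalidConfigError(
            f"objective vectors differ in length: {len(a)} vs {len(b)}"
        )
    no_worse = all(x <= y for x, y in zip(a, b))
    strictly = any(x < y for x, y in zip(a, b))
    return no_worse and strictly


def pareto_filter(points: list[ObjectiveVector]) -> list[int]:
    """Indices of the non-dominated points of ``points``.

    Exact duplicates of a retained point are retained too (they are
    mutually non-dominating).  Order of the returned indices follows the
    input.  Implemented as a sort by objective sum followed by a scan —
    a point can only be dominated by one with a smaller coordinate sum.
    """
    if not points:
        raise InvalidConfigError("pareto_filter needs at least one point")
    k = len(points[0])
    if any(len(p) != k for p in points):
        raise InvalidConfigError("objective vectors differ in length")
    order = sorted(range(len(points)), key=lambda i: sum(points[i]))
    kept: list[int] = []
    for i in order:
        if not any(dominates(points[j], points[i]) for j in kept):
            kept.append(i)
    return sorted(kept)


def _dedup_and_sort(entries: list[tuple[Menu, ObjectiveVector]]
                    ) -> ParetoSet:
    """Drop dominated and duplicate objective vectors, sort by f1."""
    if not entries:
        return ParetoSet(())
    vecs = [e[1] for e in entries]
    kept = pareto_filter(vecs)
    seen: set[tuple[float, ...]] = set()
    points = []
    for i in kept:
        key = tuple(round(v, 9) for v in vecs[i])
        if key in seen:
            continue
        seen.add(key)
        points.append(ParetoPoint(entries[i][0], vecs[i]))
    points.sort(key=lambda p: tuple(p.objectives))
    return ParetoSet(tuple(points))


def _with_extra_row(system: ConstraintSystem, row: Row) -> ConstraintSystem:
    clone = ConstraintSystem(system.grid, system.table)
    clone.rows = list(system.rows) + [row]
    clone.deviations = list(system.deviations)
    clone.composition_rules = list(system.composition_rules)
    return clone


def _spec_row(system: ConstraintSystem, spec: ObjectiveSpec, sense: str,
              rhs: float, tag: str) -> Row:
    c = objective_coefficients(spec, system.grid, system.table)
    coeffs = {j: float(v) for j, v in enumerate(c) if v != 0.0}
    return Row(coeffs, sense, float(rhs), provenance=tag)


def _negate(spec: ObjectiveSpec) -> ObjectiveSpec:
    return ObjectiveSpec(tuple((p, -c) for p, c in spec.terms),
                         deviation_penalty=spec.deviation_penalty,
                         name=f"-({spec.name})")


def _objective_extremes(system: ConstraintSystem, spec: ObjectiveSpec,
                        method: str) -> tuple[float, float]:
    lo = solve(system, spec, method=method)
    if lo.status != "optimal":
        raise EmptyFeasibleSetError(
            f"feasible set empty or solve failed ({lo.status})"
        )
    hi = solve(system, _negate(spec), method=method)
    assert hi.status == "optimal"
    return (evaluate(spec, lo.menu), evaluate(spec, hi.menu))


def _lexicographic_solve(system: ConstraintSystem, f1: ObjectiveSpec,
                         f2: ObjectiveSpec, method: str
                         ) -> SolveResult | None:
    """min f1, then min f2 subject to f1 at its optimum (tie resolution)."""
    first = solve(system, f1, method=method)
    if first.status != "optimal":
        return None
    v1 = evaluate(f1, first.menu)
    tied = _with_extra_row(
        system, _spec_row(system, f1, "<=", v1 + _TOL, f"lex f1<={v1:g}")
    )
    second = solve(tied, f2, method=method)
    return second if second.status == "optimal" else first


def epsilon_sweep(system: ConstraintSystem, f1_spec: ObjectiveSpec,
                  f2_spec: ObjectiveSpec, n_points: int,
                  method: str = "exact",
                  mode: str = "uniform") -> ParetoSet:
    """Trace the f1-vs-f2 Pareto front with the epsilon-constraint method.

    Solves ``min f1 s.t. f2 <= eps`` at up to ``n_points`` epsilon values
    spanning [min f2, max f2]; ``mode="uniform"`` descends from the top of
    the bracket, placing each eps just below the f2 of the last point found
    (with the final solve at the bracket bottom), so a budget of at least
    the number of distinct front f2 values recovers the complete front;
    ``mode="adaptive"`` starts from the bracket endpoints and repeatedly
    bisects the largest f2 gap between adjacent front points (useful where
    the front is steep).  Every returned menu is feasible and the returned
    vectors are mutually non-dominated.
    """
    if n_points < 2:
        raise InvalidConfigError(f"n_points must be >= 2, got {n_points}")
    if mode not in ("uniform", "adaptive"):
        raise InvalidConfigError(f"unknown mode {mode!r}")
    eps_min, eps_max = _objective_extremes(system, f2_spec, method)

    entries: list[tuple[Menu, ObjectiveVector]] = []

    def solve_at(eps: float) -> float:
        sub = _with_extra_row(
            system,
            _spec_row(system, f2_spec, "<=", eps + _TOL, f"eps f2<={eps:g}"),
        )
        res = _lexicographic_solve(sub, f1_spec, f2_spec, method)
        assert res is not None, "eps within bracket cannot be infeasible"
        v2 = evaluate(f2_spec, res.menu)
        entries.append((res.menu, ObjectiveVector((
            evaluate(f1_spec, res.menu), v2,
        ))))
        return v2

    if mode == "uniform":
        # sequential descent: each eps sits just below the f2 of the last
        # point found, so every solve discovers a new front point and
        # n_points >= |distinct f2 values| recovers the whole front; the
        # final solve is pinned to eps_min so the bracket is always spanned.
        # The step must exceed the backend feasibility tolerance, which
        # bounds the front resolution at ~1e-5 in f2.
        prev_v2 = None
        for k in range(n_points):
            if prev_v2 is None:
                eps = eps_max
            else:
                eps = prev_v2 - 1e-5 * max(1.0, abs(prev_v2))
                if k == n_points - 1:
                    eps = min(eps, eps_min)
            if eps < eps_min - _TOL:
                break
            prev_v2 = solve_at(eps)
    else:
        solve_at(eps_min)
        solve_at(eps_max)
        while len(entries) < n_points:
            f2s = sorted({e[1][1] for e in entries})
            if len(f2s) < 2:
                break
            gaps = [(f2s[i + 1] - f2s[i], i) for i in range(len(f2s) - 1)]
            width, i = max(gaps)
            if width <= _TOL:
                break
            solve_at((f2s[i] + f2s[i + 1]) / 2.0)

    return _dedup_and_sort(entries)


def weighted_sweep(system: ConstraintSystem, f1_spec: ObjectiveSpec,
                   f2_spec: ObjectiveSpec, alphas: list[float],
                   method: str = "exact") -> ParetoSet:
    """Trace the supported part of the front with weighted-sum solves at
    the given alphas (f = alpha*f1 + (1-alpha)*f2)."""
    if not alphas:
        raise InvalidConfigError("need at least one alpha")
    entries: list[tuple[Menu, ObjectiveVector]] = []
    for alpha in alphas:
        spec = weighted_sum([f1_spec, f2_spec], alpha)
        res = solve(system, spec, method=method)
        if res.status != "optimal":
            raise EmptyFeasibleSetError(
                f"feasible set empty or solve failed ({res.status})"
            )
        entries.append((res.menu, ObjectiveVector((
            evaluate(f1_spec, res.menu), evaluate(f2_spec, res.menu),
        ))))
    return _dedup_and_sort(entries)
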