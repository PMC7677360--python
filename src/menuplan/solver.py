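"""Optimal menu computation.

Two routes to the optimum of  min f(x) over the feasible set F:

* **exact** — a depth-first search over slots that branches on the
  composition rules (choose one dish per use group per slot), prunes with
  per-row interval bounds and an objective lower bound, and breaks ties
  between equally optimal menus deterministically (the first optimum in
  lexicographic candidate order is kept).  Intended for desk-scale
  instances and as the oracle in tests.
* **backend** — delegation to a mixed-integer programming solver
  (HiGHS, via :func:`scipy.optimize.milp`); results are validated against
  the constraint system and the objective recomputed before acceptance.

The module also implements the interchange contract for external solvers:
writing the model as an LP-format file and parsing a ``variable value``
solution file.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .constraints import ConstraintSystem
from .objective import ObjectiveSpec, evaluate, objective_coefficients
from .plan_model import (
    InvalidConfigError,
    Menu,
    MenuPlanError,
    Scope,
    aggregate_quantity,
)

DEFAULT_ENUMERATION_CAP = 1_000_000
FEAS_TOL = 1e-9
OBJ_TOL = 1e-6


class EmptyFeasibleSetError(MenuPlanError):
    """Raised when an operation requires a nonempty feasible set."""


@dataclass
class SolveResult:
    """Outcome of one solve: status, optimal menu and diagnostics."""

    status: str  # "optimal" | "infeasible" | "aborted"
    menu: Menu | None = None
    objective_value: float | None = None
    deviations: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.status not in ("optimal", "infeasible", "aborted"):
            raise InvalidConfigError(f"bad status {self.status!r}")
        if self.status != "optimal" and self.menu is not None:
            raise InvalidConfigError(
                f"status {self.status!r} must not carry a menu"
            )


def candidate_space_size(system: ConstraintSystem) -> int:
    """Upper bound on the number of composition-valid menus: the product
    over slots of the per-slot candidate counts (binomials per rule)."""
    table = system.table
    space = 1
    for slot in system.grid.slots():
        per_slot = 1
        for rule in system.composition_rules:
            if rule.meal_label != slot.meal:
                continue
            group_size = len(table.use_groups[rule.use_group])
            per_slot *= math.comb(group_size, rule.exact_count)
        space *= max(per_slot, 1)
    return space


def slot_candidates(system: ConstraintSystem) -> list[list[tuple[int, ...]]]:
    """Per-slot candidate dish-index tuples induced by composition rules.

    For each slot, the applicable rules (matching the slot's meal label)
    each contribute ``exact_count`` dishes chosen from their use group; a
    slot candidate is one such choice per rule.  Slots with no applicable
    rule stay empty.  Candidates are emitted in lexicographic dish-index
    order, which fixes the solver's tie-breaking.
    """
    table = system.table
    out: list[list[tuple[int, ...]]] = []
    for slot in system.grid.slots():
        rules = [r for r in system.composition_rules
                 if r.meal_label == slot.meal]
        if not rules:
            out.append([()])
            continue
        per_rule = []
        for rule in rules:
            members = sorted(
                table.dish_index(i) for i in table.use_groups[rule.use_group]
            )
            per_rule.append(
                list(itertools.combinations(members, rule.exact_count))
            )
        cands: list[tuple[int, ...]] = []
        seen = set()
        for combo in itertools.product(*per_rule):
            flat = tuple(sorted(d for part in combo for d in part))
            if len(set(flat)) != len(flat):
                continue  # same dish drawn via two overlapping groups
            if flat not in seen:
                seen.add(flat)
                cands.append(flat)
        out.append(sorted(cands))
    return out


def _menu_from_choice(system: ConstraintSystem,
                      choice: Sequence[tuple[int, ...]]) -> Menu:
    menu = Menu(system.grid, system.table)
    for slot, cand in zip(system.grid.slots(), choice):
        if cand:
            menu.assignment[slot] = frozenset(
                system.table.dishes[d].id for d in cand
            )
    return menu


def _solve_exact(system: ConstraintSystem, spec: ObjectiveSpec,
                 cap: int) -> SolveResult:
    grid, table = system.grid, system.table
    n = table.n_dishes
    n_slots = grid.n_slots

    space = candidate_space_size(system)
    if space > cap:
        return SolveResult(
            status="aborted",
            diagnostics={
                "candidate_space": space,
                "cap": cap,
                "guidance": (
                    f"enumeration space {space:g} exceeds cap {cap:g}; "
                    "use method='backend' or shrink the instance"
                ),
            },
        )
    cands = slot_candidates(system)

    c_full = objective_coefficients(spec, grid, table, system)
    c_bin = c_full[:grid.n_slots * n]
    nb = system.n_binary

    # Per-slot, per-candidate contributions to objective and each hard row.
    hard = [r for r in system.rows if r.hard]
    soft = [r for r in system.rows if not r.hard]
    cand_obj = [
        [sum(c_bin[s * n + d] for d in cand) for cand in cands[s]]
        for s in range(n_slots)
    ]
    row_contrib = []
    for r in hard:
        per_slot = []
        for s in range(n_slots):
            block = {j - s * n: v for j, v in r.coeffs.items()
                     if s * n <= j < (s + 1) * n}
            per_slot.append([
                sum(block.get(d, 0.0) for d in cand) for cand in cands[s]
            ])
        per_slot_arr = [np.array(p) for p in per_slot]
        row_contrib.append(per_slot_arr)

    # Suffix bounds for pruning: tightest achievable remaining contribution.
    def suffix(values_per_slot, reduce_fn):
        suf = np.zeros(n_slots + 1)
        for s in range(n_slots - 1, -1, -1):
            suf[s] = suf[s + 1] + reduce_fn(values_per_slot[s])
        return suf

    obj_min_suffix = suffix([np.array(v) for v in cand_obj], np.min)
    row_min_suffix = [suffix(rc, np.min) for rc in row_contrib]
    row_max_suffix = [suffix(rc, np.max) for rc in row_contrib]

    best_obj = math.inf
    best_choice: list[tuple[int, ...]] | None = None
    nodes = 0
    leaves = 0

    choice: list[int] = [0] * n_slots
    run_rows = np.zeros(len(hard))

    def dfs(s: int, run_obj: float) -> None:
        nonlocal best_obj, best_choice, nodes, leaves, run_rows
        nodes += 1
        # even the cheapest completion cannot strictly improve on the
        # incumbent; equally-good completions are lexicographically later
        if run_obj + obj_min_suffix[s] > best_obj - 1e-12:
            return
        for r_idx in range(len(hard)):
            row = hard[r_idx]
            lo = run_rows[r_idx] + row_min_suffix[r_idx][s]
            hi = run_rows[r_idx] + row_max_suffix[r_idx][s]
            if row.sense == "<=" and lo > row.rhs + FEAS_TOL:
                return
            if row.sense == ">=" and hi < row.rhs - FEAS_TOL:
                return
            if row.sense == "==" and (lo > row.rhs + FEAS_TOL
                                      or hi < row.rhs - FEAS_TOL):
                return
        if s == n_slots:
            leaves += 1
            # hard rows proved satisfied by the interval check above
            total = run_obj
            if soft:
                menu = _menu_from_choice(system, [cands[t][choice[t]]
                                                  for t in range(n_slots)])
                dev = system.minimal_deviations(menu)
                total = evaluate(spec, menu, deviations=dev, system=system)
            if total < best_obj - 1e-12:
                best_obj = total
                best_choice = [cands[t][choice[t]] for t in range(n_slots)]
            return
        for k in range(len(cands[s])):
            choice[s] = k
            run_rows += [rc[s][k] for rc in row_contrib]
            dfs(s + 1, run_obj + cand_obj[s][k])
            run_rows -= [rc[s][k] for rc in row_contrib]

    dfs(0, 0.0)
    diagnostics = {"nodes": nodes, "leaves": leaves,
                   "candidate_space": space}
    if best_choice is None:
        return SolveResult(status="infeasible", diagnostics=diagnostics)
    menu = _menu_from_choice(system, best_choice)
    dev = system.minimal_deviations(menu)
    value = evaluate(spec, menu, deviations=dev, system=system)
    return SolveResult(status="optimal", menu=menu, objective_value=value,
                       deviations=dev, diagnostics=diagnostics)


def _solve_backend(system: ConstraintSystem,
                   spec: ObjectiveSpec) -> SolveResult:
    grid, table = system.grid, system.table
    nb = system.n_binary
    nd = system.n_deviations
    nvar = nb + nd

    c = objective_coefficients(spec, grid, table, system)
    if len(c) < nvar:
        c = np.concatenate([c, np.zeros(nvar - len(c))])

    constraints = []
    if system.rows:
        data, r_idx, c_idx = [], [], []
        lb = np.full(len(system.rows), -np.inf)
        ub = np.full(len(system.rows), np.inf)
        for i, row in enumerate(system.rows):
            for j, v in row.coeffs.items():
                data.append(v)
                r_idx.append(i)
                c_idx.append(j)
            if row.sense == "<=":
                ub[i] = row.rhs
            elif row.sense == ">=":
                lb[i] = row.rhs
            else:
                lb[i] = ub[i] = row.rhs
        a = sparse.csc_array(
            (data, (r_idx, c_idx)), shape=(len(system.rows), nvar)
        )
        constraints.append(LinearConstraint(a, lb, ub))

    integrality = np.concatenate([np.ones(nb), np.zeros(nd)])
    bounds = Bounds(np.zeros(nvar),
                    np.concatenate([np.ones(nb), np.full(nd, np.inf)]))
    # gap 0 so the backend proves optimality (matches the exact solver)
    res = milp(c=c, constraints=constraints, integrality=integrality,
               bounds=bounds, options={"mip_rel_gap": 0.0})
    diagnostics = {"backend": "highs", "backend_status": int(res.status),
                   "backend_message": res.message}
    if res.status == 2:
        return SolveResult(status="infeasible", diagnostics=diagnostics)
    if res.status != 0 or res.x is None:
        return SolveResult(status="aborted", diagnostics=diagnostics)

    menu = Menu.from_vector(grid, table, np.round(res.x[:nb]))
    # validate at the backend's own feasibility tolerance (1e-6), not the
    # package default: HiGHS may satisfy a row only to that precision
    ok, violations = system.check_feasible(menu, tol=OBJ_TOL)
    if not ok:  # pragma: no cover - backend defect guard
        diagnostics["violations"] = [str(v) for v in violations]
        return SolveResult(status="aborted", diagnostics=diagnostics)
    dev = system.minimal_deviations(menu)
    value = evaluate(spec, menu, deviations=dev, system=system)
    if abs(value - res.fun) > OBJ_TOL * max(1.0, abs(value)):
        # minimal deviations can only improve on the backend's, never worsen
        if value > res.fun + OBJ_TOL * max(1.0, abs(value)):
            diagnostics["objective_mismatch"] = (value, float(res.fun))
            return SolveResult(status="aborted",
                               diagnostics=diagnostics)  # pragma: no cover
    return SolveResult(status="optimal", menu=menu, objective_value=value,
                       deviations=dev, diagnostics=diagnostics)


def solve(system: ConstraintSystem, spec: ObjectiveSpec,
          method: str = "exact",
          cap: int = DEFAULT_ENUMERATION_CAP) -> SolveResult:
    """Minimise ``spec`` over the feasible set of ``system``.

    ``method="exact"`` enumerates composition-valid menus with pruning and
    is guaranteed globally optimal (used as the oracle at desk scale);
    ``method="backend"`` delegates to the mixed-integer backend and
    validates the returned menu before accepting it.  An infeasible system
    yields ``status="infeasible"``, never an exception.
    """
    if method == "exact":
        return _solve_exact(system, spec, cap)
    if method == "backend":
        return _solve_backend(system, spec)
    raise InvalidConfigError(f"unknown method {method!r}")


def solve_extreme(system: ConstraintSystem, parameter: str,
                  sense: str = "min", method: str = "exact") -> float:
    """Extreme plan-level quantity of ``parameter`` over the feasible set;
    brackets the epsilon range of Pareto sweeps."""
    if sense not in ("min", "max"):
        raise InvalidConfigError(f"sense must be min/max, got {sense!r}")
    spec = (ObjectiveSpec.minimize(parameter) if sense == "min"
            else ObjectiveSpec.maximize(parameter))
    res = solve(system, spec, method=method)
    if res.status != "optimal":
        raise EmptyFeasibleSetError(
            f"cannot take {sense} of {parameter!r}: solve status "
            f"{res.status}"
        )
    return aggregate_quantity(res.menu, parameter, Scope.plan())


# ---------------------------------------------------------------------------
# External-backend interchange: LP-format export and solution parsing
# ---------------------------------------------------------------------------

def variable_name(system: ConstraintSystem, j: int) -> str:
    """Canonical variable name for flat index ``j``: ``x_<slot>_<dish>`` for
    binaries, ``d_<k>`` for deviation variables."""
    nb = system.n_binary
    if j < nb:
        n = system.table.n_dishes
        return f"x_{j // n}_{j % n}"
    return f"d_{j - nb}"


def _lp_expr(system: ConstraintSystem, coeffs: dict[int, float]) -> str:
    parts = []
    for j in sorted(coeffs):
        v = coeffs[j]
        name = variable_name(system, j)
        sign = "-" if v < 0 else "+"
        parts.append(f"{sign} {abs(v):.12g} {name}")
    s = " ".join(parts) if parts else "+ 0 " + variable_name(system, 0)
    return s.lstrip("+ ").replace("  ", " ") if s.startswith("+") else s


def write_lp(system: ConstraintSystem, spec: ObjectiveSpec,
             path: str) -> None:
    """Emit the model as an LP-format file (objective, rows, bounds, and a
    binaries section) for consumption by an external solver."""
    grid, table = system.grid, system.table
    c = objective_coefficients(spec, grid, table, system)
    obj_coeffs = {j: float(v) for j, v in enumerate(c) if v != 0.0}
    nb = system.n_binary
    lines = ["\\ menuplan model", "Minimize",
             f" obj: {_lp_expr(system, obj_coeffs)}", "Subject To"]
    for i, row in enumerate(system.rows):
        op = {"<=": "<=", ">=": ">=", "==": "="}[row.sense]
        lines.append(
            f" c{i}: {_lp_expr(system, row.coeffs)} {op} {row.rhs:.12g}"
        )
    lines.append("Bounds")
    for k in range(system.n_deviations):
        lines.append(f" 0 <= d_{k}")
    lines.append("Binaries")
    names = [variable_name(system, j) for j in range(nb)]
    for start in range(0, len(names), 8):
        lines.append(" " + " ".join(names[start:start + 8]))
    lines.append("End")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_solution(path: str) -> dict[str, float]:
    """Parse a solution file of ``variable value`` lines (blank lines and
    ``#``/``\\`` comments ignored)."""
    values: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "\\")):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise InvalidConfigError(
                    f"{path}:{lineno}: expected 'variable value', "
                    f"got {line!r}"
                )
            try:
                values[parts[0]] = float(parts[1])
            except ValueError:
                raise InvalidConfigError(
                    f"{path}:{lineno}: bad value {parts[1]!r}"
                ) from None
    return values


def menu_from_solution(system: ConstraintSystem,
                       values: dict[str, float]) -> Menu:
    """Rebuild a menu from parsed ``x_<slot>_<dish>`` solution values."""
    n = system.table.n_dishes
    x = np.zeros(system.n_binary)
    for name, v in values.items():
        if not name.startswith("x_"):
            continue
        try:
            _, s, d = name.split("_")
            x[int(s) * n + int(d)] = v
        except (ValueError, IndexError):
            raise InvalidConfigError(f"bad variable name {name!r}") from None
    return Menu.from_vector(system.grid, system.table, np.round(x))
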