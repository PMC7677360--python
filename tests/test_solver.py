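"""Exact solver vs exhaustive enumeration, backend parity, LP interchange."""

import numpy as np
import pytest

from menuplan import (
    CompositionRule,
    ConstraintSystem,
    Dish,
    EmptyFeasibleSetError,
    ObjectiveSpec,
    PlanGrid,
    QuantityBound,
    RateBound,
    RecipeTable,
    Row,
    evaluate,
    menu_from_solution,
    read_solution,
    solve,
    solve_extreme,
    write_lp,
)

from conftest import enumerate_composition_menus, menu_satisfies


def brute_force_minimum(grid, table, rules, qbounds, rbounds, spec):
    """Independent optimum: enumerate every composition-valid menu, filter
    by the direct feasibility oracle, minimise by direct evaluation."""
    best = None
    for menu in enumerate_composition_menus(grid, table, rules):
        if not menu_satisfies(menu, qbounds, rbounds):
            continue
        v = evaluate(spec, menu)
        if best is None or v < best - 1e-12:
            best = v
    return best


def random_instance(rng, max_space=2000):
    """A random desk-scale instance: <= 12 slots, <= 8 dishes, and at most
    ``max_space`` composition-valid menus so enumeration stays instant."""
    group_sizes = {"first": int(rng.integers(2, 4)),
                   "second": int(rng.integers(2, 4))}
    if sum(group_sizes.values()) < 7 and rng.random() < 0.5:
        group_sizes["side"] = 2
    per_slot = int(np.prod(list(group_sizes.values())))
    max_slots = max(2, int(np.log(max_space) / np.log(per_slot)))

    n_meals = int(rng.integers(1, 3))
    n_days = int(rng.integers(1, 4))
    weeks = int(rng.integers(1, 3))
    while n_meals * n_days * weeks > min(12, max_slots):
        if weeks > 1:
            weeks -= 1
        elif n_days > 1:
            n_days -= 1
        else:
            n_meals = 1
    meals = ["lunch", "dinner"][:n_meals]
    days = ["mon", "tue", "wed"][:n_days]
    grid = PlanGrid(meals, days, weeks)
    food_pool = ["pasta", "red meat", "fish", "legumes", "vegetables"]
    dishes = []
    for g, size in group_sizes.items():
        for k in range(size):
            dishes.append(Dish(
                f"{g}{k}", f"{g} {k}", 100.0,
                {"energy": float(rng.uniform(80, 400)),
                 "price": float(np.round(rng.uniform(0.3, 3.0), 2)),
                 "carbon_footprint": float(np.round(rng.uniform(0.1, 3.0),
                                                    2))},
                {g}, {food_pool[int(rng.integers(len(food_pool)))]},
            ))
    table = RecipeTable(dishes)
    rules = [CompositionRule(g, m) for g in group_sizes for m in meals]

    # calibrate a day-scope energy box from a feasible anchor menu so the
    # instance is usually (not always) feasible
    anchor = next(enumerate_composition_menus(grid, table, rules))
    from menuplan import Scope, aggregate_quantity
    day_totals = [aggregate_quantity(anchor, "energy", sc)
                  for sc in Scope.instances(grid, "day")]
    mid = float(np.mean(day_totals))
    qbounds = [QuantityBound("energy", "day",
                             lower=mid * 0.5, upper=mid * 1.5)]
    rbounds = []
    if "red meat" in table.food_groups and rng.random() < 0.5:
        rbounds.append(RateBound("red meat", "plan",
                                 max_count=int(rng.integers(0, 4))))
    system = ConstraintSystem(grid, table)
    system.add_composition(rules)
    for b in qbounds:
        system.add_quantity_bound(b)
    for b in rbounds:
        system.add_rate_bound(b)
    return grid, table, rules, qbounds, rbounds, system


class TestSolveExact:
    def test_singleton_feasible_set_returns_unique_menu(self):
        dishes = [Dish("a", "a", 100, {"price": 2.0}, {"first"}),
                  Dish("b", "b", 100, {"price": 1.0}, {"second"})]
        table = RecipeTable(dishes)
        grid = PlanGrid(["lunch"], ["mon"], 1)
        system = ConstraintSystem(grid, table)
        system.add_composition([CompositionRule("first", "lunch"),
                                CompositionRule("second", "lunch")])
        for spec in (ObjectiveSpec.minimize("price"),
                     ObjectiveSpec.maximize("price")):
            res = solve(system, spec)
            assert res.status == "optimal"
            assert res.menu.n_servings() == 2

    def test_contradictory_rate_bounds_infeasible(self, toy_system):
        toy_system.add_rate_bound(RateBound("d0", "plan", min_count=2))
        toy_system.add_rate_bound(RateBound("d0", "plan", max_count=1))
        res = solve(toy_system, ObjectiveSpec.minimize("price"))
        assert res.status == "infeasible"
        assert res.menu is None

    def test_toy_price_optimum_matches_enumeration(self, toy_grid, toy_table,
                                                   toy_rules):
        qbounds = [QuantityBound("energy", "day", lower=540, upper=640)]
        system = ConstraintSystem(toy_grid, toy_table)
        system.add_composition(toy_rules)
        system.add_quantity_bound(qbounds[0])
        spec = ObjectiveSpec.minimize("price")
        res = solve(system, spec)
        expected = brute_force_minimum(toy_grid, toy_table, toy_rules,
                                       qbounds, [], spec)
        assert res.status == "optimal"
        assert res.objective_value == pytest.approx(expected)
        assert system.check_feasible(res.menu)[0]

    def test_cap_exceeded_aborts_with_guidance(self, toy_system):
        res = solve(toy_system, ObjectiveSpec.minimize("price"), cap=3)
        assert res.status == "aborted"
        assert "backend" in res.diagnostics["guidance"]

    def test_zero_coefficient_objective_returns_feasible_menu(
            self, toy_system):
        res = solve(toy_system, ObjectiveSpec((("price", 0.0),)))
        assert res.status == "optimal"
        assert toy_system.check_feasible(res.menu)[0]

    def test_deterministic_tie_breaking(self, toy_grid, toy_rules):
        """With a constant objective all menus tie; the returned menu is
        identical across runs."""
        dishes = [Dish(f"{g}{k}", f"{g}{k}", 100, {"price": 1.0}, {g})
                  for g in ("first", "second", "side") for k in range(2)]
        table = RecipeTable(dishes)
        system = ConstraintSystem(toy_grid, table)
        system.add_composition(toy_rules)
        spec = ObjectiveSpec.minimize("price")
        first = solve(system, spec)
        second = solve(system, spec)
        assert first.menu == second.menu

    def test_reoptimising_under_own_optimum_bound_stays_feasible(
            self, toy_system):
        """Adding f <= f* as a constraint and re-solving returns the same
        objective value (idempotence of the optimum)."""
        spec = ObjectiveSpec.minimize("price")
        res = solve(toy_system, spec)
        from menuplan.objective import objective_coefficients
        c = objective_coefficients(spec, toy_system.grid, toy_system.table)
        coeffs = {j: float(v) for j, v in enumerate(c) if v != 0.0}
        toy_system.rows.append(Row(coeffs, "<=",
                                   res.objective_value + 1e-9,
                                   provenance="optimum cap"))
        again = solve(toy_system, spec)
        assert again.status == "optimal"
        assert again.objective_value == pytest.approx(res.objective_value)


class TestRandomizedOracle:
    def test_exact_matches_enumeration_and_backend(self):
        """On random desk-scale instances the exact optimum equals both the
        brute-force enumeration and the mixed-integer backend."""
        rng = np.random.default_rng(2024)
        n_feasible = 0
        for trial in range(30):
            grid, table, rules, qb, rb, system = random_instance(rng)
            spec = ObjectiveSpec.minimize(
                "price" if trial % 2 else "carbon_footprint"
            )
            expected = brute_force_minimum(grid, table, rules, qb, rb, spec)
            res = solve(system, spec, method="exact")
            if expected is None:
                assert res.status == "infeasible"
                continue
            n_feasible += 1
            assert res.status == "optimal"
            assert res.objective_value == pytest.approx(expected)
            assert system.check_feasible(res.menu)[0]
            backend = solve(system, spec, method="backend")
            assert backend.status == "optimal"
            assert backend.objective_value == pytest.approx(expected)
        assert n_feasible >= 20  # the generator mostly emits feasible cases


class TestSolveExtreme:
    def test_extremes_match_enumeration(self, toy_grid, toy_table, toy_rules,
                                        toy_system):
        menus = list(enumerate_composition_menus(toy_grid, toy_table,
                                                 toy_rules))
        prices = [evaluate(ObjectiveSpec.minimize("price"), m)
                  for m in menus]
        lo = solve_extreme(toy_system, "price", "min")
        hi = solve_extreme(toy_system, "price", "max")
        assert lo == pytest.approx(min(prices))
        assert hi == pytest.approx(max(prices))
        assert lo <= hi

    def test_single_feasible_menu_same_value_both_senses(self):
        dishes = [Dish("a", "a", 100, {"price": 2.0}, {"first"})]
        table = RecipeTable(dishes)
        grid = PlanGrid(["lunch"], ["mon"], 1)
        system = ConstraintSystem(grid, table)
        system.add_composition([CompositionRule("first", "lunch")])
        assert solve_extreme(system, "price", "min") == \
            solve_extreme(system, "price", "max") == pytest.approx(2.0)

    def test_empty_feasible_set_raises(self, toy_system):
        toy_system.add_rate_bound(RateBound("d0", "plan", min_count=2))
        toy_system.add_rate_bound(RateBound("d0", "plan", max_count=1))
        with pytest.raises(EmptyFeasibleSetError):
            solve_extreme(toy_system, "price", "min")


class TestLpInterchange:
    def test_round_trip_through_lp_and_solution_file(self, tmp_path,
                                                     toy_system):
        spec = ObjectiveSpec.minimize("price")
        lp_path = tmp_path / "model.lp"
        write_lp(toy_system, spec, lp_path)
        text = lp_path.read_text()
        for section in ("Minimize", "Subject To", "Binaries", "End"):
            assert section in text

        res = solve(toy_system, spec)
        sol_path = tmp_path / "model.sol"
        lines = []
        x = res.menu.to_vector()
        for j, v in enumerate(x):
            from menuplan.solver import variable_name
            lines.append(f"{variable_name(toy_system, j)} {v:g}")
        sol_path.write_text("\n".join(lines) + "\n")

        values = read_solution(sol_path)
        rebuilt = menu_from_solution(toy_system, values)
        assert rebuilt == res.menu
        assert np.array_equal(rebuilt.to_vector(), x)

    def test_solution_parser_rejects_malformed_lines(self, tmp_path):
        bad = tmp_path / "bad.sol"
        bad.write_text("x_0_0 1 extra\n")
        with pytest.raises(Exception):
            read_solution(bad)
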