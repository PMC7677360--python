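"""Constraint expansion: row counts, soft relaxation, feasibility checks."""

import numpy as np
import pytest

from menuplan import (
    CompositionRule,
    ConstraintSystem,
    Dish,
    InvalidConfigError,
    MealShareBound,
    Menu,
    PlanGrid,
    QuantityBound,
    RateBound,
    RecipeTable,
    Slot,
    UndefinedParameterError,
    amdr_to_bounds,
    expand_composition,
    expand_quantity_bound,
    expand_rate_bound,
)

from conftest import enumerate_composition_menus, menu_satisfies

WORKWEEK = ["mon", "tue", "wed", "thu", "fri"]
FULLWEEK = WORKWEEK + ["sat", "sun"]


def _table(params, groups=("first", "second", "side", "bread", "fruit"),
           per_group=2):
    dishes = []
    rng = np.random.default_rng(7)
    for g in groups:
        for k in range(per_group):
            dishes.append(Dish(
                f"{g}{k}", f"{g} {k}", 100.0,
                {p: float(rng.uniform(1, 10)) for p in params},
                {g}, {"pasta"} if g == "first" else set(),
            ))
    return RecipeTable(dishes)


class TestQuantityBoundExpansion:
    def test_interval_counts_two_rows_per_scope_instance(self):
        table = _table(["energy"])
        grid = PlanGrid(["lunch"], WORKWEEK, 4)
        bound = QuantityBound("energy", "day", lower=500, upper=700)
        assert len(expand_quantity_bound(bound, grid, table)) == 40

    def test_one_sided_counts_one_row_per_instance(self):
        table = _table(["sodium"])
        grid = PlanGrid(["lunch"], WORKWEEK, 4)
        bound = QuantityBound("sodium", "day", upper=800)
        rows = expand_quantity_bound(bound, grid, table)
        assert len(rows) == 20
        assert all(r.sense == "<=" for r in rows)

    def test_plan_scope_yields_single_instance(self):
        table = _table(["carbon_footprint"])
        grid = PlanGrid(["lunch"], WORKWEEK, 4)
        bound = QuantityBound("carbon_footprint", "plan", upper=30.0)
        assert len(expand_quantity_bound(bound, grid, table)) == 1

    def test_daily_school_lunch_configuration_row_count(self):
        """Energy/carbohydrate/fiber/sodium intervals plus protein/fat/sugar
        caps, per day over a 20-day plan: 220 scalar inequalities."""
        params = ["energy", "carbohydrates", "fiber", "sodium",
                  "protein", "fat", "sugar"]
        table = _table(params)
        grid = PlanGrid(["lunch"], WORKWEEK, 4)
        bounds = (
            [QuantityBound(p, "day", lower=10, upper=99)
             for p in ("energy", "carbohydrates", "fiber", "sodium")]
            + [QuantityBound(p, "day", upper=99)
               for p in ("protein", "fat", "sugar")]
        )
        rows = [r for b in bounds
                for r in expand_quantity_bound(b, grid, table)]
        assert len(rows) == 220

    def test_daily_full_board_configuration_row_count(self):
        """Breakfast energy-share floor, energy/protein/carbohydrate/fat
        intervals and a sugar cap, per day over 14 days: 140 rows."""
        params = ["energy", "protein", "carbohydrates", "fat", "sugar"]
        table = _table(params)
        grid = PlanGrid(["breakfast", "lunch", "dinner"], FULLWEEK, 2)
        bounds = (
            [MealShareBound("energy", "breakfast", 0.10)]
            + [QuantityBound(p, "day", lower=10, upper=99)
               for p in ("energy", "protein", "carbohydrates", "fat")]
            + [QuantityBound("sugar", "day", upper=99)]
        )
        rows = [r for b in bounds
                for r in expand_quantity_bound(b, grid, table)]
        assert len(rows) == 140

    def test_unknown_parameter_rejected(self):
        table = _table(["energy"])
        grid = PlanGrid(["lunch"], ["mon"], 1)
        with pytest.raises(UndefinedParameterError):
            expand_quantity_bound(QuantityBound("zinc", "day", upper=1),
                                  grid, table)

    def test_bound_without_sides_rejected(self):
        with pytest.raises(InvalidConfigError):
            QuantityBound("energy", "day")

    def test_crossed_bounds_rejected(self):
        with pytest.raises(InvalidConfigError):
            QuantityBound("energy", "day", lower=10, upper=5)

    def test_meal_share_row_is_meal_minus_fraction_of_day(self):
        table = _table(["energy"], groups=("cereals", "first"), per_group=1)
        grid = PlanGrid(["breakfast", "lunch"], ["mon"], 1)
        rows = expand_quantity_bound(
            MealShareBound("energy", "breakfast", 0.10), grid, table
        )
        assert len(rows) == 1
        row = rows[0]
        assert row.sense == ">=" and row.rhs == 0.0
        n = table.n_dishes
        e = table.param_vector("energy")
        # breakfast slot coefficients are (1 - frac) * q, lunch ones -frac*q
        for d in range(n):
            assert row.coeffs[d] == pytest.approx(0.9 * e[d])
            assert row.coeffs[n + d] == pytest.approx(-0.1 * e[d])


class TestCompositionExpansion:
    @pytest.mark.parametrize("groups,expected", [
        (("first", "second", "side", "bread", "fruit"), 100),
        (("first", "second", "side"), 60),
    ])
    def test_rule_count_times_slots(self, groups, expected):
        table = _table(["energy"], groups=groups)
        grid = PlanGrid(["lunch"], WORKWEEK, 4)
        rules = [CompositionRule(g, "lunch") for g in groups]
        rows = expand_composition(rules, grid, table)
        assert len(rows) == expected
        assert all(r.sense == "==" and r.rhs == 1.0 for r in rows)

    def test_exact_count_zero_forces_group_out(self, toy_grid, toy_table):
        rows = expand_composition(
            [CompositionRule("first", "lunch", exact_count=0)],
            toy_grid, toy_table,
        )
        assert all(r.rhs == 0.0 for r in rows)
        menu = Menu(toy_grid, toy_table,
                    {Slot("lunch", "mon", 1): ["d0"]})
        ext = np.concatenate([menu.to_vector(), []])
        assert rows[0].value(ext) == 1.0  # serving a first course violates

    def test_rules_only_apply_to_matching_meal(self):
        table = _table(["energy"], groups=("cereals",), per_group=3)
        grid = PlanGrid(["breakfast", "lunch"], ["mon", "tue"], 1)
        rows = expand_composition(
            [CompositionRule("cereals", "breakfast")], grid, table
        )
        assert len(rows) == 2  # two breakfast slots only


class TestRateBoundExpansion:
    def test_weekly_red_meat_cap_one_row_per_week(self):
        table = _table(["energy"])
        grid = PlanGrid(["lunch"], WORKWEEK, 4)
        rows = expand_rate_bound(RateBound("pasta", "week", max_count=3),
                                 grid, table)
        assert len(rows) == 4
        assert all(r.sense == "<=" and r.rhs == 3.0 for r in rows)

    def test_daily_plus_weekly_pasta_rows(self):
        table = _table(["energy"])
        grid = PlanGrid(["lunch"], WORKWEEK, 4)
        rows = (
            expand_rate_bound(RateBound("pasta", "day", max_count=1),
                              grid, table)
            + expand_rate_bound(RateBound("pasta", "week", max_count=4),
                                grid, table)
        )
        assert len(rows) == 24

    def test_min_equals_max_emits_equivalent_pair(self):
        table = _table(["energy"])
        grid = PlanGrid(["lunch"], WORKWEEK, 2)
        rows = expand_rate_bound(
            RateBound("first0", "week", min_count=1, max_count=1),
            grid, table,
        )
        assert len(rows) == 4  # >= and <= per week
        senses = sorted(r.sense for r in rows)
        assert senses == ["<=", "<=", ">=", ">="]


class TestAmdrConversion:
    @pytest.mark.parametrize("lo,hi,energy,density,expected", [
        (0.45, 0.65, 2000, 4, (225.0, 325.0)),
        (0.0, 1.0, 1800, 9, (0.0, 200.0)),
        (0.5, 0.5, 1000, 4, (125.0, 125.0)),
    ])
    def test_gram_bounds(self, lo, hi, energy, density, expected):
        assert amdr_to_bounds(lo, hi, energy, density) == \
            pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidConfigError):
            amdr_to_bounds(0.6, 0.4, 2000, 4)
        with pytest.raises(InvalidConfigError):
            amdr_to_bounds(0.4, 0.6, 2000, 0)


class TestSoftConstraints:
    def _soft_system(self, toy_grid, toy_table, toy_rules):
        system = ConstraintSystem(toy_grid, toy_table)
        system.add_composition(toy_rules)
        system.add_quantity_bound(QuantityBound(
            "energy", "day", lower=560, upper=600, mode="soft",
            soft_weight_lower=2.0, soft_weight_upper=1.0,
        ))
        return system

    def test_each_deviation_in_exactly_one_row(self, toy_grid, toy_table,
                                               toy_rules):
        system = self._soft_system(toy_grid, toy_table, toy_rules)
        nb = system.n_binary
        for k in range(system.n_deviations):
            carrying = [r for r in system.rows if nb + k in r.coeffs]
            assert len(carrying) == 1
            assert not carrying[0].hard

    def test_softening_never_shrinks_feasible_set(self, toy_grid, toy_table,
                                                  toy_rules):
        hard = ConstraintSystem(toy_grid, toy_table)
        hard.add_composition(toy_rules)
        bound = QuantityBound("energy", "day", lower=560, upper=600)
        hard.add_quantity_bound(bound)
        soft = self._soft_system(toy_grid, toy_table, toy_rules)
        for menu in enumerate_composition_menus(toy_grid, toy_table,
                                                toy_rules):
            if hard.check_feasible(menu)[0]:
                assert soft.check_feasible(menu)[0]
                assert np.all(soft.minimal_deviations(menu) == 0.0)

    def test_minimal_deviations_measure_overshoot(self, toy_grid, toy_table,
                                                  toy_rules):
        system = self._soft_system(toy_grid, toy_table, toy_rules)
        menu = Menu(toy_grid, toy_table, {
            Slot("lunch", "mon", 1): ["d1", "d2", "d4"],  # 640 kcal
            Slot("lunch", "tue", 1): ["d0", "d3", "d4"],  # 570 kcal
        })
        dev = system.minimal_deviations(menu)
        # mon overshoots the 600 kcal cap by 40; tue is inside the box
        assert sorted(dev, reverse=True)[0] == pytest.approx(40.0)
        assert sum(v > 0 for v in dev) == 1


class TestCheckFeasible:
    def test_empty_system_always_feasible(self, toy_grid, toy_table):
        system = ConstraintSystem(toy_grid, toy_table)
        ok, violations = system.check_feasible(Menu(toy_grid, toy_table))
        assert ok and violations == []

    def test_violation_names_bound_and_day(self, toy_grid, toy_table,
                                           toy_rules):
        system = ConstraintSystem(toy_grid, toy_table)
        system.add_composition(toy_rules)
        system.add_quantity_bound(QuantityBound("energy", "day", upper=500))
        menu = Menu(toy_grid, toy_table, {
            Slot("lunch", "mon", 1): ["d0", "d3", "d4"],  # 570 kcal
            Slot("lunch", "tue", 1): ["d0", "d3", "d4"],
        })
        ok, violations = system.check_feasible(menu)
        assert not ok
        quantity_violations = [v for v in violations
                               if "Q[energy]" in v.provenance]
        assert len(quantity_violations) == 2
        assert "day(mon,1)" in quantity_violations[0].provenance
        assert quantity_violations[0].slack == pytest.approx(-70.0)

    def test_agrees_with_direct_evaluation_on_all_toy_menus(
            self, toy_grid, toy_table, toy_rules):
        """Row-based verdicts match evaluation straight from the dish data
        for every composition-valid menu of the toy instance."""
        qbounds = [QuantityBound("energy", "day", lower=540, upper=620)]
        rbounds = [RateBound("red meat", "plan", max_count=1)]
        system = ConstraintSystem(toy_grid, toy_table)
        system.add_composition(toy_rules)
        for b in qbounds:
            system.add_quantity_bound(b)
        for b in rbounds:
            system.add_rate_bound(b)
        verdicts = []
        for menu in enumerate_composition_menus(toy_grid, toy_table,
                                                toy_rules):
            expected = menu_satisfies(menu, qbounds, rbounds)
            assert system.check_feasible(menu)[0] == expected
            verdicts.append(expected)
        assert any(verdicts) and not all(verdicts)
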