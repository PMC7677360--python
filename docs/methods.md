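# Methods

## Model

A menu over a plan grid (meal set M, day set D, N_W weeks) is a 0/1 vector
x indexed by (slot, dish), with flat index `slot_index * n_dishes +
dish_index` and week-major slot order (week, then day, then meal). The
feasible set is defined by three linear constraint families:

* **Quantity bounds** `L_p <= Q^p(x) <= U_p` at meal, day, week or plan
  scope, where `Q^p` is the sum of the per-portion values `q_i^p` of the
  dishes served inside the scope. A two-sided bound is emitted as two
  one-sided scalar rows, one per scope instance; a one-sided bound as one
  row per instance. This convention makes constraint-family sizes exactly
  predictable: for example, four day-scope intervals plus three day-scope
  caps over a 20-day grid yield 4·2·20 + 3·20 = 220 inequality rows.
* **Rate bounds** `min <= R(x) <= max` counting servings of a dish, use
  group or food group per scope instance, emitted the same way.
* **Composition rules**: one equality per (rule, applicable slot) forcing
  exactly `exact_count` dishes of a use group in every slot of a meal type.

A meal's minimum share of the daily content of a parameter (e.g. breakfast
must provide at least 10 % of daily energy) is linear after rearrangement
and emitted as one row per day: `Q_meal - frac * Q_day >= 0`.

Assumptions inherited from the modelling paradigm: portions are fixed (no
fractional servings — a dish is either on the plate or not), parameter
values are per-portion constants independent of the rest of the menu (no
cooking-loss or interaction modelling), and all criteria are linear in x.
Units are fixed per parameter and never converted; tables mixing parameter
inventories are rejected at load.

### Soft constraints

A soft bound side is relaxed goal-programming style with one nonnegative
continuous deviation variable per side: `Q + d >= L` below, `Q - d <= U`
above, `d >= 0`, with a per-side weight (default 1 per unit of deviation)
collected into the objective through an aggregate `deviation_penalty`
factor. The inequality form is deliberate: relaxation must never shrink
the feasible set, and any menu feasible under the hard bound is feasible
under the softened form with zero deviation. Given an assignment, the
minimal deviations have the closed form `max(0, L - Q)` / `max(0, Q - U)`,
which both solvers use.

### Objectives and scalarization

An objective is `f(x) = sum_p c_p * Q^p(x, plan)` plus deviation
penalties; maximisation is coefficient negation. Two-objective trade-offs
are traced by:

* **ε-constraint sweep** (complete): minimise f1 subject to `f2 <= ε`.
  The ε schedule descends from max f2 over the feasible set, each value
  placed just below the f2 of the last point found and the final solve
  pinned at min f2, so a budget of at least the number of distinct front
  f2 values recovers the complete non-dominated set. Each solve is
  followed by a lexicographic second solve (min f2 subject to f1 at its
  optimum) so weakly dominated ties are resolved; dominated and duplicate
  vectors are filtered before the front is returned. An adaptive mode
  instead bisects the largest f2 gap between adjacent points, useful on
  very steep fronts.
* **weighted-sum sweep** (supported points only): minimise
  `alpha*f1 + (1-alpha)*f2` over a weight grid; its points are always a
  subset of the ε-constraint front.

Fronts are reported sorted by f1, optionally as percent change from the
minimum-f1 point (`100 * (v - v_ref) / v_ref`).

## Solvers

* **Exact**: depth-first search over slots branching on composition rules
  (one candidate per combination of rule choices, in lexicographic
  dish-index order). Pruning uses per-row interval bounds (running value
  plus the min/max achievable remaining contribution) and an objective
  lower bound from the assignment-linear part (deviation penalties are
  nonnegative, so omitting them keeps the bound valid). Dishes not
  reachable through any composition rule are never served by this method —
  the candidate space *is* the composition structure. Ties between equally
  optimal menus break deterministically to the first optimum in search
  order. The method refuses instances whose candidate space exceeds a cap
  (default 10^6) and directs the caller to the backend.
* **Backend**: the model is handed to the HiGHS mixed-integer solver
  (through `scipy.optimize.milp`) with `mip_rel_gap = 0` so optimality is
  proved, matching the exact solver. Returned menus are re-validated
  against the constraint system at the backend's own feasibility tolerance
  (1e-6; HiGHS may satisfy a row only to that precision) and the objective
  is recomputed with minimal deviations before acceptance. The interchange
  contract for other solvers is an LP-format model file plus a
  `variable value` solution-file parser.

Numerical choices: hard-row feasibility tolerance 1e-9 (exact arithmetic on
0/1 variables makes this generous); backend validation and objective
comparison at 1e-6; ε descent step `1e-5 * max(1, |f2|)`, which must exceed
the backend feasibility tolerance and therefore bounds the front resolution
— front points closer than that in f2 merge. Infeasible systems yield
`status="infeasible"`, never an exception; an empty feasible set in a sweep
raises explicitly.

## Synthetic scenarios

Three templates reproduce the *structure* of published case studies — a
20-day Spanish school-lunch plan (starter/main/dessert from 20/20/7
dishes), a 20-day Italian school-lunch plan (first/second/side from
33/48/23 plus bread and fruit), and a 14-day Italian full-board
nursing-home plan (breakfast from cereals/beverages/sweeteners 8/5/4;
lunch and dinner from first/second/side/bread/fruit 47/55/15/2/9) — while
the per-dish parameter values are synthetic: the underlying recipe,
food-composition, life-cycle and price databases are not published.

Values are drawn per use group from fixed distribution centres: nutrients
from normals truncated at zero (relative spread 0.25), price and footprints
from log-normals (sigma 0.4 — right-skewed and strictly positive), with
carbon-footprint means scaled by food group following the qualitative
life-cycle ordering (ruminant meat ≫ white meat ≈ fish > starches >
legumes/vegetables). Day-scope quantity bounds are calibrated to the
interquartile range of per-day totals of 200 random composition-valid
menus, which places feasible menus strictly inside the box; the calibration
is verified by one backend solve and redrawn (bounded retries) before an
explicit infeasible-scenario error. Generation is a pure function of
(spec, seed).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: real nutrient correlations across dishes (energy
and macronutrients are drawn independently), dish sharing between use
groups, seasonal price structure, and the published studies' actual
footprint/price optima. Quantitative optima of those studies (e.g. their
minimum-footprint or minimum-price values) are therefore out of reach by
construction; what is reproducible is the structural arithmetic (variable,
combination and row counts) and the qualitative trade-off shape — monotone
price-vs-carbon fronts, steep at the cheap end.

`shrink` scales use-group sizes and weeks down (ceil, floor 1) to create
exhaustively enumerable instances; oracle tests additionally reduce the
day set through the scenario spec's own grid fields.

## Design notes on open points

* A slot may in principle hold any set of dishes; "one per course" is a
  constraint, not a type invariant, so unusual meal structures stay
  expressible.
* Whether the per-meal-type combination counts of a multi-meal plan should
  be summed across meal types is left to the caller;
  `count_meal_combinations` is per meal type.
* Rate bounds at meal scope apply to every slot of the grid's meal
  instances (only day/week/plan scopes are exercised by the templates).
* The full-board template reuses the lunch dish pool and composition rules
  for dinner, matching full-board practice.
* In the CLI, `validate` prints model-structure statistics; exit codes are
  0 (success), 2 (infeasible model), 1 (any other error).

## Limitations

Desk-scale exactness: the built-in solver is for oracle-sized instances;
full-scale instances go to the backend, where proving a gap-0 optimum on
plans with many near-tied menus (log-normal objective data produce them)
can be slow. Sweeps default to the backend for such instances. No
portion-size optimization, ingredient substitution or nonlinear criteria;
sweeps are pairwise (dominance and filtering support any number of
objectives).
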