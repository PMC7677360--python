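# menuplan

Sustainable, culturally acceptable menu design as 0–1 binary integer linear
programming.

Classic diet optimization (the Stigler-style LP) returns *food plans* —
consumption levels of food groups — which say nothing about what actually
lands on a plate, and make variety and eating habits nearly impossible to
express. `menuplan` instead assigns whole, fixed-portion **dishes** to
**meal slots** over a multi-week plan, so the decision object is a realistic
menu and acceptability becomes a first-class linear constraint. It is aimed
at nutritionists, food-service planners and operations-research
practitioners designing school-lunch or full-board (e.g. nursing-home)
menus under nutritional, cultural, environmental and economic requirements.

## The model

A slot is a triple (m, d, w): meal *m* of day *d* of week *w*. For each of
the *N* dishes and each slot, a binary variable

x<sub>m,d,w</sub><sup>i</sup> ∈ {0, 1}

says whether dish *i* is served there, giving N·N<sub>M</sub>·N<sub>D</sub>·N<sub>W</sub>
variables. Each dish carries per-portion parameter values q<sub>i</sub><sup>p</sup>
(energy, macro/micronutrients, carbon and water footprints, price) and
belongs to *use groups* (its course: first, second, side, dessert, …) and
*food groups* (pasta, red meat, legumes, …). Everything of interest is
linear in x:

* **quantities** Q<sup>p</sup>(x) = Σ x·q<sup>p</sup> over a meal, day,
  week or the whole plan — bounded by dietary reference intakes
  (L<sub>p</sub> ≤ Q<sup>p</sup><sub>d,w</sub>(x) ≤ U<sub>p</sub>), footprint
  caps or budgets;
* **rates** R(x) — serving counts of a dish or group per scope — bounding
  repetition (e.g. red meat at most 3 times a week, a specific dish at most
  twice in the plan);
* **composition equalities** — exactly one dish per course per meal
  (Σ<sub>i∈first</sub> x<sup>i</sup><sub>lunch,d,w</sub> = 1, …), encoding
  the cultural meal structure.

Bounds may be *hard* or *soft* (goal programming: a nonnegative deviation
variable absorbs the miss and is penalised in the objective). A selection
criterion f(x) = Σ c<sub>p</sub>·Q<sup>p</sup>(x) is minimised over the
feasible set; with two conflicting goals (price vs. carbon footprint) the
**Pareto optimal set** is traced by ε-constraint or weighted-sum
scalarization.

Macronutrient ranges given as fractions of energy (AMDRs) convert to gram
bounds via energy density: 45–65 % of a 2 000 kcal diet at 4 kcal/g is
225–325 g of carbohydrate (`amdr_to_bounds`).

Two solve routes are provided: an exact pruned depth-first enumeration over
composition-valid menus (desk scale, used as the oracle in the test suite)
and delegation to the HiGHS mixed-integer backend via SciPy, with LP-format
export for any other external solver.

## Worked example

No recipe database is needed: the synthetic generator emulates three study
templates (`school_lunch_es`, `school_lunch_it`, `nursing_home_it`) with
calibrated, feasible constraint configurations. A reduced full-board
scenario, end to end:

```sh
menuplan generate --template nursing_home_it --seed 7 \
    --shrink-factor 0.2 --days mon,tue --weeks 1 --out-dir scenario
menuplan validate --recipes scenario/recipes.csv --plan scenario/plan.yaml \
    --constraints scenario/constraints.yaml
menuplan solve --recipes scenario/recipes.csv --plan scenario/plan.yaml \
    --constraints scenario/constraints.yaml \
    --objective scenario/objective.yaml --method backend --out-dir out
menuplan pareto --recipes scenario/recipes.csv --plan scenario/plan.yaml \
    --constraints scenario/constraints.yaml \
    --f1 price --f2 carbon_footprint --n-points 6 --method backend \
    --out-dir front
```

prints

```
scenario 'nursing_home_it' (seed 7): 31 dishes, 6 slots -> scenario
dishes:               31
slots:                6
binary variables:     186
...
objective min price: 10.4418
schedule written to out/schedule.csv
6 non-dominated points -> front/front.csv
```

`out/schedule.csv` is the cheapest feasible menu (10.44 EUR for the 2-day
plan), week-major with one row per serving; `out/report.json` holds per-day
quantities of every parameter. `front/front.csv` is the price-vs-carbon
Pareto front, and `front/summary.json` reports each point as percent change
from the minimum-price menu — here a 0.75 % price increase already buys an
18.1 % carbon-footprint reduction, the steep left limb typical of these
trade-off curves:

```
price %   carbon_footprint %
 0.000      0.000
 0.125     -0.826
 0.751    -18.144
 2.225    -18.284
 ...
```

The same machinery is available as a library (`menuplan.generate`,
`menuplan.solve`, `menuplan.epsilon_sweep`, …); the CLI is a thin wrapper.

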