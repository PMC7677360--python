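"""Linear objective functions over plan-level quantities.

An objective is a linear combination of whole-plan quantities
``f(x) = sum_p c_p * Q^p(x)`` plus, when soft constraints are present, a
penalty on the deviation variables.  Minimisation is the canonical sense;
maximising a quantity is encoded by negating its coefficient (the reporting
layer un-negates for display).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constraints import ConstraintSystem
from .plan_model import (
    InvalidConfigError,
    Menu,
    PlanGrid,
    RecipeTable,
    Scope,
    aggregate_quantity,
)


@dataclass(frozen=True)
class ObjectiveSpec:
    """A named linear objective: parameter coefficients plus an aggregate
    weight on soft-constraint deviations.

    ``terms`` maps parameter name -> coefficient; minimise is implied, so
    e.g. maximising iron content is ``{"iron": -1.0}``.
    """

    terms: tuple[tuple[str, float], ...]
    deviation_penalty: float = 0.0
    name: str = "objective"

    def __post_init__(self):
        terms = tuple((str(p), float(c)) for p, c in dict(self.terms).items())
        object.__setattr__(self, "terms", terms)
        if not self.terms and self.deviation_penalty == 0.0:
            raise InvalidConfigError(
                "objective needs at least one term or a deviation penalty"
            )
        for p, c in self.terms:
            if not np.isfinite(c):
                raise InvalidConfigError(f"coefficient for {p!r} not finite")
        if self.deviation_penalty < 0:
            raise InvalidConfigError("deviation_penalty must be >= 0")

    @classmethod
    def minimize(cls, parameter: str, name: str | None = None,
                 deviation_penalty: float = 0.0) -> "ObjectiveSpec":
        return cls(((parameter, 1.0),), deviation_penalty,
                   name or f"min {parameter}")

    @classmethod
    def maximize(cls, parameter: str, name: str | None = None,
                 deviation_penalty: float = 0.0) -> "ObjectiveSpec":
        return cls(((parameter, -1.0),), deviation_penalty,
                   name or f"max {parameter}")


@dataclass(frozen=True)
class ObjectiveVector:
    """Objective values f_1(x)..f_k(x) of one menu."""

    values: tuple[float, ...]

    def __post_init__(self):
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidConfigError("objective values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, i: int) -> float:
        return self.values[i]

    def __iter__(self):
        return iter(self.values)


def evaluate(spec: ObjectiveSpec, menu: Menu,
             deviations: np.ndarray | None = None,
             system: ConstraintSystem | None = None) -> float:
    """f(menu) = sum_p c_p * Q^p(menu, plan) + deviation penalties.

    Deviation penalties are ``deviation_penalty * sum_k w_k * d_k`` where
    the per-side weights ``w_k`` live on the bounds that created the
    deviation variables (``system.deviations``).
    """
    plan = Scope.plan()
    value = sum(c * aggregate_quantity(menu, p, plan)
                for p, c in spec.terms)
    if deviations is not None and len(deviations) and spec.deviation_penalty:
        if system is None:
            raise InvalidConfigError(
                "deviation penalties need the constraint system for weights"
            )
        weights = np.array([d.weight for d in system.deviations])
        value += spec.deviation_penalty * float(
            np.dot(weights, np.asarray(deviations, dtype=float))
        )
    return float(value)


def weighted_sum(specs: Sequence[ObjectiveSpec], alpha: float
                 ) -> ObjectiveSpec:
    """Convex combination of two objectives: coefficients alpha and 1-alpha.

    The deviation penalty is combined with the same weights.
    """
    if len(specs) != 2:
        raise InvalidConfigError(
            f"weighted_sum combines exactly 2 objectives, got {len(specs)}"
        )
    if not 0.0 <= alpha <= 1.0:
        raise InvalidConfigError(f"alpha must be in [0,1], got {alpha}")
    f1, f2 = specs
    merged: dict[str, float] = {}
    for p, c in f1.terms:
        merged[p] = merged.get(p, 0.0) + alpha * c
    for p, c in f2.terms:
        merged[p] = merged.get(p, 0.0) + (1.0 - alpha) * c
    return ObjectiveSpec(
        tuple(merged.items()),
        deviation_penalty=(alpha * f1.deviation_penalty
                           + (1 - alpha) * f2.deviation_penalty),
        name=f"{alpha:g}*{f1.name} + {1 - alpha:g}*{f2.name}",
    )


def objective_coefficients(spec: ObjectiveSpec, grid: PlanGrid,
                           table: RecipeTable,
                           system: ConstraintSystem | None = None
                           ) -> np.ndarray:
    """Dense coefficient vector over (binary ⊕ deviation) variables with
    f = c . (x ⊕ dev)."""
    n = table.n_dishes
    c_bin = np.zeros(grid.n_slots * n)
    for p, coeff in spec.terms:
        q = table.param_vector(p)
        c_bin += coeff * np.tile(q, grid.n_slots)
    if system is not None and system.n_deviations:
        c_dev = spec.deviation_penalty * np.array(
            [d.weight for d in system.deviations]
        )
        return np.concatenate([c_bin, c_dev])
    return c_bin


def objective_vector(menu: Menu, specs: Sequence[ObjectiveSpec],
                     deviations: np.ndarray | None = None,
                     system: ConstraintSystem | None = None
                     ) -> ObjectiveVector:
    """Evaluate several objectives on one menu."""
    return ObjectiveVector(tuple(
        evaluate(s, menu, deviations=deviations, system=system)
        for s in specs
    ))
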