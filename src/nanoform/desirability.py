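"""Derringer-Suich multi-response desirability optimization.

Each response prediction is mapped to an individual desirability
``d in [0, 1]`` via linear ramps between configurable lower/upper
anchors (raised to a weight exponent), and the overall desirability D
is the geometric mean of the individual scores.  D is maximized over
the coded factor cube [-1, 1]^3 by a dense deterministic grid search
followed by a Nelder-Mead polish.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import TransformDomainError
from .rsm import FittedModel, model_matrix, predict

__all__ = [
    "ResponseGoal",
    "DesirabilitySpec",
    "OptimizationResult",
    "desirability",
    "overall_desirability",
    "optimize_desirability",
    "prediction_error",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResponseGoal:
    """Goal and anchor window for one response, on its original scale."""

    name: str
    goal: str  # "minimize" | "maximize"
    lower: float
    upper: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.goal not in ("minimize", "maximize"):
            raise ValueError(f"goal must be minimize or maximize, got {self.goal!r}")
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: lower anchor must be below upper")
        if self.weight <= 0:
            raise ValueError(f"{self.name}: weight must be positive")


@dataclass
class DesirabilitySpec:
    """Per-response goals; responses absent from the spec are ignored."""

    goals: tuple[ResponseGoal, ...]

    def __post_init__(self) -> None:
        self.goals = tuple(self.goals)
        if not self.goals:
            raise ValueError("at least one response goal is required")


@dataclass
class OptimizationResult:
    coded_point: np.ndarray
    actual_values: dict[str, float]
    predictions: dict[str, float]
    individual: dict[str, float]
    overall: float

    def to_dict(self) -> dict:
        return {
            "coded_point": [float(v) for v in self.coded_point],
            "actual_factors": self.actual_values,
            "predicted_responses": self.predictions,
            "individual_desirability": self.individual,
            "overall_desirability": self.overall,
        }


def desirability(value: float, goal: str, lower: float, upper: float,
                 weight: float = 1.0) -> float:
    """One-sided Derringer desirability with clipping outside the anchors."""
    if not lower < upper:
        raise ValueError("lower anchor must be strictly below upper anchor")
    if goal == "maximize":
        frac = (value - lower) / (upper - lower)
    elif goal == "minimize":
        frac = (upper - value) / (upper - lower)
    else:
        raise ValueError(f"goal must be minimize or maximize, got {goal!r}")
    return float(np.clip(frac, 0.0, 1.0) ** weight)


def overall_desirability(d_values) -> float:
    """Geometric mean of individual desirabilities."""
    d = np.asarray(list(d_values), dtype=float)
    if d.size == 0:
        raise ValueError("no desirability values supplied")
    if np.any((d < 0) | (d > 1)):
        raise ValueError("individual desirabilities must lie in [0, 1]")
    if np.any(d == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(d))))


def default_anchors(response_values) -> tuple[float, float]:
    """Observed min/max of a response over the design runs."""
    v = np.asarray(response_values, dtype=float)
    return float(v.min()), float(v.max())


def _evaluate(models: dict[str, FittedModel], spec: DesirabilitySpec,
              point: np.ndarray) -> tuple[float, dict, dict]:
    preds, ds = {}, {}
    for goal in spec.goals:
        try:
            y = predict(models[goal.name], point)
        except TransformDomainError:
            log.warning("prediction domain error at %s for %s; D set to 0",
                        point.tolist(), goal.name)
            return 0.0, {}, {}
        preds[goal.name] = y
        ds[goal.name] = desirability(y, goal.goal, goal.lower, goal.upper,
                                     goal.weight)
    return overall_desirability(ds.values()), preds, ds


def optimize_desirability(models: dict[str, FittedModel],
                          spec: DesirabilitySpec,
                          grid_density: int = 41,
                          polish_tol: float = 1e-6) -> OptimizationResult:
    """Maximize overall desirability over the coded cube [-1, 1]^3.

    Deterministic: a full ``grid_density**3`` scan locates the basin,
    then a Nelder-Mead polish (coordinates clipped to the cube) refines
    it.  Ties in D are broken by the smaller predicted value of the
    first minimize-goal response, then by lexicographic coded point.
    """
    for goal in spec.goals:
        if goal.name not in models:
            raise KeyError(f"no fitted model supplied for response {goal.name!r}")
    minimize_names = [g.name for g in spec.goals if g.goal == "minimize"]

    grid = np.linspace(-1.0, 1.0, grid_density)
    points = np.array(list(itertools.product(grid, repeat=3)))
    d_each = np.ones((points.shape[0], len(spec.goals)))
    preds_grid_all = {}
    for j, goal in enumerate(spec.goals):
        m = models[goal.name]
        z = model_matrix(m.terms, points) @ m.coef
        with np.errstate(divide="ignore"):
            if m.transform.kind == "sqrt":
                y = np.where(z > 0, z ** 2, np.nan)
            elif m.transform.kind == "inverse":
                y = np.where(z > 0, 1.0 / np.where(z == 0, np.nan, z), np.nan)
            else:
                y = z
        preds_grid_all[goal.name] = y
        span = goal.upper - goal.lower
        frac = ((y - goal.lower) / span if goal.goal == "maximize"
                else (goal.upper - y) / span)
        d_each[:, j] = np.where(np.isnan(y), 0.0,
                                np.clip(np.nan_to_num(frac), 0.0, 1.0) ** goal.weight)
    d_all = np.prod(d_each, axis=1) ** (1.0 / len(spec.goals))
    tie = (np.nan_to_num(preds_grid_all[minimize_names[0]], nan=np.inf)
           if minimize_names else np.zeros(points.shape[0]))
    order = np.lexsort(tuple(points[:, ::-1].T) + (tie, -d_all))
    best_point = points[order[0]]

    def negd(p: np.ndarray) -> float:
        return -_evaluate(models, spec, np.clip(p, -1.0, 1.0))[0]

    res = optimize.minimize(negd, best_point, method="Nelder-Mead",
                            options={"xatol": polish_tol, "fatol": polish_tol ** 2,
                                     "maxiter": 2000})
    polished = np.clip(res.x, -1.0, 1.0)
    d_pol, preds_pol, ds_pol = _evaluate(models, spec, polished)
    d_grid, preds_grid, ds_grid = _evaluate(models, spec, best_point)
    if d_pol >= d_grid:
        point, d, preds, ds = polished, d_pol, preds_pol, ds_pol
    else:  # polish never worsens the grid optimum, but guard regardless
        point, d, preds, ds = best_point, d_grid, preds_grid, ds_grid

    factors = next(iter(models.values())).design.factors
    actual = {f.name: float(f.center + c * f.half_range)
              for f, c in zip(factors, point)}
    return OptimizationResult(
        coded_point=point, actual_values=actual,
        predictions=preds, individual=ds, overall=d,
    )


def prediction_error(experimental: float, predicted: float) -> float:
    """Percent deviation of a model prediction from the measured value."""
    if experimental == 0:
        raise ValueError("experimental value must be nonzero")
    return 100.0 * (experimental - predicted) / experimental
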