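"""Coarse-to-fine interval-shrinking search for SVM hyperparameters.

An evolutionary (iterative interval-refinement) alternative to exhaustive
grid search: evaluate a coarse grid over the current interval of each
parameter, re-center the interval on the best point, shrink interval and
step geometrically, and stop as soon as an iteration fails to improve the
best accuracy.  Both C and sigma are searched on a log10 scale, the standard
parameterization for SVM hyperparameters.  Exhaustive grid search is kept as
an optional mode and as the test oracle.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, TmsrespError

__all__ = ["ParamRange", "SearchSpace", "SearchTrace", "evolutionary_search", "grid_search"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParamRange:
    """One parameter's search interval and initial step, in log10 units."""

    name: str
    log_min: float
    log_max: float
    log_step: float

    def __post_init__(self) -> None:
        if self.log_min >= self.log_max:
            raise ParameterError(f"{self.name}: min must be below max")
        if self.log_step <= 0:
            raise ParameterError(f"{self.name}: step must be positive")


@dataclass(frozen=True)
class SearchSpace:
    """Search intervals for (C, sigma) plus the refinement schedule.

    Defaults: C in [1e-2, 1e3], sigma in [1e-2, 1e2], five grid points per
    axis initially, interval and step halved each iteration, at most six
    iterations (final step ~ 1.5% of the initial interval width).
    """

    params: tuple[ParamRange, ...] = (
        ParamRange("C", -2.0, 3.0, 1.25),
        ParamRange("sigma", -2.0, 2.0, 1.0),
    )
    shrink: float = 0.5
    max_iterations: int = 6

    def __post_init__(self) -> None:
        if not 0 < self.shrink < 1:
            raise ParameterError("shrink factor must be in (0, 1)")
        if self.max_iterations < 1:
            raise ParameterError("max_iterations must be >= 1")
        names = [p.name for p in self.params]
        if len(set(names)) != len(names):
            raise ParameterError("parameter names must be unique")


@dataclass
class SearchTrace:
    """Full audit of the search: per-iteration points, accuracies, bounds, best."""

    iterations: list[dict] = field(default_factory=list)
    best_params: dict[str, float] | None = None
    best_accuracy: float = -np.inf
    n_evaluations: int = 0

    def to_jsonable(self) -> dict:
        return {
            "iterations": self.iterations,
            "best_params": self.best_params,
            "best_accuracy": self.best_accuracy,
            "n_evaluations": self.n_evaluations,
        }


def _axis_points(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    return lo + step * np.arange(n)


def _evaluate_grid(objective, axes: list[np.ndarray], names: list[str],
                   trace: SearchTrace) -> list[tuple[tuple[float, ...], float]]:
    """Evaluate the objective at every grid point; failed points are skipped."""
    results = []
    for log_point in itertools.product(*axes):
        point = {n: 10.0**v for n, v in zip(names, log_point)}
        try:
            acc = float(objective(**point))
        except Exception as exc:  # objective failure: skip and log
            logger.warning("objective failed at %s: %s", point, exc)
            continue
        trace.n_evaluations += 1
        results.append((log_point, acc))
    return results


def _pick_best(results: list[tuple[tuple[float, ...], float]]) -> tuple[tuple[float, ...], float]:
    # ties broken toward the lexicographically smallest point (smaller C, then
    # smaller sigma): the simpler, smoother model
    best_acc = max(acc for _, acc in results)
    candidates = sorted(pt for pt, acc in results if acc == best_acc)
    return candidates[0], best_acc


def evolutionary_search(objective, space: SearchSpace = SearchSpace()) -> tuple[dict[str, float], SearchTrace]:
    """Interval-shrinking maximization of ``objective(**params) -> accuracy``.

    Each iteration evaluates the coarse grid of the current intervals,
    re-centers every interval on the best point seen in that iteration,
    and shrinks intervals and steps by the shrink factor.  The first
    iteration whose best fails to improve on the running best stops the
    search.  Returns the argmax over *all* evaluated points plus the trace.
    """
    names = [p.name for p in space.params]
    lows = np.array([p.log_min for p in space.params])
    highs = np.array([p.log_max for p in space.params])
    steps = np.array([p.log_step for p in space.params])
    lo, hi = lows.copy(), highs.copy()

    trace = SearchTrace()
    for it in range(space.max_iterations):
        axes = [_axis_points(lo[i], hi[i], steps[i]) for i in range(len(names))]
        results = _evaluate_grid(objective, axes, names, trace)
        if not results:
            raise TmsrespError("every objective evaluation failed in this iteration")
        iter_best_pt, iter_best_acc = _pick_best(results)
        trace.iterations.append(
            {
                "bounds": [[float(lo[i]), float(hi[i])] for i in range(len(names))],
                "step": steps.tolist(),
                "points": [
                    {**{n: 10.0**v for n, v in zip(names, pt)}, "accuracy": acc}
                    for pt, acc in results
                ],
                "iteration_best": {n: 10.0**v for n, v in zip(names, iter_best_pt)},
                "iteration_best_accuracy": iter_best_acc,
            }
        )
        improved = iter_best_acc > trace.best_accuracy
        if improved:
            trace.best_accuracy = iter_best_acc
            trace.best_params = {n: 10.0**v for n, v in zip(names, iter_best_pt)}
        if not improved and it > 0:
            break
        # re-center on the iteration best; clip to the original box
        center = np.array(iter_best_pt)
        width = (hi - lo) * space.shrink
        steps = steps * space.shrink
        lo = np.maximum(center - width / 2, lows)
        hi = np.minimum(center + width / 2, highs)
    return dict(trace.best_params), trace


def grid_search(objective, space: SearchSpace = SearchSpace(), resolution: int = 10) -> tuple[dict[str, float], float, int]:
    """Exhaustive evaluation on a ``resolution``-per-axis log grid.

    Returns (best params, best accuracy, points evaluated).  By construction
    this is the global maximum over the evaluated grid; the evolutionary
    search is validated against it.
    """
    if resolution < 1:
        raise ParameterError("resolution must be >= 1")
    names = [p.name for p in space.params]
    axes = [
        np.linspace(p.log_min, p.log_max, resolution) if resolution > 1
        else np.array([(p.log_min + p.log_max) / 2])
        for p in space.params
    ]
    trace = SearchTrace()
    results = _evaluate_grid(objective, axes, names, trace)
    if not results:
        raise TmsrespError("every objective evaluation failed")
    best_pt, best_acc = _pick_best(results)
    return {n: 10.0**v for n, v in zip(names, best_pt)}, best_acc, trace.n_evaluations
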