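"""Grid search over the three caller parameters against the in silico
validation set, maximising sensitivity.

Each candidate (min_correlation, min_coverage, transition_prob) triple is
run through the full caller; the resulting calls are projected onto the
validated regions and scored against the validation states.  Ties on the
objective break by higher F-score (so a call-everything configuration
never wins), then higher specificity, then proximity to the default
parameters (L2 distance on grid rank indices), then grid order — the
whole search is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .benchmark import ConfusionCounts, MetricsResult, confusion, metrics, states_from_calls
from .caller import CallerParams, CoverageMatrix, call_cohort
from .consensus import ValidationSet

__all__ = [
    "ParameterGrid",
    "GridEntry",
    "OptimizationResult",
    "default_grid",
    "evaluate_params",
    "optimize",
]

MAX_VALUES_PER_PARAMETER = 22

_DEFAULTS = CallerParams()


@dataclass(frozen=True)
class ParameterGrid:
    """Candidate values per parameter (each list capped at 22 values and
    required to contain the parameter's default, so the search can never
    do worse than the default configuration)."""

    correlation_values: tuple[float, ...]
    coverage_values: tuple[float, ...]
    transition_values: tuple[float, ...]
    search_mode: str = "full_grid"

    def __post_init__(self) -> None:
        if self.search_mode not in ("full_grid", "coordinate"):
            raise ValueError(f"unknown search mode {self.search_mode!r}")
        for label, values, default, lo, hi in (
            ("correlation", self.correlation_values, _DEFAULTS.min_correlation, 0.0, 1.0),
            ("coverage", self.coverage_values, _DEFAULTS.min_coverage, 0.0, math.inf),
            ("transition", self.transition_values, _DEFAULTS.transition_prob, 0.0, 0.5),
        ):
            if not values:
                raise ValueError(f"{label} grid is empty")
            if len(values) > MAX_VALUES_PER_PARAMETER:
                raise ValueError(
                    f"{label} grid has {len(values)} values; at most "
                    f"{MAX_VALUES_PER_PARAMETER} are supported"
                )
            if list(values) != sorted(values):
                raise ValueError(f"{label} grid must be sorted ascending")
            if not all(lo < v < hi if label != "coverage" else lo <= v < hi for v in values):
                raise ValueError(f"{label} grid values out of range")
            if default not in values:
                raise ValueError(
                    f"{label} grid must contain the default value {default}"
                )

    @property
    def size(self) -> int:
        return (
            len(self.correlation_values)
            * len(self.coverage_values)
            * len(self.transition_values)
        )


@dataclass(frozen=True)
class GridEntry:
    params: CallerParams
    counts: ConfusionCounts
    metrics: MetricsResult


@dataclass
class OptimizationResult:
    best: CallerParams
    table: list[GridEntry] = field(default_factory=list)
    objective: str = "sensitivity"

    def best_entry(self) -> GridEntry:
        for entry in self.table:
            if entry.params == self.best:
                return entry
        raise ValueError("best parameters missing from the results table")


def default_grid() -> ParameterGrid:
    """12 correlation x 10 coverage x 10 transition values (1200
    combinations), each list containing its parameter's default."""
    return ParameterGrid(
        correlation_values=(
            0.80, 0.82, 0.84, 0.86, 0.88, 0.90, 0.92, 0.94, 0.96, 0.97, 0.98, 0.99,
        ),
        coverage_values=(20, 40, 60, 80, 100, 120, 140, 160, 180, 200),
        transition_values=(
            1e-5, 3e-5, 1e-4, 3e-4, 1e-3, 3e-3, 0.01, 0.03, 0.1, 0.2,
        ),
        search_mode="full_grid",
    )


def evaluate_params(
    params: CallerParams,
    matrix: CoverageMatrix,
    validation: ValidationSet,
    mode: str = "default",
) -> tuple[ConfusionCounts, MetricsResult]:
    """Score one parameter combination: run the caller, restrict its calls
    to the validated regions, and compare with the validation states.

    An all-no-call outcome is a legitimate (terrible) evaluation, not an
    error: every validated CNV scores as a false negative.
    """
    if validation.is_empty():
        raise ValueError("validation set is empty; build the consensus first")
    callset = call_cohort(matrix, params, mode=mode)
    rois_by_key = {r.key: r.interval for r in matrix.rois}
    predicted = states_from_calls(
        callset,
        samples=validation.states.samples,
        regions=validation.validated_regions,
        nocall_policy="as_normal",
        rois_by_key=rois_by_key,
    )
    counts = confusion(predicted, validation.states)
    return counts, metrics(counts)


_OBJECTIVES = ("sensitivity", "specificity", "ppv", "npv", "f_score")


def _score_tuple(entry: GridEntry, objective: str, grid: ParameterGrid) -> tuple:
    m = entry.metrics.as_dict()

    def val(name: str) -> float:
        v = m[name]
        return -math.inf if v is None else v

    # proximity to defaults measured on grid rank indices
    ranks = (
        grid.correlation_values.index(entry.params.min_correlation)
        if entry.params.min_correlation in grid.correlation_values
        else -1,
        grid.coverage_values.index(entry.params.min_coverage)
        if entry.params.min_coverage in grid.coverage_values
        else -1,
        grid.transition_values.index(entry.params.transition_prob)
        if entry.params.transition_prob in grid.transition_values
        else -1,
    )
    default_ranks = (
        grid.correlation_values.index(_DEFAULTS.min_correlation),
        grid.coverage_values.index(_DEFAULTS.min_coverage),
        grid.transition_values.index(_DEFAULTS.transition_prob),
    )
    dist2 = sum((a - b) ** 2 for a, b in zip(ranks, default_ranks))
    return (val(objective), val("f_score"), val("specificity"), -dist2)


def optimize(
    matrix: CoverageMatrix,
    validation: ValidationSet,
    grid: Optional[ParameterGrid] = None,
    objective: str = "sensitivity",
    mode: str = "default",
) -> OptimizationResult:
    """Search the parameter grid and return the best combination plus the
    complete per-combination results table.

    ``full_grid`` evaluates every combination.  ``coordinate`` sweeps one
    parameter at a time holding the others at the current best, repeating
    the pass once if the incumbent changed (a deterministic heuristic for
    large grids whose best can only match, never beat, the full grid).
    """
    if grid is None:
        grid = default_grid()
    if objective not in _OBJECTIVES:
        raise ValueError(f"unknown objective {objective!r}; pick one of {_OBJECTIVES}")
    if validation.is_empty():
        raise ValueError("validation set is empty; run the consensus step first")

    cache: dict[CallerParams, GridEntry] = {}

    def evaluate(params: CallerParams) -> GridEntry:
        if params not in cache:
            counts, m = evaluate_params(params, matrix, validation, mode=mode)
            cache[params] = GridEntry(params=params, counts=counts, metrics=m)
        return cache[params]

    def better(a: GridEntry, b: GridEntry) -> bool:
        return _score_tuple(a, objective, grid) > _score_tuple(b, objective, grid)

    if grid.search_mode == "full_grid":
        best: Optional[GridEntry] = None
        for corr in grid.correlation_values:
            for cov in grid.coverage_values:
                for trans in grid.transition_values:
                    entry = evaluate(CallerParams(corr, cov, trans))
                    if best is None or better(entry, best):
                        best = entry
        assert best is not None
    else:
        current = evaluate(_DEFAULTS)
        for _pass in range(2):
            changed = False
            for axis, values in (
                ("min_correlation", grid.correlation_values),
                ("min_coverage", grid.coverage_values),
                ("transition_prob", grid.transition_values),
            ):
                for v in values:
                    kwargs = {
                        "min_correlation": current.params.min_correlation,
                        "min_coverage": current.params.min_coverage,
                        "transition_prob": current.params.transition_prob,
                    }
                    kwargs[axis] = v
                    entry = evaluate(CallerParams(**kwargs))
                    if better(entry, current):
                        current = entry
                        changed = True
            if not changed:
                break
        best = current

    table = sorted(
        cache.values(),
        key=lambda e: (
            e.params.min_correlation,
            e.params.min_coverage,
            e.params.transition_prob,
        ),
    )
    return OptimizationResult(best=best.params, table=table, objective=objective)
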