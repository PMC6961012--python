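"""Sequential optimization of the adjustable classifier parameters.

One parameter is swept at a time over a grid while the others stay fixed:
first the segmentation window size (at the legacy activity threshold), then
the activity threshold at the chosen window size.  The orientation
threshold is never varied — for a fixed wear location it is a geometric
constant.

For each grid value, every participant's recording is classified and the
per-class absolute percentage error against the annotation totals is
computed; the grid objective is the sum over the three classes of the group
median APE.  Summing treats the classes equally and, because APE does not
cancel signed errors, tracks individual-level accuracy.  Ties break toward
the smaller parameter value: shorter windows resolve activity transitions
better, and a lower threshold is the more sensitive choice at equal error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .agreement import AgreementReport, compute_agreement
from .classify import (
    AlgorithmParameters,
    classify_branches,
    class_totals,
    prepare_branches,
)
from .io import AccelerometerRecording, ActivityLabel, AnnotationSeries, annotation_totals

_SWEEPABLE = ("window_size", "pa_threshold")


@dataclass(frozen=True)
class GridPoint:
    """Agreement summary for one grid value of the swept parameter."""

    value: float
    report: AgreementReport

    @property
    def objective(self) -> float:
        """Sum of per-class median APE across the classes present."""
        return sum(s.median_ape for s in self.report.group.values())


@dataclass
class ParameterGridResult:
    """Full sweep of one parameter."""

    parameter_name: str
    points: list[GridPoint] = field(default_factory=list)

    @property
    def best_value(self) -> float:
        """Grid value minimizing the objective; ties go to the smaller value."""
        best = min(self.points, key=lambda p: (p.objective, p.value))
        return best.value

    @property
    def best_objective(self) -> float:
        return min(p.objective for p in self.points)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (grid value, class)."""
        rows = []
        for point in self.points:
            for label in ActivityLabel:
                summary = point.report.group.get(label)
                if summary is None:
                    continue
                rows.append(
                    {
                        "value": point.value,
                        "class": label.value,
                        "median_pe": summary.median_pe,
                        "pe_ci_low": summary.pe_ci[0],
                        "pe_ci_high": summary.pe_ci[1],
                        "median_ape": summary.median_ape,
                        "ape_ci_low": summary.ape_ci[0],
                        "ape_ci_high": summary.ape_ci[1],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class OptimizationResult:
    """Outcome of the two-stage sweep."""

    best_window_size: float
    best_pa_threshold: float
    window_grid: ParameterGridResult
    pa_grid: ParameterGridResult

    @property
    def best_objective(self) -> float:
        return self.pa_grid.best_objective

    @property
    def best_parameters(self) -> AlgorithmParameters:
        return AlgorithmParameters(
            window_size=self.best_window_size,
            pa_threshold=self.best_pa_threshold,
        )


Dataset = list[tuple[AccelerometerRecording, AnnotationSeries]]


def _prepare_dataset(dataset: Dataset, constants):
    """Filter every recording once; sweeps reuse the BA/GA branches."""
    prepared = []
    for recording, annotation in dataset:
        ba, ga = prepare_branches(recording, constants)
        prepared.append((recording.subject_id, ba, ga, annotation_totals(annotation)))
    return prepared


def _evaluate_prepared(prepared, params: AlgorithmParameters) -> AgreementReport:
    totals = []
    for subject_id, ba, ga, gold in prepared:
        series = classify_branches(ba, ga, params)
        totals.append((subject_id, gold, class_totals(series)))
    return compute_agreement(totals)


def evaluate_dataset(
    dataset: Dataset, params: AlgorithmParameters
) -> AgreementReport:
    """Classify every participant and report PE/APE agreement per class."""
    if not dataset:
        raise ValueError("dataset must be non-empty")
    prepared = _prepare_dataset(dataset, params.filter_constants)
    return _evaluate_prepared(prepared, params)


def evaluate_grid(
    dataset: Dataset,
    base_params: AlgorithmParameters,
    parameter_name: str,
    values,
) -> ParameterGridResult:
    """Sweep one parameter over ``values``, holding the others at base."""
    if parameter_name not in _SWEEPABLE:
        raise ValueError(
            f"parameter_name must be one of {_SWEEPABLE}, got {parameter_name!r}"
        )
    values = list(values)
    if not values:
        raise ValueError("values must be non-empty")
    if not dataset:
        raise ValueError("dataset must be non-empty")
    prepared = _prepare_dataset(dataset, base_params.filter_constants)
    result = ParameterGridResult(parameter_name=parameter_name)
    for value in values:
        params = base_params.replace(**{parameter_name: float(value)})
        result.points.append(
            GridPoint(value=float(value), report=_evaluate_prepared(prepared, params))
        )
    return result


def optimize_sequential(
    dataset: Dataset,
    ws_values=tuple(range(1, 11)),
    pa_values=tuple(range(3, 13)),
    base_params: AlgorithmParameters | None = None,
) -> OptimizationResult:
    """Two-stage sweep: window size first, then activity threshold.

    Defaults sweep window sizes 1–10 s at the legacy 5 cps threshold, then
    thresholds 3–12 cps at the chosen window size.  The orientation
    threshold is held fixed throughout.
    """
    from .classify import LEGACY_PARAMETERS

    if base_params is None:
        base_params = LEGACY_PARAMETERS
    ws_values = list(ws_values)
    pa_values = list(pa_values)
    if not ws_values or not pa_values:
        raise ValueError("ws_values and pa_values must be non-empty")
    ws_grid = evaluate_grid(dataset, base_params, "window_size", ws_values)
    best_ws = ws_grid.best_value
    pa_grid = evaluate_grid(
        dataset,
        base_params.replace(window_size=best_ws),
        "pa_threshold",
        pa_values,
    )
    return OptimizationResult(
        best_window_size=best_ws,
        best_pa_threshold=pa_grid.best_value,
        window_grid=ws_grid,
        pa_grid=pa_grid,
    )
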