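"""Benchmark table and combinatorial apply machinery.

A :class:`BenchmarkTable` is a long-format table with one row per
dataset x method combination. The first step column is always ``data``
(the dataset name); each call to :func:`apply_methods` appends one step
column and multiplies the row count by the size of the applied method list.
The terminal ``result`` column holds a :class:`StepOutcome`: either the
success value produced by the row's method chain or the error record of the
first failure, propagated downstream without re-executing later methods.

Failures are data, not exceptions: a method that raises is recorded as a
per-row failure and the benchmark continues. Row counts are invariant under
failures, so the Cartesian structure D x |L1| x ... x |Lk| always holds.
"""

from __future__ import annotations

import logging
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Mapping, Optional, Sequence

import pandas as pd

from .errors import ValidationError
from .registry import Method, MethodList
from .sc_data import SCDataset

__all__ = [
    "ErrorRecord",
    "StepOutcome",
    "BenchmarkRow",
    "BenchmarkTable",
    "begin_benchmark",
    "apply_methods",
    "collect_results",
    "pipeline_id",
]

logger = logging.getLogger("pipebench")

PIPE_SEP = "→"  # arrow used to join method names into a pipeline id


@dataclass(frozen=True)
class ErrorRecord:
    """Provenance of the first failure along a row's method chain."""

    message: str
    step: str
    method: str
    upstream: bool = False


@dataclass(frozen=True)
class StepOutcome:
    """Tagged union: success(value) | failure(error record)."""

    status: str  # "success" | "failure"
    value: Any = None
    error: Optional[ErrorRecord] = None

    def __post_init__(self) -> None:
        if self.status not in ("success", "failure"):
            raise ValueError(f"invalid status {self.status!r}")
        if self.status == "failure" and self.error is None:
            raise ValueError("failure outcome requires an error record")
        if self.status == "success" and self.error is not None:
            raise ValueError("success outcome must not carry an error record")

    @property
    def is_failure(self) -> bool:
        return self.status == "failure"

    @classmethod
    def success(cls, value: Any) -> "StepOutcome":
        return cls(status="success", value=value)

    @classmethod
    def failure(cls, message: str, step: str, method: str,
                upstream: bool = False) -> "StepOutcome":
        return cls(status="failure",
                   error=ErrorRecord(message=message, step=step,
                                     method=method, upstream=upstream))


@dataclass(frozen=True)
class BenchmarkRow:
    """One dataset x method combination: step labels plus its outcome."""

    steps: tuple[str, ...]  # method name per step column, first is dataset name
    result: Any  # StepOutcome or timing.TimedOutcome


@dataclass(frozen=True)
class BenchmarkTable:
    """Long-format benchmark table (rectangular by construction)."""

    step_names: tuple[str, ...]  # first is always "data"
    rows: tuple[BenchmarkRow, ...]

    def __post_init__(self) -> None:
        if not self.step_names or self.step_names[0] != "data":
            raise ValidationError('first step column must be "data"')
        for row in self.rows:
            if len(row.steps) != len(self.step_names):
                raise ValidationError("ragged benchmark table")
        keys = [row.steps for row in self.rows]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (dataset, methods...) combinations")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def outcome(self, i: int) -> StepOutcome:
        """The plain StepOutcome of row ``i`` (durations stripped)."""
        return _resolve(self.rows[i].result)

    def __repr__(self) -> str:
        n_fail = sum(1 for i in range(len(self.rows)) if self.outcome(i).is_failure)
        return (
            f"BenchmarkTable({self.n_rows} rows, steps={list(self.step_names)}, "
            f"{n_fail} failures)"
        )


def _resolve(result: Any) -> StepOutcome:
    """Unwrap TimedOutcome wrappers down to the underlying StepOutcome."""
    while not isinstance(result, StepOutcome):
        result = result.inner
    return result


def begin_benchmark(datasets: Mapping[str, SCDataset]) -> BenchmarkTable:
    """Start a benchmark table with one success row per named dataset."""
    items = list(datasets.items())
    if not items:
        raise ValueError("begin_benchmark requires at least one dataset")
    names = [n for n, _ in items]
    if len(set(names)) != len(names):
        raise ValueError("duplicate dataset names")
    rows = tuple(
        BenchmarkRow(steps=(name,), result=StepOutcome.success(ds))
        for name, ds in items
    )
    return BenchmarkTable(step_names=("data",), rows=rows)


def _run_one(row: BenchmarkRow, method: Method, step_name: str,
             validator: Optional[Callable[[Any], None]],
             timed: bool) -> Any:
    """Execute one (row, method) task; exceptions become failure outcomes."""
    prev = _resolve(row.result)
    if prev.is_failure:
        # propagate the original error verbatim; the method is not invoked
        outcome = StepOutcome(
            status="failure", error=replace(prev.error, upstream=True)
        )
        duration = 0.0
    else:
        t0 = time.monotonic()
        try:
            value = method(prev.value)
            if validator is not None:
                validator(value)
            outcome = StepOutcome.success(value)
        except Exception as exc:  # failures are data, not crashes
            outcome = StepOutcome.failure(
                message=f"{type(exc).__name__}: {exc}",
                step=step_name, method=method.name,
            )
        duration = time.monotonic() - t0
    logger.debug(
        "step=%s method=%s dataset=%s status=%s duration=%.6fs",
        step_name, method.name, row.steps[0], outcome.status, duration,
    )
    if timed:
        from .timing import TimedOutcome  # local import to avoid a cycle

        return TimedOutcome(duration=duration, inner=outcome)
    return outcome


def _expand(t: BenchmarkTable, ml: MethodList, workers: int,
            timed: bool) -> BenchmarkTable:
    if ml.step_name in t.step_names:
        raise ValueError(
            f"step column {ml.step_name!r} already exists in the table"
        )
    if workers < 1:
        raise ValueError("workers must be a positive integer")
    tasks = [(row, method) for row in t.rows for method in ml]
    if workers == 1:
        results = [
            _run_one(row, m, ml.step_name, ml.validator, timed)
            for row, m in tasks
        ]
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            results = list(
                pool.map(
                    lambda task: _run_one(task[0], task[1], ml.step_name,
                                          ml.validator, timed),
                    tasks,
                )
            )
    rows = tuple(
        BenchmarkRow(steps=row.steps + (method.name,), result=res)
        for (row, method), res in zip(tasks, results)
    )
    return BenchmarkTable(step_names=t.step_names + (ml.step_name,), rows=rows)


def apply_methods(t: BenchmarkTable, ml: MethodList,
                  workers: int = 1) -> BenchmarkTable:
    """Apply every method of ``ml`` to every row of ``t``.

    Output has ``len(t) * len(ml)`` rows (failures never drop rows) and a new
    step column named ``ml.step_name``. Row order is input-major,
    method-minor: for each input row in order, each method in registration
    order. Rows whose result is already a failure propagate it with
    ``upstream=True`` without invoking the method. The output is identical
    for any ``workers`` value (methods must be deterministic; stochastic
    methods bind an explicit seed at registration).
    """
    return _expand(t, ml, workers, timed=False)


def pipeline_id(row: BenchmarkRow | Sequence[str]) -> str:
    """Join a row's method names (excluding the dataset) with an arrow.

    Stable and unique per method combination; rows with the same methods on
    different datasets share a pipeline id.
    """
    steps = row.steps if isinstance(row, BenchmarkRow) else tuple(row)
    return PIPE_SEP.join(steps[1:]) if len(steps) > 1 else ""


def collect_results(t: BenchmarkTable, scalar_only: bool = False) -> pd.DataFrame:
    """Export a benchmark table as a tidy DataFrame.

    Columns: the step columns, then ``value`` (the success value, or empty
    on failure) and ``error`` (the failure message, or empty on success).
    Tables produced by ``time_methods`` gain a ``seconds`` column. With
    ``scalar_only=True`` every success value must be a numeric scalar (the
    usual state after a metric step).
    """
    from .timing import TimedOutcome

    records = []
    timed = any(isinstance(r.result, TimedOutcome) for r in t.rows)
    for i, row in enumerate(t.rows):
        outcome = t.outcome(i)
        rec: dict[str, Any] = dict(zip(t.step_names, row.steps))
        if outcome.is_failure:
            rec["value"] = None
            err = outcome.error
            rec["error"] = f"[{err.step}/{err.method}] {err.message}"
        else:
            value = outcome.value
            if scalar_only and not isinstance(value, (int, float)):
                raise ValidationError(
                    f"row {i} ({pipeline_id(row)}): non-scalar result "
                    f"{type(value).__name__} with scalar_only=True"
                )
            rec["value"] = value
            rec["error"] = ""
        if timed:
            res = row.result
            rec["seconds"] = round(res.duration, 6) if isinstance(res, TimedOutcome) else 0.0
        records.append(rec)
    columns = list(t.step_names) + ["value", "error"] + (["seconds"] if timed else [])
    return pd.DataFrame.from_records(records, columns=columns)
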