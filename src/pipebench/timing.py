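"""Per-combination running-time measurement.

``time_methods`` has identical expansion semantics to ``apply_methods`` but
wraps each outcome in a :class:`TimedOutcome` carrying the wall-clock
duration of the method call (monotonic clock; adapters registered as part of
the method are included; expansion bookkeeping is not). Upstream-propagated
failures carry duration 0 because the method is never invoked.

``scaling_series`` sub-samples a dataset to several sizes and times one
method list on each, giving controlled run-time scaling measurements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import pandas as pd

from .core import BenchmarkTable, StepOutcome, begin_benchmark, _expand
from .registry import MethodList
from .sc_data import SCDataset, sample_cells

__all__ = ["TimedOutcome", "time_methods", "scaling_series"]


@dataclass(frozen=True)
class TimedOutcome:
    """Wall-clock duration (seconds) around an inner outcome."""

    duration: float
    inner: Any  # StepOutcome, or TimedOutcome from an earlier timed step

    def __post_init__(self) -> None:
        if not (self.duration >= 0):
            raise ValueError("duration must be non-negative")


def time_methods(t: BenchmarkTable, ml: MethodList,
                 workers: int = 1) -> BenchmarkTable:
    """Like :func:`~pipebench.core.apply_methods`, recording durations.

    Stripping the durations from the result reproduces ``apply_methods``
    output exactly (same rows, same outcomes).
    """
    return _expand(t, ml, workers, timed=True)


def strip_durations(t: BenchmarkTable) -> BenchmarkTable:
    """Replace every TimedOutcome with its underlying StepOutcome."""
    from dataclasses import replace

    rows = tuple(
        replace(row, result=t.outcome(i)) for i, row in enumerate(t.rows)
    )
    return BenchmarkTable(step_names=t.step_names, rows=rows)


def scaling_series(d: SCDataset, sizes: Sequence[int], ml: MethodList,
                   seed: int) -> pd.DataFrame:
    """Time ``ml`` on sub-samples of ``d`` at each cell count in ``sizes``.

    Returns a tidy table with columns (size, step, method, seconds), one row
    per size x method. Sub-sampling uses ``sample_cells`` with the given
    seed, so the series is reproducible and nested comparisons are
    controlled.
    """
    sizes = list(sizes)
    if not sizes:
        raise ValueError("sizes must be a non-empty list of cell counts")
    records = []
    for size in sizes:
        sub = sample_cells(d, size, seed)
        timed = time_methods(begin_benchmark({d.name: sub}), ml)
        for row in timed.rows:
            records.append({
                "size": size,
                "step": ml.step_name,
                "method": row.steps[-1],
                "seconds": round(row.result.duration, 6),
            })
    return pd.DataFrame.from_records(
        records, columns=["size", "step", "method", "seconds"]
    )
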