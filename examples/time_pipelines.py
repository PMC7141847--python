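"""Measure per-combination running times and run-time scaling.

time_methods mirrors apply_methods but records the wall-clock duration of
every method call; scaling_series sub-samples cells to measure how run time
grows with dataset size.
"""

from pipebench import (
    SimConfig,
    begin_benchmark,
    collect_results,
    demo_method_lists,
    simulate_dataset,
    time_methods,
)
from pipebench.timing import scaling_series

d = simulate_dataset(SimConfig(n_genes=200, n_cells=120, seed=7), name="sim")
norm, impute, cluster = demo_method_lists(seed=1)

table = begin_benchmark({"sim": d})
for ml in (norm, impute, cluster):
    table = time_methods(table, ml)
timings = collect_results(table)
print(timings[["norm_method", "impute_method", "cluster_method", "seconds"]]
      .head(9).to_string(index=False))
# "seconds" is the wall-clock duration of the last applied step only.

# scaling_series times a step that consumes raw datasets (here the
# normalizers) on sub-samples of increasing size.
series = scaling_series(d, sizes=[30, 60, 120], ml=norm, seed=0)
print(series.to_string(index=False))
# One timed record per (cell count, method): how each normalizer scales as
# the dataset grows.
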