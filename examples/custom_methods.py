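"""Register your own method lists and see error tolerance in action.

A benchmark is just: begin_benchmark -> apply_methods per step. Methods of
one step share an input/output contract; wrap_method adapts a core function
to that contract. A method that raises records a per-row failure and the
benchmark keeps running — downstream steps propagate the failure without
re-executing.
"""

import numpy as np

from pipebench import (
    SimConfig,
    apply_methods,
    begin_benchmark,
    collect_results,
    make_method_list,
    simulate_dataset,
    wrap_method,
)
from pipebench.demo import state_from_dataset


def sqrt_stabilize(state):
    return state.__class__(matrix=np.sqrt(state.matrix),
                           gene_ids=state.gene_ids, cell_ids=state.cell_ids,
                           labels=state.labels, name=state.name)


def broken_transform(state):
    raise RuntimeError("this method is deliberately broken")


norm = make_method_list("transform", {
    "identity": wrap_method(lambda s: s, pre_adapter=state_from_dataset),
    "sqrt": wrap_method(sqrt_stabilize, pre_adapter=state_from_dataset),
    "broken": wrap_method(broken_transform, pre_adapter=state_from_dataset),
})
score = make_method_list("score", {
    "total": lambda s: float(s.matrix.sum()),
    "n_zero": lambda s: float((s.matrix == 0).sum()),
})

d = simulate_dataset(SimConfig(n_genes=50, n_cells=30, seed=0), name="toy")
table = apply_methods(apply_methods(begin_benchmark({"toy": d}), norm), score)
print(collect_results(table, scalar_only=False).to_string(index=False))
# 1 dataset x 3 transforms x 2 scores = 6 rows; the two "broken" rows carry
# the original error message with upstream provenance instead of a value.
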