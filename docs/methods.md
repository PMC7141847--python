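# Methods

## The benchmark model

A benchmark is a long-format table. `begin_benchmark` seeds one row per
named dataset; each `apply_methods(table, method_list)` call replaces every
row with one row per method in the list, appending a step column that
records the method name. After applying lists L₁…Lₖ to D datasets the table
holds exactly D·|L₁|·…·|Lₖ| rows — the full Cartesian product — and this
count is invariant under failures. Row order is fixed as input-major,
method-minor (for each input row in order, each method in registration
order), so outputs are diffable and parallel execution can reassemble
deterministically.

The result column holds a tagged outcome: `success(value)` or
`failure(error record)`. A method that raises is captured per row with the
step and method that raised; rows already failed propagate the original
error verbatim with `upstream=True` and the next method is *not* invoked —
re-running a method on a failed row could only produce noise, and skipping
keeps failed subtrees cheap. Methods must be pure with respect to the table
(no mutation of their input); stochastic methods bind an explicit seed at
registration, so the framework itself introduces no randomness.

Parallelism uses a thread pool with per-task scheduling and reassembly by
task index. Threads avoid any pickling constraint on registered callables
and the numerical workhorses (BLAS, scikit-learn) release the GIL; the
contract is only that outputs are identical for any worker count, which the
deterministic reassembly guarantees for deterministic methods.

## Timing

`time_methods` has identical expansion semantics and wraps each outcome
with the wall-clock (monotonic) duration of the method call. Wall clock
rather than CPU time matches the user-facing notion of running time and
works for methods that shell out. Adapters attached by `wrap_method` are
timed as part of the method — they are part of the method as registered —
while expansion bookkeeping is excluded. Upstream-propagated failures carry
duration 0. `scaling_series` sub-samples cells (`sample_cells`, seeded) to
measure run time at controlled dataset sizes.

## Metrics

* **Adjusted Rand index** (Hubert–Arabie) from the contingency table; see
  README for the formula. The chance-correction denominator is 0 exactly
  when both partitions are all singletons or both are a single cluster; the
  formula is then 0/0 and we return 1.0 when the partitions coincide and
  0.0 otherwise (a documented convention — with the degenerate cases the
  partitions in fact always coincide). The implementation is cross-checked
  in the tests against a brute-force pair-counting oracle and against
  scikit-learn.
* **Mean silhouette width**, Euclidean, on the embedding the clustering
  step stored in its result; singleton clusters score 0 (Rousseeuw's
  convention; scikit-learn's `silhouette_samples` implements this). A
  single-cluster assignment is undefined and raises, which the benchmark
  records as a per-row failure. An all-singleton assignment returns 0
  directly.
* **Cluster-count deviation**: (#distinct assigned) − (#distinct true),
  signed.

Metrics return plain scalars and are packaged as a method list, so they
chain through `apply_methods` like any other step.

## Synthetic data

The generator emulates clustered scRNA-seq counts: gene baseline means from
Gamma(2, 1); per group, round(`de_frac`·n_genes) genes receive a 2^±lfc
multiplier with sign by fair coin; cells are assigned to groups from
`group_props`; library sizes are log-normal (`lib_size_mu` is the median
total count per cell); expected counts are the cell's library size times
its group's normalized expression profile; counts are gamma-Poisson with
variance μ + φμ². Random draws occur in a fixed, documented order from one
seeded generator, so datasets are bit-reproducible.

Defaults (200 genes × 120 cells, 3 balanced groups, de_frac 0.1, lfc 2,
φ 0.1, median depth 5000, σ_log 0.25) describe a small, well-powered
plate-like experiment; `simulate_pair` adds a droplet-like variant at one
tenth the depth, which raises the zero fraction from ~1% to ~25%. What the
generator does **not** emulate: zero-inflation beyond NB sampling, batch
effects, trajectories, doublets, or realistic gene-gene correlation.
Passing benchmarks on this data therefore demonstrates that the framework
and method plumbing behave correctly and that the stand-in methods recover
strong, well-separated structure — not that any method would win on real
tissue.

## Stand-in methods

The demonstration lists mirror a 4 × 3 × 3 design with self-contained
stand-ins: normalization = {none, cpm, logcpm, median-of-ratios with a
"poscounts" geometric mean so it is defined on sparse data}; imputation =
{none, kNN smoothing in PCA space (k = 5), one-step row-normalized
kNN-graph diffusion}; clustering = {k-means, Ward agglomeration, kNN graph
+ greedy modularity}. k-means and Ward read the true group count from the
labels, mirroring a benchmark's use of ground truth; the graph clusterer's
community count is data-driven, which is what makes the cluster-count
metric informative.

Clustering stand-ins (and the imputers' neighbour search) embed cells by
median-depth equalization → log1p → per-gene z-score → 10-component PCA.
Internal depth normalization inside a clustering wrapper reflects how real
single-cell clustering tools preprocess their input, and it makes the
wrappers robust to whatever scale the upstream normalization produced
(on depth-equalized input it is a near-identity). The upstream steps still
change the matrix the clusterer sees, which is what the benchmark measures.

Inter-step state is a bundle (matrix, gene/cell ids, labels, name) because
clusterers need labels for k and metrics need identifiers; the wrapper
contract leaves payload design to the method-list author.

## Numerical and design choices

* Sampling utilities subset without shuffling (original axis order kept) —
  stable diffs and conserved cell/label pairing. Sampling is simple uniform,
  not stratified by label.
* Counts are validated as non-negative integers at construction/read time;
  fractional input is a hard error rather than silent rounding.
* Top-k ranking breaks ties by descending ARI then lexicographic pipeline
  id; ranking is per (clusterer, dataset), and `k` larger than the
  available pipelines returns everything with a warning.
* Step-column name collisions are errors, not auto-renames — silent renames
  hide configuration bugs.
* Method names must be CSV-safe (no commas/newlines), enforced at
  registration, because they become cell values in exported tables.
* Problem sizes throughout (200 × 120 simulations, 10 PCs, 500-pair metric
  cross-checks) keep the full demonstration and test suite in the
  tens-of-seconds range on a single CPU while leaving the group structure
  statistically unambiguous.

## Known limitations

Evaluation is eager; there is no deferred pipeline construction, no result
caching, and no cross-machine distribution. Loaders cover Matrix Market and
dense CSV/TSV only. The stand-in methods are deliberately simple and are
not substitutes for evaluating real normalization/imputation/clustering
tools; wrap those with `wrap_method` and register them to benchmark them.
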