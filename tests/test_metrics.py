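import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from pipebench import (
    ClusteringResult,
    UndefinedMetricError,
    adjusted_rand_index,
    apply_methods,
    begin_benchmark,
    cluster_count_deviation,
    collect_results,
    make_method_list,
    metrics_as_method_list,
    silhouette_width,
)


def ari_pair_counting(a, b):
    """Independent oracle: count concordant/discordant pairs directly."""
    n = len(a)
    n11 = n10 = n01 = n00 = 0
    for i in range(n):
        for j in range(i + 1, n):
            sa, sb = a[i] == a[j], b[i] == b[j]
            if sa and sb:
                n11 += 1
            elif sa:
                n10 += 1
            elif sb:
                n01 += 1
            else:
                n00 += 1
    denom = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    if denom == 0:
        return 1.0  # only possible when the partitions coincide
    return 2.0 * (n11 * n00 - n10 * n01) / denom


labels_strategy = st.lists(st.integers(0, 4), min_size=2, max_size=30)


class TestAdjustedRandIndex:
    def test_identical_partitions(self):
        assert adjusted_rand_index([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0

    def test_label_permutation(self):
        assert adjusted_rand_index([1, 1, 2, 2], [2, 2, 1, 1]) == 1.0

    def test_crossed_partition_is_minus_half(self):
        assert adjusted_rand_index([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            adjusted_rand_index([1, 2], [1, 2, 3])

    def test_string_labels_accepted(self):
        assert adjusted_rand_index(list("aabb"), [0, 0, 1, 1]) == 1.0

    @pytest.mark.parametrize("a,b,expected", [
        ([1, 2, 3], [4, 5, 6], 1.0),   # both all-singletons: same partition
        ([1, 1, 1], [2, 2, 2], 1.0),   # both single-cluster: same partition
    ])
    def test_degenerate_denominator_convention(self, a, b, expected):
        assert adjusted_rand_index(a, b) == expected

    def test_matches_oracle_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = rng.integers(2, 31)
            a = rng.integers(0, rng.integers(1, 6), size=n).tolist()
            b = rng.integers(0, rng.integers(1, 6), size=n).tolist()
            assert adjusted_rand_index(a, b) == pytest.approx(
                ari_pair_counting(a, b), abs=1e-12
            )

    @given(labels_strategy, labels_strategy)
    @settings(max_examples=60, deadline=None)
    def test_symmetry(self, a, b):
        m = min(len(a), len(b))
        a, b = a[:m], b[:m]
        assert adjusted_rand_index(a, b) == pytest.approx(
            adjusted_rand_index(b, a), abs=1e-12
        )

    @given(labels_strategy, st.permutations(list(range(5))))
    @settings(max_examples=60, deadline=None)
    def test_relabeling_invariance(self, a, perm):
        b = [x % 3 for x in range(len(a))]
        relabeled = [perm[x] for x in a]
        assert adjusted_rand_index(a, b) == pytest.approx(
            adjusted_rand_index(relabeled, b), abs=1e-12
        )

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = rng.integers(0, 4, size=40).tolist()
            b = rng.integers(0, 4, size=40).tolist()
            assert adjusted_rand_index(a, b) == pytest.approx(
                adjusted_rand_score(a, b), abs=1e-12
            )

    def test_independent_partitions_concentrate_near_zero(self):
        rng = np.random.default_rng(2)
        scores = [
            adjusted_rand_index(rng.integers(0, 4, 200), rng.integers(0, 4, 200))
            for _ in range(100)
        ]
        assert np.mean(np.abs(scores)) < 0.02


class TestSilhouetteWidth:
    def test_perfectly_separated_coincident_clusters(self):
        emb = np.array([[0.0], [0.0], [10.0], [10.0]])
        assert silhouette_width(emb, [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_single_cluster_undefined(self):
        with pytest.raises(UndefinedMetricError):
            silhouette_width(np.arange(4.0)[:, None], [0, 0, 0, 0])

    def test_worked_example_two_line_clusters(self):
        # points 0,1 | 10,11: s = (10.5-1)/10.5 and (9.5-1)/9.5, mean ~0.8997
        emb = np.array([[0.0], [1.0], [10.0], [11.0]])
        assert silhouette_width(emb, [0, 0, 1, 1]) == pytest.approx(0.9, abs=5e-3)

    def test_all_singletons_score_zero(self):
        emb = np.array([[0.0], [5.0], [9.0]])
        assert silhouette_width(emb, [0, 1, 2]) == 0.0

    def test_bounded_and_monotone_in_separation(self):
        rng = np.random.default_rng(3)
        jitter = rng.normal(0, 0.5, size=(40, 2))
        labels = [0] * 20 + [1] * 20
        prev = -1.0
        for sep in [1.0, 3.0, 9.0, 27.0]:
            emb = jitter.copy()
            emb[20:, 0] += sep
            s = silhouette_width(emb, labels)
            assert -1.0 <= s <= 1.0
            assert s > prev
            prev = s


class TestClusterCountDeviation:
    @pytest.mark.parametrize("assigned,truth,expected", [
        ([1, 2, 3], [1, 2, 3], 0),
        ([1, 2, 3, 4, 5], [1, 2, 3, 1, 2], 2),
        ([1, 1, 1], [1, 2, 3], -2),
    ])
    def test_signed_difference(self, assigned, truth, expected):
        assert cluster_count_deviation(assigned, truth) == expected


class TestMetricsAsMethodList:
    def _result(self):
        return ClusteringResult(
            cell_ids=("c1", "c2", "c3", "c4"),
            assigned=(0, 0, 1, 1),
            truth=("A", "A", "B", "B"),
            embedding=np.array([[0.0], [1.0], [10.0], [11.0]]),
        )

    def _table(self):
        from pipebench.core import BenchmarkRow, BenchmarkTable, StepOutcome

        row = BenchmarkRow(steps=("d", "clu"),
                           result=StepOutcome.success(self._result()))
        return BenchmarkTable(step_names=("data", "cluster"), rows=(row,))

    def test_all_three_metrics_chain(self):
        t = apply_methods(self._table(), metrics_as_method_list(
            ["ari", "silhouette", "n_cluster_dev"]))
        assert t.n_rows == 3
        df = collect_results(t, scalar_only=True)
        by = dict(zip(df["metric"], df["value"]))
        assert by["ari"] == 1.0
        assert by["silhouette"] == pytest.approx(0.9, abs=5e-3)
        assert by["n_cluster_dev"] == 0

    def test_metric_on_failed_row_propagates(self):
        def fail(x):
            raise RuntimeError("upstream crash")

        t = apply_methods(self._table(), make_method_list("mid", {"f": fail}))
        t = apply_methods(t, metrics_as_method_list(["ari"]))
        out = t.outcome(0)
        assert out.is_failure and out.error.upstream

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            metrics_as_method_list(["ari", "nmi"])

    def test_silhouette_without_embedding_is_failure(self):
        res = ClusteringResult(cell_ids=("a", "b"), assigned=(0, 1),
                               truth=("x", "y"))
        from pipebench.core import BenchmarkRow, BenchmarkTable, StepOutcome

        t = BenchmarkTable(
            step_names=("data", "cluster"),
            rows=(BenchmarkRow(("d", "c"), StepOutcome.success(res)),),
        )
        t = apply_methods(t, metrics_as_method_list(["silhouette"]))
        out = t.outcome(0)
        assert out.is_failure and "embedding" in out.error.message
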