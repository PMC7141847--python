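import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pipebench import (
    SCDataset,
    ValidationError,
    filter_zero_genes,
    read_dataset,
    sample_cells,
    sample_genes,
    write_dataset,
)


class TestSCDatasetValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError, match="negative"):
            SCDataset(np.array([[1, -1]]), ("g1",), ("c1", "c2"))

    def test_fractional_counts_rejected(self):
        with pytest.raises(ValidationError, match="integer"):
            SCDataset(np.array([[1.5, 2.0]]), ("g1",), ("c1", "c2"))

    @pytest.mark.parametrize("genes,cells,labels,axis", [
        (("g1",), ("c1", "c2", "c3"), None, "cell"),
        (("g1", "g2", "g3"), ("c1", "c2"), None, "gene"),
        (("g1",), ("c1", "c2"), ("A",), "cell"),
    ])
    def test_dimension_mismatch_names_axis(self, genes, cells, labels, axis):
        with pytest.raises(ValidationError, match=axis):
            SCDataset(np.ones((1, 2)), genes, cells, labels)

    @pytest.mark.parametrize("genes,cells", [
        (("g1", "g1"), ("c1", "c2")),
        (("g1", "g2"), ("c1", "c1")),
    ])
    def test_duplicate_ids_rejected(self, genes, cells):
        with pytest.raises(ValidationError, match="duplicate"):
            SCDataset(np.ones((2, 2)), genes, cells)


class TestIO:
    def test_read_csv(self, tmp_path):
        p = tmp_path / "counts.csv"
        p.write_text("gene,c1,c2\ng1,0,1\ng2,2,3\ng3,4,5\n")
        d = read_dataset(p, format="csv")
        assert d.n_genes == 3 and d.n_cells == 2
        assert d.gene_ids == ("g1", "g2", "g3")
        assert d.cell_ids == ("c1", "c2")
        np.testing.assert_array_equal(d.counts, [[0, 1], [2, 3], [4, 5]])

    def test_read_mtx_all_zeros(self, tmp_path):
        (tmp_path / "matrix.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n5 4 0\n"
        )
        (tmp_path / "genes.tsv").write_text("\n".join(f"g{i}" for i in range(5)) + "\n")
        (tmp_path / "barcodes.tsv").write_text("\n".join(f"c{i}" for i in range(4)) + "\n")
        d = read_dataset(tmp_path, format="mtx")
        assert (d.n_genes, d.n_cells) == (5, 4)
        assert d.counts.sum() == 0

    def test_mtx_roundtrip_with_labels(self, tiny_dataset, tmp_path):
        write_dataset(tiny_dataset, tmp_path / "ds", format="mtx")
        d = read_dataset(tmp_path / "ds", format="mtx",
                         labels_path=tmp_path / "ds" / "labels.csv")
        np.testing.assert_array_equal(d.counts, tiny_dataset.counts)
        assert d.gene_ids == tiny_dataset.gene_ids
        assert d.labels == tiny_dataset.labels

    def test_csv_roundtrip(self, tiny_dataset, tmp_path):
        write_dataset(tiny_dataset, tmp_path / "ds", format="csv")
        d = read_dataset(tmp_path / "ds" / "counts.csv", format="csv")
        np.testing.assert_array_equal(d.counts, tiny_dataset.counts)

    def test_unknown_label_cell_id_rejected(self, tmp_path):
        p = tmp_path / "counts.csv"
        p.write_text("gene,c1,c2\ng1,0,1\n")
        lab = tmp_path / "labels.csv"
        lab.write_text("cell_id,label\nc1,A\nc2,B\nmystery,C\n")
        with pytest.raises(ValidationError, match="unknown cell ids"):
            read_dataset(p, format="csv", labels_path=lab)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_dataset(tmp_path / "nope.csv", format="csv")


class TestSampling:
    def test_sample_all_genes_is_identity(self, tiny_dataset):
        out = sample_genes(tiny_dataset, tiny_dataset.n_genes, seed=0)
        assert out.gene_ids == tiny_dataset.gene_ids
        np.testing.assert_array_equal(out.counts, tiny_dataset.counts)

    def test_sample_genes_deterministic(self, sim_dataset):
        a = sample_genes(sim_dataset, 5, seed=1)
        b = sample_genes(sim_dataset, 5, seed=1)
        assert a.gene_ids == b.gene_ids
        np.testing.assert_array_equal(a.counts, b.counts)

    @pytest.mark.parametrize("n", [0, -1, 1000])
    def test_sample_genes_bad_n(self, tiny_dataset, n):
        with pytest.raises(ValueError):
            sample_genes(tiny_dataset, n, seed=0)

    def test_sample_cells_keeps_label_pairing(self, sim_dataset):
        out = sample_cells(sim_dataset, 20, seed=5)
        assert out.n_cells == 20 and len(out.labels) == 20
        orig = dict(zip(sim_dataset.cell_ids, sim_dataset.labels))
        for cid, lab in zip(out.cell_ids, out.labels):
            assert orig[cid] == lab

    def test_sample_cells_preserves_columns(self, tiny_dataset):
        out = sample_cells(tiny_dataset, 2, seed=0)
        for j, cid in enumerate(out.cell_ids):
            k = tiny_dataset.cell_ids.index(cid)
            np.testing.assert_array_equal(out.counts[:, j],
                                          tiny_dataset.counts[:, k])

    def test_sample_cells_too_many(self, tiny_dataset):
        with pytest.raises(ValueError):
            sample_cells(tiny_dataset, 4, seed=0)


class TestFilterZeroGenes:
    def test_removes_only_zero_rows(self):
        d = SCDataset(np.array([[0, 0], [1, 2]]), ("g1", "g2"), ("c1", "c2"))
        out = filter_zero_genes(d)
        assert out.gene_ids == ("g2",)
        np.testing.assert_array_equal(out.counts, [[1, 2]])

    def test_no_zero_rows_is_identity(self, sim_dataset):
        filtered = filter_zero_genes(sim_dataset)
        refiltered = filter_zero_genes(filtered)
        assert filtered.gene_ids == refiltered.gene_ids

    def test_all_zero_matrix_gives_empty_gene_axis(self):
        d = SCDataset(np.zeros((4, 3)), tuple("abcd"), ("c1", "c2", "c3"))
        out = filter_zero_genes(d)
        assert out.n_genes == 0 and out.n_cells == 3

    @given(arrays(np.int64, shape=st.tuples(st.integers(1, 8), st.integers(1, 6)),
                  elements=st.integers(0, 5)))
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, counts):
        d = SCDataset(counts,
                      tuple(f"g{i}" for i in range(counts.shape[0])),
                      tuple(f"c{j}" for j in range(counts.shape[1])))
        once = filter_zero_genes(d)
        twice = filter_zero_genes(once)
        assert once.gene_ids == twice.gene_ids
        np.testing.assert_array_equal(once.counts, twice.counts)
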