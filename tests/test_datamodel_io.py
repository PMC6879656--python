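import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mrmrsig.datamodel_io import (
    NEGATIVE,
    POSITIVE,
    DatasetPair,
    ExpressionMatrix,
    intersect_genes,
    quantile_normalize,
    read_expression_matrix,
    read_labels,
    write_expression_matrix,
    write_labels,
)

from conftest import write_tsv


def _em(gene_ids, values, sample_ids=None, labels=None):
    values = np.asarray(values, dtype=float)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(gene_ids, sample_ids, values, labels)


class TestReadExpressionMatrix:
    def test_well_formed(self, tmp_path):
        p = write_tsv(tmp_path / "m.tsv", "gene\ts1\ts2\ngA\t1.0\t2.0\ngB\t3\t4\ngC\t5\t6\n")
        m = read_expression_matrix(p)
        assert m.values.shape == (3, 2)
        assert m.gene_ids == ["gA", "gB", "gC"]
        assert m.sample_ids == ["s1", "s2"]

    def test_duplicate_gene_id_errors(self, tmp_path):
        p = write_tsv(tmp_path / "m.tsv", "gene\ts1\ngA\t1\ngA\t2\n")
        with pytest.raises(ValueError, match="gA"):
            read_expression_matrix(p)

    def test_duplicate_sample_id_errors(self, tmp_path):
        p = write_tsv(tmp_path / "m.tsv", "gene\ts1\ts1\ngA\t1\t2\n")
        with pytest.raises(ValueError, match="s1"):
            read_expression_matrix(p)

    def test_missing_cell_drops_gene(self, tmp_path):
        # 4 genes x 3 samples, one missing cell in gB -> 3 surviving rows
        p = write_tsv(
            tmp_path / "m.tsv",
            "gene\ts1\ts2\ts3\n"
            "gA\t1\t2\t3\n"
            "gB\t4\t\t6\n"
            "gC\t7\t8\t9\n"
            "gD\t10\t11\t12\n",
        )
        m = read_expression_matrix(p)
        assert m.values.shape == (3, 3)
        assert m.gene_ids == ["gA", "gC", "gD"]

    def test_non_numeric_cell_drops_gene(self, tmp_path):
        p = write_tsv(tmp_path / "m.tsv", "gene\ts1\ts2\ngA\t1\tNA\ngB\t3\t4\n")
        m = read_expression_matrix(p)
        assert m.gene_ids == ["gB"]

    def test_labels_loaded_and_mapped(self, tmp_path):
        mp = write_tsv(tmp_path / "m.tsv", "gene\ts1\ts2\ngA\t1\t2\n")
        lp = write_tsv(tmp_path / "l.tsv", "s1\tCOPD\ns2\tILD\n")
        m = read_expression_matrix(mp, label_path=lp)
        assert m.labels == {"s1": POSITIVE, "s2": NEGATIVE}
        assert m.class_counts() == (1, 1)

    def test_label_for_unknown_sample_errors(self, tmp_path):
        mp = write_tsv(tmp_path / "m.tsv", "gene\ts1\ngA\t1\n")
        lp = write_tsv(tmp_path / "l.tsv", "s1\tCOPD\nsX\tILD\n")
        with pytest.raises(ValueError, match="sX"):
            read_expression_matrix(mp, label_path=lp)

    def test_roundtrip(self, tmp_path, separable_matrix):
        mp = tmp_path / "m.tsv"
        lp = tmp_path / "l.tsv"
        write_expression_matrix(separable_matrix, mp)
        write_labels(separable_matrix, lp)
        back = read_expression_matrix(mp, label_path=lp)
        assert back.gene_ids == separable_matrix.gene_ids
        assert back.labels == separable_matrix.labels
        np.testing.assert_allclose(back.values, separable_matrix.values, rtol=1e-12)


class TestExpressionMatrixInvariants:
    def test_duplicate_gene_rejected(self):
        with pytest.raises(ValueError, match="duplicate gene"):
            _em(["gA", "gA"], [[1, 2], [3, 4]])

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            _em(["gA"], [[1, np.nan]])

    def test_partial_labels_rejected(self):
        with pytest.raises(ValueError, match="without a label"):
            _em(["gA"], [[1, 2]], labels={"s0": POSITIVE})

    def test_unknown_label_value_rejected(self):
        with pytest.raises(ValueError, match="invalid label"):
            _em(["gA"], [[1, 2]], labels={"s0": "YES", "s1": "NO"})


class TestIntersectGenes:
    def test_basic_intersection(self):
        a = _em(["A", "B", "C"], np.arange(6.0).reshape(3, 2), ["a1", "a2"])
        b = _em(["B", "C", "D"], np.arange(6.0).reshape(3, 2) + 10, ["b1", "b2"])
        pair = intersect_genes(a, b)
        assert pair.train.gene_ids == ["B", "C"]
        assert pair.test.gene_ids == ["B", "C"]
        np.testing.assert_array_equal(pair.train.values, [[2, 3], [4, 5]])
        np.testing.assert_array_equal(pair.test.values, [[10, 11], [12, 13]])

    def test_identical_gene_sets(self):
        a = _em(["B", "A"], [[1, 2], [3, 4]], ["a1", "a2"])
        b = _em(["A", "B"], [[3, 4], [1, 2]], ["b1", "b2"])
        pair = intersect_genes(a, b)
        assert pair.train.gene_ids == ["A", "B"]
        np.testing.assert_array_equal(pair.train.values, pair.test.values)

    def test_six_of_ten_shared(self):
        shared = [f"S{i}" for i in range(6)]
        a = _em(shared + ["X1", "X2", "X3", "X4"], np.random.default_rng(0).normal(size=(10, 3)),
                ["a1", "a2", "a3"])
        b = _em(shared + ["Y1", "Y2", "Y3", "Y4"], np.random.default_rng(1).normal(size=(10, 3)),
                ["b1", "b2", "b3"])
        pair = intersect_genes(a, b)
        assert pair.train.values.shape == (6, 3)
        assert pair.test.values.shape == (6, 3)

    def test_empty_intersection_errors(self):
        a = _em(["A"], [[1, 2]], ["a1", "a2"])
        b = _em(["B"], [[1, 2]], ["b1", "b2"])
        with pytest.raises(ValueError, match="empty"):
            intersect_genes(a, b)

    def test_symmetric_gene_set(self):
        rng = np.random.default_rng(5)
        a = _em(["C", "A", "B"], rng.normal(size=(3, 2)), ["a1", "a2"])
        b = _em(["B", "D", "C"], rng.normal(size=(3, 2)), ["b1", "b2"])
        assert intersect_genes(a, b).train.gene_ids == intersect_genes(b, a).train.gene_ids

    def test_shared_sample_ids_rejected(self):
        a = _em(["A"], [[1, 2]], ["s1", "s2"])
        b = _em(["A"], [[1, 2]], ["s2", "s3"])
        with pytest.raises(ValueError, match="share sample"):
            intersect_genes(a, b)


class TestQuantileNormalize:
    def test_single_sample_unchanged(self):
        m = _em(["g1", "g2"], [[3.0], [1.0]], ["s1"])
        out = quantile_normalize(m)
        np.testing.assert_array_equal(out.values, m.values)

    def test_single_gene_unchanged(self):
        m = _em(["g1"], [[3.0, 1.0]], ["s1", "s2"])
        out = quantile_normalize(m)
        np.testing.assert_array_equal(out.values, m.values)

    def test_identical_sorted_vectors_fixed_point(self):
        m = _em(["g1", "g2", "g3"], [[1.0, 3.0], [2.0, 1.0], [3.0, 2.0]], ["s1", "s2"])
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, m.values, atol=1e-12)

    def test_hand_computed_3x2(self):
        # columns [5,2,3] and [4,1,4]; sorted: [2,3,5] and [1,4,4]
        # rank means: [1.5, 3.5, 4.5]; ties in column 2 average to 4.0
        m = _em(["g1", "g2", "g3"], [[5.0, 4.0], [2.0, 1.0], [3.0, 4.0]], ["s1", "s2"])
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values[:, 0], [4.5, 1.5, 3.5])
        np.testing.assert_allclose(out.values[:, 1], [4.0, 1.5, 4.0])
        assert out.gene_ids == m.gene_ids and out.sample_ids == m.sample_ids

    def test_labels_preserved(self, small_matrix):
        out = quantile_normalize(small_matrix)
        assert out.labels == small_matrix.labels

    def test_input_not_mutated(self, small_matrix):
        before = small_matrix.values.copy()
        quantile_normalize(small_matrix)
        np.testing.assert_array_equal(small_matrix.values, before)

    @given(
        arrays(
            np.float64,
            st.tuples(st.integers(2, 12), st.integers(2, 6)),
            elements=st.floats(-100, 100, allow_nan=False, width=32),
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_property_columns_share_sorted_vector(self, values):
        # the ties=average dialect intentionally breaks exact column equality
        # when a column has ties, so de-tie with a deterministic jitter
        values = values + np.arange(values.size).reshape(values.shape) * 1e-6
        for j in range(values.shape[1]):
            assume(len(np.unique(values[:, j])) == values.shape[0])
        m = _em([f"g{i}" for i in range(values.shape[0])], values)
        out = quantile_normalize(m)
        ref = np.sort(out.values[:, 0])
        for j in range(out.values.shape[1]):
            np.testing.assert_allclose(np.sort(out.values[:, j]), ref, atol=1e-9)

    def test_idempotent_on_tie_free_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            values = rng.normal(size=(rng.integers(2, 20), rng.integers(2, 8)))
            m = _em([f"g{i}" for i in range(values.shape[0])], values)
            once = quantile_normalize(m)
            twice = quantile_normalize(once)
            np.testing.assert_allclose(twice.values, once.values, atol=1e-9)


class TestDatasetPair:
    def test_gene_mismatch_rejected(self):
        a = _em(["A", "B"], [[1, 2], [3, 4]], ["a1", "a2"])
        b = _em(["A", "C"], [[1, 2], [3, 4]], ["b1", "b2"])
        with pytest.raises(ValueError, match="gene_ids differ"):
            DatasetPair(train=a, test=b)
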