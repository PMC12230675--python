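import numpy as np
import pytest

from conftest import indicator_for, processed_from_matrix
from coregsearch.preprocess import (
    RawDataset,
    center_rows,
    log_cpm,
    maybe_log2,
    preprocess_dataset,
    quantile_normalize,
    reduce_samples,
    select_top_expressed,
)
from coregsearch.scoring import pct_var


class TestLogCpm:
    def test_hand_computed_column(self):
        out = log_cpm(np.array([[90.0], [10.0]]))
        expected = [np.log2(9e5 + 1), np.log2(1e5 + 1)]
        np.testing.assert_allclose(out[:, 0], expected, rtol=1e-12)

    def test_zero_count_maps_to_zero(self):
        out = log_cpm(np.array([[0.0, 5.0], [10.0, 5.0]]))
        assert out[0, 0] == 0.0

    def test_equal_counts_give_equal_values(self):
        out = log_cpm(np.array([[5.0], [5.0]]))
        assert out[0, 0] == out[1, 0]

    def test_zero_library_size_errors_with_sample(self):
        with pytest.raises(ValueError, match=r"\[1\]"):
            log_cpm(np.array([[1.0, 0.0], [2.0, 0.0]]))

    def test_monotone_within_column(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 1000, size=(50, 3)).astype(float)
        out = log_cpm(counts)
        for j in range(3):
            order = np.argsort(counts[:, j], kind="stable")
            assert np.all(np.diff(out[order, j]) >= 0)


class TestMaybeLog2:
    def test_linear_scale_transformed(self):
        values = np.array([[20000.0, 3.0]])
        np.testing.assert_allclose(maybe_log2(values), np.log2(values + 1))

    def test_log_scale_unchanged(self):
        values = np.array([[14.2, 3.0]])
        np.testing.assert_array_equal(maybe_log2(values), values)

    def test_zero_matrix_unchanged(self):
        values = np.zeros((3, 2))
        np.testing.assert_array_equal(maybe_log2(values), values)


class TestQuantileNormalize:
    def test_two_column_hand_example(self):
        out = quantile_normalize(np.array([[1.0, 2.0], [3.0, 4.0]]))
        np.testing.assert_allclose(out, [[1.5, 1.5], [3.5, 3.5]])

    def test_identical_columns_unchanged(self):
        col = np.array([3.0, 1.0, 2.0])
        values = np.column_stack([col, col, col])
        np.testing.assert_allclose(quantile_normalize(values), values)

    def test_single_column_unchanged(self):
        values = np.array([[3.0], [1.0], [2.0]])
        np.testing.assert_allclose(quantile_normalize(values), values)

    def test_columns_share_sorted_vector_and_preserve_ranks(self):
        rng = np.random.default_rng(1)
        values = rng.standard_normal((40, 5)) * [1, 2, 5, 0.5, 3]
        out = quantile_normalize(values)
        reference = np.sort(values, axis=0).mean(axis=1)
        for j in range(5):
            np.testing.assert_allclose(np.sort(out[:, j]), reference, rtol=1e-12)
            assert np.array_equal(np.argsort(out[:, j]), np.argsort(values[:, j]))

    def test_ties_get_mean_of_tied_reference_positions(self):
        values = np.array([[1.0, 1.0], [1.0, 2.0], [5.0, 3.0]])
        out = quantile_normalize(values)
        reference = np.sort(values, axis=0).mean(axis=1)
        # first column has a tie occupying reference slots 0 and 1
        expected_tied = reference[:2].mean()
        assert out[0, 0] == expected_tied == out[1, 0]


class TestSelectTopExpressed:
    def test_fewer_rows_than_cap_keeps_all(self):
        values = np.arange(10.0).reshape(5, 2)
        sub, kept = select_top_expressed(values, list("abcde"), n_keep=10000)
        assert kept == list("abcde")
        np.testing.assert_array_equal(sub, values)

    def test_ranking_by_row_mean_keeps_original_order(self):
        values = np.array([[1.0], [3.0], [2.0]])
        sub, kept = select_top_expressed(values, ["g1", "g2", "g3"], n_keep=2)
        assert kept == ["g2", "g3"]
        np.testing.assert_array_equal(sub, [[3.0], [2.0]])

    def test_tie_at_cut_keeps_earlier_row(self):
        values = np.array([[2.0], [1.0], [1.0]])
        _, kept = select_top_expressed(values, ["a", "b", "c"], n_keep=2)
        assert kept == ["a", "b"]


class TestCenterRows:
    def test_arithmetic(self):
        np.testing.assert_allclose(center_rows(np.array([[1.0, 2.0, 3.0]])), [[-1, 0, 1]])

    def test_idempotent(self):
        centered = center_rows(np.random.default_rng(2).standard_normal((5, 4)))
        np.testing.assert_allclose(center_rows(centered), centered, atol=1e-12)

    def test_single_sample_gives_zeros(self):
        np.testing.assert_array_equal(center_rows(np.array([[7.0], [3.0]])), [[0.0], [0.0]])


class TestReduceSamples:
    def test_no_reduction_branch(self):
        centered = center_rows(np.random.default_rng(3).standard_normal((10, 3)))
        scores, loadings = reduce_samples(centered, r=20)
        np.testing.assert_array_equal(scores, centered)
        np.testing.assert_array_equal(loadings, np.eye(3))

    def test_rank_one_matrix_exact(self):
        rng = np.random.default_rng(4)
        u = rng.standard_normal(50)
        v = rng.standard_normal(30)
        centered = center_rows(np.outer(u, v))
        scores, loadings = reduce_samples(centered, r=20)
        assert (np.abs(scores) > 1e-9).any(axis=0).sum() == 1
        full = processed_from_matrix(centered, r=10**9)
        red = processed_from_matrix(centered, r=20)
        for seed in range(10):
            idx = np.random.default_rng(seed).choice(50, 5, replace=False)
            p = indicator_for(idx, 50)
            assert pct_var(red, p, 5) == pytest.approx(pct_var(full, p, 5), rel=1e-10)

    def test_low_rank_matrix_preserves_score_exactly(self):
        rng = np.random.default_rng(5)
        centered = center_rows(rng.standard_normal((100, 20)) @ rng.standard_normal((20, 40)))
        full = processed_from_matrix(centered, r=10**9)
        red = processed_from_matrix(centered, r=20)
        assert red.scores.shape[1] <= 20
        for seed in range(20):
            idx = np.random.default_rng(100 + seed).choice(100, 10, replace=False)
            p = indicator_for(idx, 100)
            assert pct_var(red, p, 10) == pytest.approx(pct_var(full, p, 10), rel=1e-8)

    def test_truncation_only_removes_energy(self):
        rng = np.random.default_rng(6)
        centered = center_rows(rng.standard_normal((60, 40)))
        scores, _ = reduce_samples(centered, r=20)
        assert (scores**2).sum() <= (centered**2).sum() + 1e-9

    def test_reconstruction_rows_stay_centered_and_loadings_orthonormal(self):
        rng = np.random.default_rng(7)
        centered = center_rows(rng.standard_normal((60, 40)))
        scores, loadings = reduce_samples(centered, r=20)
        np.testing.assert_allclose(loadings.T @ loadings, np.eye(loadings.shape[1]), atol=1e-8)
        recon = scores @ loadings.T
        assert np.abs(recon.mean(axis=1)).max() <= 1e-8


class TestPreprocessDataset:
    @staticmethod
    def _raw(n, m, kind, seed=0, scale=1.0):
        rng = np.random.default_rng(seed)
        return RawDataset(
            id="raw",
            genes=[f"g{i}" for i in range(n)],
            samples=[f"s{j}" for j in range(m)],
            values=np.abs(rng.standard_normal((n, m))) * scale,
            kind=kind,
            sample_metadata=[f"sample {j} treated" for j in range(m)],
        )

    def test_rnaseq_dimension_bookkeeping(self):
        ds = preprocess_dataset(self._raw(12000, 5, "rnaseq"), n_keep=10000)
        assert ds.n_genes == 10000
        assert ds.n_reduced == 5
        assert ds.provenance["normalization"] == "log_cpm"

    def test_microarray_log_branch_skipped_for_log_scale_data(self):
        ds = preprocess_dataset(self._raw(50, 4, "microarray", scale=10.0))
        assert ds.provenance["log2_applied"] is False

    def test_microarray_log_branch_taken_for_linear_scale_data(self):
        ds = preprocess_dataset(self._raw(50, 4, "microarray", scale=5000.0))
        assert ds.provenance["log2_applied"] is True

    def test_many_samples_reduced_to_twenty(self):
        ds = preprocess_dataset(self._raw(100, 30, "microarray"))
        assert ds.n_reduced == 20
        assert ds.n_samples == 30

    def test_invariants_total_ss_and_orthonormal_loadings(self):
        ds = preprocess_dataset(self._raw(100, 30, "microarray"))
        assert ds.total_ss == pytest.approx(float((ds.scores**2).sum()), rel=1e-12)
        np.testing.assert_allclose(
            ds.loadings.T @ ds.loadings, np.eye(ds.n_reduced), atol=1e-8
        )
        recon = ds.scores @ ds.loadings.T
        assert np.abs(recon.mean(axis=1)).max() <= 1e-8

    def test_sample_words_tokenized(self):
        ds = preprocess_dataset(self._raw(30, 4, "microarray"))
        assert "treated" in ds.sample_words[0]

    def test_duplicate_genes_rejected(self):
        raw = self._raw(5, 3, "microarray")
        raw.genes[1] = raw.genes[0]
        with pytest.raises(ValueError, match="duplicate gene"):
            preprocess_dataset(raw)
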