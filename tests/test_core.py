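"""Unit and property tests for the four-stage transform."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scpsd import (
    CorrelationMatrix,
    OmicsMatrix,
    correlation_transform,
    dft_power,
    filter_zero_features,
    gene_correlation,
    minmax_scale_columns,
    psd_transform,
    spectral_entropy,
)
from scpsd.core import correlation_transform_blocked


def naive_dft(x: np.ndarray) -> np.ndarray:
    """Direct O(n^2) summation DFT, the independent oracle for the FFT stage."""
    n = len(x)
    j, k = np.meshgrid(np.arange(n), np.arange(n))
    return (x * np.exp(-2j * np.pi * j * k / n)).sum(axis=1)


def pearson_two_pass(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook two-pass covariance / sigma Pearson correlation."""
    mx, my = x.mean(), y.mean()
    cov = ((x - mx) * (y - my)).mean()
    sx = np.sqrt(((x - mx) ** 2).mean())
    sy = np.sqrt(((y - my) ** 2).mean())
    return cov / (sx * sy)


class TestOmicsMatrix:
    def test_rejects_nan_inf_negative(self):
        with pytest.raises(ValueError, match="NaN or Inf"):
            OmicsMatrix(np.array([[1.0, np.nan]]), ["g"], ["a", "b"])
        with pytest.raises(ValueError, match="non-negative"):
            OmicsMatrix(np.array([[1.0, -1.0]]), ["g"], ["a", "b"])

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValueError, match="duplicate"):
            OmicsMatrix(np.ones((2, 2)), ["g", "g"], ["a", "b"])

    def test_rejects_misaligned_labels(self):
        with pytest.raises(ValueError, match="labels"):
            OmicsMatrix(np.ones((2, 2)), ["g", "h"], ["a", "b"], labels=["x"])


class TestFilterZeroFeatures:
    def test_removes_all_zero_rows(self, zero_row_matrix):
        out = filter_zero_features(zero_row_matrix)
        assert out.feature_ids == ["g0", "g2"]
        np.testing.assert_array_equal(out.values, [[1, 2], [3, 4]])

    def test_identity_when_nothing_to_remove(self, toy_matrix):
        out = filter_zero_features(toy_matrix)
        np.testing.assert_array_equal(out.values, toy_matrix.values)
        assert out.feature_ids == toy_matrix.feature_ids

    def test_all_zero_matrix_errors(self):
        M = OmicsMatrix(np.zeros((3, 2)), list("abc"), ["x", "y"])
        with pytest.raises(ValueError, match="empty matrix"):
            filter_zero_features(M)


class TestGeneCorrelation:
    def test_duplicated_row_correlates_to_one(self):
        row = np.array([1.0, 3.0, 2.0, 5.0])
        M = OmicsMatrix(np.vstack([row, row]), ["a", "b"], list("wxyz"))
        R = gene_correlation(M)
        assert R.rho[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_reflected_row_correlates_to_minus_one(self):
        row = np.array([1.0, 3.0, 2.0, 5.0])
        M = OmicsMatrix(np.vstack([row, 10.0 - row]), ["a", "b"], list("wxyz"))
        R = gene_correlation(M)
        assert R.rho[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_two_pass_oracle(self, toy_matrix):
        R = gene_correlation(toy_matrix)
        for i in range(5):
            for j in range(5):
                expected = pearson_two_pass(toy_matrix.values[i], toy_matrix.values[j])
                assert abs(R.rho[i, j] - expected) < 1e-12

    def test_symmetric_unit_diagonal_bounded(self, toy_matrix):
        R = gene_correlation(toy_matrix)
        np.testing.assert_allclose(R.rho, R.rho.T, atol=1e-10)
        np.testing.assert_allclose(np.diag(R.rho), 1.0)
        assert np.all(np.abs(R.rho) <= 1.0)

    def test_constant_feature_gets_zero_off_diagonal(self):
        values = np.array([[2.0, 2.0, 2.0], [1.0, 4.0, 2.0]])
        R = gene_correlation(OmicsMatrix(values, ["c", "v"], list("xyz")))
        assert R.rho[0, 1] == 0.0 and R.rho[0, 0] == 1.0

    def test_single_cell_errors(self):
        M = OmicsMatrix(np.ones((3, 1)), list("abc"), ["only"])
        with pytest.raises(ValueError, match="2 cells"):
            gene_correlation(M)


class TestCorrelationTransform:
    def test_identity_correlation_is_identity(self, toy_matrix):
        R = CorrelationMatrix(np.eye(5), list(toy_matrix.feature_ids))
        np.testing.assert_array_equal(
            correlation_transform(toy_matrix, R), toy_matrix.values
        )

    def test_hand_multiplied_two_by_two(self):
        M = OmicsMatrix(np.array([[2.0, 0.0], [0.0, 2.0]]), ["a", "b"], ["x", "y"])
        R = CorrelationMatrix(np.array([[1.0, 0.5], [0.5, 1.0]]), ["a", "b"])
        np.testing.assert_array_equal(
            correlation_transform(M, R), [[2.0, 1.0], [1.0, 2.0]]
        )

    def test_mismatched_ids_error(self, toy_matrix):
        R = CorrelationMatrix(np.eye(5), ["q0", "q1", "q2", "q3", "q4"])
        with pytest.raises(ValueError, match="feature ids"):
            correlation_transform(toy_matrix, R)

    @pytest.mark.parametrize("block_size", [1, 3, 7, 64, 1000])
    def test_blocked_equals_dense(self, block_size):
        rng = np.random.default_rng(5)
        M = OmicsMatrix(
            rng.gamma(2.0, 1.0, size=(37, 12)),
            [f"g{i}" for i in range(37)],
            [f"c{j}" for j in range(12)],
        )
        dense = correlation_transform(M, gene_correlation(M))
        blocked = correlation_transform_blocked(M, block_size)
        np.testing.assert_allclose(blocked, dense, atol=1e-10)


class TestDftPower:
    def test_constant_column_concentrates_at_dc(self):
        col = np.full((8, 1), 3.0)
        out = dft_power(col)
        np.testing.assert_allclose(out[0], 3.0, atol=1e-12)
        np.testing.assert_allclose(out[1:], 0.0, atol=1e-12)

    def test_impulse_column_is_flat(self):
        col = np.zeros((16, 1))
        col[0, 0] = 1.0
        np.testing.assert_allclose(dft_power(col), 1.0 / 16, atol=1e-12)

    @pytest.mark.parametrize("n", [3, 16, 64, 257])
    def test_matches_naive_dft(self, n):
        rng = np.random.default_rng(n)
        A1 = rng.normal(size=(n, 4))
        expected = np.column_stack(
            [np.abs(naive_dft(np.abs(A1[:, j]))) / n for j in range(4)]
        )
        np.testing.assert_allclose(dft_power(A1), expected, atol=1e-9)


class TestSpectralEntropy:
    def test_identical_columns_give_zero(self):
        col = np.array([1.0, 3.0, 2.0])
        A2 = np.column_stack([col, col, col])
        np.testing.assert_array_equal(spectral_entropy(A2), 0.0)

    def test_single_column_gives_zero(self):
        np.testing.assert_array_equal(
            spectral_entropy(np.array([[1.0], [2.0]])), 0.0
        )

    def test_matches_scalar_loop_oracle(self):
        A2 = np.array([[1.0, 3.0], [1.0, 1.0]])
        # scalar-loop recomputation of P, I, H, A3
        H = np.empty((2, 2))
        for j in range(2):
            total = A2[:, j].sum()
            for k in range(2):
                p = A2[k, j] / total
                H[k, j] = -p * np.log2(p) if p > 0 else 0.0
        expected = H.mean(axis=1, keepdims=True) - H
        np.testing.assert_allclose(spectral_entropy(A2), expected, atol=1e-12)
        np.testing.assert_allclose(
            A2 / A2.sum(axis=0), [[0.5, 0.75], [0.5, 0.25]], atol=1e-15
        )

    def test_zero_probability_entries_contribute_zero(self):
        A2 = np.array([[1.0, 2.0], [0.0, 1.0]])
        out = spectral_entropy(A2)
        assert np.isfinite(out).all()

    def test_zero_sum_column_names_cell(self):
        A2 = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="degenerate cell spectrum: bad_cell"):
            spectral_entropy(A2, cell_ids=["ok", "bad_cell"])


class TestMinmaxScale:
    def test_affine_map(self):
        out, deg = minmax_scale_columns(np.array([[2.0], [4.0], [6.0]]))
        np.testing.assert_array_equal(out[:, 0], [0.0, 0.5, 1.0])
        assert deg == []

    def test_constant_column_flagged_zero(self):
        out, deg = minmax_scale_columns(np.array([[5.0], [5.0], [5.0]]))
        np.testing.assert_array_equal(out, 0.0)
        assert deg == [0]

    def test_idempotent(self, toy_matrix):
        once, _ = minmax_scale_columns(toy_matrix.values)
        twice, _ = minmax_scale_columns(once)
        np.testing.assert_array_equal(once, twice)


class TestPsdTransform:
    def test_output_in_unit_interval(self, small_clustered):
        res = psd_transform(small_clustered)
        assert res.transformed.min() >= 0.0 and res.transformed.max() <= 1.0

    def test_nondegenerate_columns_attain_bounds(self, small_clustered):
        res = psd_transform(small_clustered)
        ok = [j for j, c in enumerate(res.cell_ids)
              if c not in res.provenance["degenerate_cells"]]
        assert ok, "expected non-degenerate columns"
        np.testing.assert_array_equal(res.transformed[:, ok].min(axis=0), 0.0)
        np.testing.assert_array_equal(res.transformed[:, ok].max(axis=0), 1.0)

    def test_composition_matches_stagewise(self, toy_matrix):
        res = psd_transform(toy_matrix, keep_intermediates=True)
        F = filter_zero_features(toy_matrix)
        A1 = correlation_transform(F, gene_correlation(F))
        A3 = spectral_entropy(dft_power(A1), F.cell_ids)
        scaled, _ = minmax_scale_columns(A3)
        np.testing.assert_array_equal(res.transformed, scaled)  # bit-identical
        np.testing.assert_array_equal(res.intermediates["A1"], A1)

    def test_deterministic_rerun(self, small_clustered):
        a = psd_transform(small_clustered).transformed
        b = psd_transform(small_clustered).transformed
        np.testing.assert_array_equal(a, b)

    def test_blocked_close_to_dense(self, small_clustered):
        dense = psd_transform(small_clustered).transformed
        blocked = psd_transform(small_clustered, block_size=17).transformed
        np.testing.assert_allclose(blocked, dense, atol=1e-8)

    def test_removed_features_recorded(self, zero_row_matrix):
        res = psd_transform(zero_row_matrix)
        assert res.provenance["removed_features"] == ["g1"]
        assert res.feature_ids == ["g0", "g2"]

    def test_step1_permutation_equivariance(self, toy_matrix):
        perm = np.array([3, 0, 4, 1, 2])
        P = toy_matrix.subset_features(perm)
        rho = gene_correlation(toy_matrix).rho
        rho_p = gene_correlation(P).rho
        np.testing.assert_array_equal(rho_p, rho[np.ix_(perm, perm)])
        A1 = correlation_transform(toy_matrix, gene_correlation(toy_matrix))
        A1_p = correlation_transform(P, gene_correlation(P))
        # the matrix product accumulates in permuted order, so equivariance
        # of A1 holds to rounding, not bitwise
        np.testing.assert_allclose(A1_p, A1[perm], rtol=1e-12, atol=1e-12)

    def test_improves_vrc_on_clustered_data(self, clustered):
        from scpsd import vrc

        res = psd_transform(clustered)
        before = vrc(clustered.values.T, clustered.labels)
        after = vrc(res.transformed.T, clustered.labels)
        assert after > before


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    n=st.integers(2, 24),
    m=st.integers(2, 8),
    seed=st.integers(0, 2**20),
)
def test_probability_columns_sum_to_one(n, m, seed):
    """Inside the entropy stage, every cell's spectrum is a probability vector."""
    rng = np.random.default_rng(seed)
    A2 = dft_power(rng.normal(size=(n, m)))
    P = A2 / A2.sum(axis=0)
    np.testing.assert_allclose(P.sum(axis=0), 1.0, atol=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(n=st.integers(3, 20), m=st.integers(2, 6), seed=st.integers(0, 2**20))
def test_transform_output_always_in_unit_interval(n, m, seed):
    rng = np.random.default_rng(seed)
    M = OmicsMatrix(
        rng.gamma(1.0, 2.0, size=(n, m)) + 1e-6,
        [f"g{i}" for i in range(n)],
        [f"c{j}" for j in range(m)],
    )
    out = psd_transform(M).transformed
    assert out.min() >= 0.0 and out.max() <= 1.0
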