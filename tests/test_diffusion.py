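"""Kernel, Markov normalization, and spectral decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mapalign.diffusion import (
    AffinityMatrix,
    DisconnectedGraphWarning,
    DistanceMatrix,
    MarkovOperator,
    diffusion_distance,
    diffusion_map,
    gknn_kernel,
    markov_power_from_basis,
    normalize_to_markov,
    spectral_decompose,
)

from conftest import basis_from_cloud, point_cloud_distances


def two_state_operator(p):
    m = np.array([[1 - p, p], [p, 1 - p]])
    return MarkovOperator(values=m, symmetric_conjugate=m,
                          stationary_weights=np.ones(2))


class TestGknnKernel:
    def test_collinear_hand_values(self):
        # points at 0, 1, 3 with k_nn=1: nn distances 1, 1, 2
        D = DistanceMatrix(np.array([[0, 1, 3], [1, 0, 2], [3, 2, 0]], float))
        K = gknn_kernel(D, 1).values
        assert K[0, 1] == pytest.approx(np.exp(-1), rel=1e-12)
        assert K[1, 2] == pytest.approx(np.exp(-2), rel=1e-12)
        assert K[0, 2] == pytest.approx(np.exp(-4.5), rel=1e-12)
        assert np.all(np.diag(K) == 1.0)

    @pytest.mark.parametrize("c", [1e-3, 1.0, 1e3])
    def test_scale_free(self, rng, c):
        D = point_cloud_distances(rng, 30)
        K1 = gknn_kernel(D, 7).values
        K2 = gknn_kernel(DistanceMatrix(c * D.values), 7).values
        assert np.max(np.abs(K1 - K2)) < 1e-12

    def test_duplicate_points_raise_and_floor(self):
        vals = np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0]], float)
        D = DistanceMatrix(vals, agent_ids=("a", "b", "c"))
        with pytest.raises(ValueError, match="'a'.*'b'"):
            gknn_kernel(D, 1)
        K = gknn_kernel(D, 1, distance_floor=True)
        assert np.all(np.isfinite(K.values))

    def test_k_nn_out_of_range(self, rng):
        D = point_cloud_distances(rng, 5)
        with pytest.raises(ValueError):
            gknn_kernel(D, 5)


class TestNormalizeToMarkov:
    def test_two_by_two_closed_form(self):
        a = 0.5
        M = normalize_to_markov(AffinityMatrix(np.array([[1, a], [a, 1]])))
        expected = np.array([[1 / (1 + a), a / (1 + a)]] * 2)
        expected[1] = expected[1][::-1]
        assert np.allclose(M.values, expected, atol=1e-14)

    def test_constant_affinity_gives_uniform(self):
        n = 6
        A = AffinityMatrix(np.ones((n, n)))
        M = normalize_to_markov(A)
        assert np.allclose(M.values, 1.0 / n, atol=1e-14)

    @given(n=st.integers(5, 40), seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_rows_sum_to_one(self, n, seed):
        rng = np.random.default_rng(seed)
        M = normalize_to_markov(gknn_kernel(point_cloud_distances(rng, n), min(7, n - 1)))
        assert np.max(np.abs(M.values.sum(axis=1) - 1.0)) < 1e-10


class TestSpectralDecompose:
    def test_uniform_operator_spectrum_zero(self):
        n = 8
        M = normalize_to_markov(AffinityMatrix(np.ones((n, n))))
        B = spectral_decompose(M)
        assert np.max(np.abs(B.eigenvalues)) < 1e-12

    def test_two_state_closed_form(self):
        B = spectral_decompose(two_state_operator(0.25))
        assert B.eigenvalues[0] == pytest.approx(0.5, abs=1e-12)
        assert np.allclose(np.abs(B.eigenvectors[:, 0]), 1 / np.sqrt(2), atol=1e-12)
        coords = diffusion_map(B, 1).ravel()
        assert np.allclose(np.sort(coords), [-0.5 / np.sqrt(2), 0.5 / np.sqrt(2)], atol=1e-12)

    @pytest.mark.parametrize("t", [1, 2, 5])
    def test_reconstruction_matches_matrix_power(self, rng, t):
        M = normalize_to_markov(gknn_kernel(point_cloud_distances(rng, 40), 7))
        recon = markov_power_from_basis(M, t)
        direct = np.linalg.matrix_power(M.values, t)
        assert np.max(np.abs(recon - direct)) < 1e-8

    def test_eigenvalue_bound_and_orthonormality(self, rng):
        B = basis_from_cloud(rng, 45)
        assert np.all(np.abs(B.eigenvalues) <= 1 + 1e-10)
        G = B.eigenvectors.T @ B.eigenvectors
        assert np.max(np.abs(G - np.eye(B.size))) < 1e-8

    def test_sign_convention(self, rng):
        B = basis_from_cloud(rng, 30)
        peaks = np.abs(B.eigenvectors).argmax(axis=0)
        assert np.all(B.eigenvectors[peaks, np.arange(B.size)] > 0)

    def test_permutation_equivariance(self, rng):
        D = point_cloud_distances(rng, 25)
        perm = rng.permutation(25)
        Dp = DistanceMatrix(D.values[np.ix_(perm, perm)])
        B = spectral_decompose(normalize_to_markov(gknn_kernel(D, 7)))
        Bp = spectral_decompose(normalize_to_markov(gknn_kernel(Dp, 7)))
        assert np.allclose(B.eigenvalues, Bp.eigenvalues, atol=1e-10)
        for j in range(5):  # leading modes, up to sign
            a, b = B.eigenvectors[perm, j], Bp.eigenvectors[:, j]
            assert min(np.max(np.abs(a - b)), np.max(np.abs(a + b))) < 1e-8

    def test_disconnected_graph_flagged(self):
        block = np.ones((3, 3))
        A = np.zeros((6, 6))
        A[:3, :3] = block
        A[3:, 3:] = block
        with pytest.warns(DisconnectedGraphWarning):
            B = spectral_decompose(normalize_to_markov(AffinityMatrix(A)))
        assert B.disconnected


class TestDiffusionMapAndDistance:
    def test_column_norms_equal_eigenvalues(self, rng):
        B = basis_from_cloud(rng, 30)
        coords = diffusion_map(B, B.size)
        assert np.allclose(np.linalg.norm(coords, axis=0), np.abs(B.eigenvalues), atol=1e-10)

    def test_k_too_large_raises(self, rng):
        B = basis_from_cloud(rng, 10)
        with pytest.raises(ValueError):
            diffusion_map(B, B.size + 1)

    def test_identical_rows_zero_distance(self, rng):
        M = normalize_to_markov(gknn_kernel(point_cloud_distances(rng, 15), 5))
        assert diffusion_distance(M, 3, 4, 4) == 0.0

    def test_uniform_operator_distance_zero(self):
        M = normalize_to_markov(AffinityMatrix(np.ones((5, 5))))
        assert diffusion_distance(M, 1, 0, 3) == pytest.approx(0.0, abs=1e-14)

    def test_two_state_hand_value(self):
        # D_1(1,2)^2 = 2 * 0.5^2 = 0.5
        assert diffusion_distance(two_state_operator(0.25), 1, 0, 1) ** 2 == pytest.approx(
            0.5, rel=1e-12
        )


class TestTypeInvariants:
    def test_distance_matrix_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(np.array([[0, 1], [2, 0.0]]))  # asymmetric
        with pytest.raises(ValueError):
            DistanceMatrix(np.array([[0, -1], [-1, 0.0]]))  # negative
        with pytest.raises(ValueError):
            DistanceMatrix(np.array([[0.0]]))  # n < 2

    def test_affinity_matrix_validation(self):
        with pytest.raises(ValueError):
            AffinityMatrix(np.array([[0.5, 0.2], [0.2, 1.0]]))  # diagonal != 1
        with pytest.raises(ValueError):
            AffinityMatrix(np.array([[1.0, 1.2], [1.2, 1.0]]))  # > 1

    def test_markov_row_sum_validation(self):
        with pytest.raises(ValueError):
            MarkovOperator(values=np.array([[0.5, 0.4], [0.5, 0.5]]),
                           symmetric_conjugate=np.eye(2),
                           stationary_weights=np.ones(2))
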