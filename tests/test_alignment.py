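"""Projections, the beta null, and the map alignment statistic."""

import math

import numpy as np
import pytest
from scipy import stats

from mapalign.alignment import (
    map_alignment_statistic,
    null_model,
    project_norm,
    standardized_projection,
    suggest_k,
)
from mapalign.diffusion import DiffusionBasis

from conftest import basis_from_cloud, orthonormal_basis


def z_max(n, k):
    """Closed-form Z for identical bases with equal retained eigenvalues."""
    return math.sqrt(k) * (1 - k / n) * math.sqrt((n**3 + 2 * n**2) / (2 * (n - k) * k))


def z_min(n, k):
    """Closed-form Z for fully orthogonal bases with equal eigenvalues."""
    return -math.sqrt(k) * (k / n) * math.sqrt((n**3 + 2 * n**2) / (2 * (n - k) * k))


class TestProjectNorm:
    def test_vector_in_span_gives_one(self, rng):
        B = orthonormal_basis(rng, 50, 10)
        assert project_norm(B.eigenvectors[:, 0], B, 5) == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_vector_gives_zero(self, rng):
        B = orthonormal_basis(rng, 50, 10)
        phi = rng.standard_normal(50)
        phi -= B.eigenvectors @ (B.eigenvectors.T @ phi)
        phi /= np.linalg.norm(phi)
        assert project_norm(phi, B, 10) == pytest.approx(0.0, abs=1e-10)

    def test_non_unit_vector_raises(self, rng):
        B = orthonormal_basis(rng, 20, 5)
        with pytest.raises(ValueError, match="unit"):
            project_norm(np.ones(20), B, 3)

    def test_monte_carlo_mean_matches_null(self, rng):
        n, k, draws = 200, 15, 5000
        B = orthonormal_basis(rng, n, k)
        x = rng.standard_normal((draws, n))
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        sq = np.array([project_norm(v, B, k) ** 2 for v in x[:500]])
        se = sq.std(ddof=1) / np.sqrt(sq.size)
        assert abs(sq.mean() - k / n) < 3 * se


class TestStandardizedProjection:
    def test_centering(self):
        assert standardized_projection(0.1, 100, 10) == pytest.approx(0.0, abs=1e-12)

    def test_printed_formula_extremes(self):
        assert standardized_projection(1.0, 100, 10) == pytest.approx(21.4243, abs=5e-5)
        assert standardized_projection(0.0, 100, 10) == pytest.approx(-2.3805, abs=5e-5)

    def test_affine_increasing_in_sq_norm(self):
        vals = [standardized_projection(s, 50, 5) for s in np.linspace(0, 1, 7)]
        diffs = np.diff(vals)
        assert np.all(diffs > 0)
        assert np.allclose(diffs, diffs[0], rtol=1e-10)  # affine

    def test_invalid_k_raises(self):
        with pytest.raises(ValueError):
            standardized_projection(0.5, 10, 10)


class TestNullModel:
    def test_printed_moments(self):
        nm = null_model(100, 10)
        assert nm.mean == pytest.approx(0.1)
        assert nm.variance == pytest.approx(1800 / 1_020_000, rel=1e-12)

    def test_beta_moments_match_printed(self):
        # the configured shape pair must reproduce the printed mean/variance
        for n, k in [(50, 5), (200, 15), (97, 13)]:
            nm = null_model(n, k)
            a, b = nm.shape
            assert a / (a + b) == pytest.approx(nm.mean, rel=1e-12)
            beta_var = a * b / ((a + b) ** 2 * (a + b + 1))
            assert beta_var == pytest.approx(nm.variance, rel=1e-12)

    def test_goodness_of_fit_of_squared_projections(self, rng):
        n, k = 200, 15
        x = rng.standard_normal((5000, n))
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        sq = np.sum(x[:, :k] ** 2, axis=1)
        p = stats.kstest(sq, null_model(n, k).frozen.cdf).pvalue
        assert p > 0.01

    def test_invalid_nk_raises(self):
        with pytest.raises(ValueError):
            null_model(10, 10)
        with pytest.raises(ValueError):
            null_model(10, 0)


class TestMapAlignmentStatistic:
    def test_identical_bases_equal_eigenvalues_closed_form(self, rng):
        n, k = 100, 10
        B = orthonormal_basis(rng, n, 20, eigenvalues=np.full(20, 0.8))
        res = map_alignment_statistic(B, B, k)
        assert res.z == pytest.approx(z_max(n, k), abs=1e-8)
        assert res.z == pytest.approx(67.7495, abs=5e-4)

    def test_orthogonal_bases_closed_form(self, rng):
        n, k = 100, 10
        B1 = orthonormal_basis(rng, n, k, eigenvalues=np.full(k, 0.8))
        # complement of B1's span
        Q = B1.eigenvectors
        comp = np.linalg.qr(
            (np.eye(n) - Q @ Q.T) @ rng.standard_normal((n, k))
        )[0]
        B2 = DiffusionBasis(eigenvalues=np.full(k, 0.8), eigenvectors=comp)
        res = map_alignment_statistic(B1, B2, k)
        assert res.z == pytest.approx(z_min(n, k), abs=1e-8)
        assert res.z == pytest.approx(-7.5278, abs=5e-4)

    def test_null_mean_near_zero(self, rng):
        n, k, reps = 200, 15, 200
        zs = np.empty(reps)
        for i in range(reps):
            B1 = orthonormal_basis(rng, n, k)
            B2 = orthonormal_basis(rng, n, k)
            zs[i] = map_alignment_statistic(B1, B2, k).z
        se = zs.std(ddof=1) / np.sqrt(reps)
        assert abs(zs.mean()) < 3 * se

    def test_summand_null_calibration(self, rng):
        # each standardized projection is ~centered with ~unit variance
        # under independent orthonormal bases
        n, k, draws = 200, 15, 5000
        B2 = orthonormal_basis(rng, n, k)
        x = rng.standard_normal((draws, n))
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        sq = np.sum((x @ B2.eigenvectors) ** 2, axis=1)
        P = (sq - k / n) * math.sqrt((n**3 + 2 * n**2) / (2 * (n - k) * k))
        assert abs(P.mean()) < 0.05
        assert abs(P.var() - 1.0) < 0.1

    def test_asymmetry_both_directions_computable(self, rng):
        B1 = basis_from_cloud(rng, 40)
        B2 = basis_from_cloud(rng, 40)
        f = map_alignment_statistic(B1, B2, 8)
        r = map_alignment_statistic(B2, B1, 8)
        assert np.isfinite(f.z) and np.isfinite(r.z)
        assert f.z != r.z  # generically different

    def test_determinism(self, rng):
        B1 = basis_from_cloud(np.random.default_rng(7), 30)
        B2 = basis_from_cloud(np.random.default_rng(8), 30)
        r1 = map_alignment_statistic(B1, B2, 6)
        r2 = map_alignment_statistic(B1, B2, 6)
        assert r1.z == r2.z
        assert np.array_equal(r1.sq_projections, r2.sq_projections)

    def test_mismatched_agents_raise(self, rng):
        B1 = orthonormal_basis(rng, 20, 5)
        B2 = DiffusionBasis(
            eigenvalues=np.linspace(0.9, 0.5, 5),
            eigenvectors=np.linalg.qr(rng.standard_normal((20, 5)))[0],
            agent_ids=tuple(f"x{i}" for i in range(20)),
        )
        with pytest.raises(ValueError, match="agent"):
            map_alignment_statistic(B1, B2, 5)

    def test_unweightable_degenerate_spectrum(self, rng):
        B1 = orthonormal_basis(rng, 30, 5, eigenvalues=np.zeros(5))
        B2 = orthonormal_basis(rng, 30, 5)
        res = map_alignment_statistic(B1, B2, 5)
        assert res.unweightable
        assert res.z == 0.0

    def test_completeness_at_full_rank(self, rng):
        # squared projections onto the full basis sum to 1 for any unit vector
        n = 30
        B = orthonormal_basis(rng, n, n, eigenvalues=np.linspace(1, 0.1, n))
        phi = rng.standard_normal(n)
        phi /= np.linalg.norm(phi)
        total = sum(
            (B.eigenvectors[:, j] @ phi) ** 2 for j in range(n)
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_z_stabilizes_in_k(self, rng):
        # beyond the shared structure, growing k changes Z only slowly
        n, shared = 150, 5
        Q = np.linalg.qr(rng.standard_normal((n, 40)))[0]
        lam = np.concatenate([np.full(shared, 0.9), np.full(35, 0.2)])
        B1 = DiffusionBasis(eigenvalues=lam, eigenvectors=Q)
        # B2 shares the first modes, rest independent
        Q2 = np.linalg.qr(
            np.hstack([Q[:, :shared], rng.standard_normal((n, 35))])
        )[0]
        B2 = DiffusionBasis(eigenvalues=lam, eigenvectors=Q2)
        z10 = map_alignment_statistic(B1, B2, 10).z
        z15 = map_alignment_statistic(B1, B2, 15).z
        z20 = map_alignment_statistic(B1, B2, 20).z
        z25 = map_alignment_statistic(B1, B2, 25).z
        assert abs(z20 - z15) < abs(z15 - z10)
        assert abs(z25 - z20) < abs(z20 - z15)


class TestSuggestK:
    def test_constructed_tail_cut(self):
        lam = np.concatenate([np.full(4, 0.9), 0.9 * (np.arange(5, 15.0) - 4.0) ** -2])
        s = suggest_k([lam])
        assert s.k in (4, 5)

    def test_exact_power_law_returns_one(self):
        lam = 0.9 * np.arange(1, 21.0) ** -1.5
        s = suggest_k([lam])
        assert s.k == 1 and s.converged

    def test_stability_diagnostic_flags_noise_tails(self, rng):
        # frames whose variance-explained fractions are stable mode by mode
        base = np.sort(rng.random(20))[::-1]
        spectra = [base * c for c in (0.5, 1.0, 2.0, 1.5)]  # fractions identical
        s = suggest_k(spectra)
        assert s.stable_fraction_modes is not None
        assert s.stable_fraction_modes.all()

    def test_all_nonpositive_raises(self):
        with pytest.raises(ValueError):
            suggest_k([np.full(12, -1.0)])
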