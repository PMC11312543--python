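import numpy as np
import pytest

import pf2sc as p
from pf2sc.core import cpd_als, init_factors, project_data, update_projections
from pf2sc.errors import NumericError, ValidationError

from conftest import random_orthonormal


def _random_ds(rng, I=3, J=(6, 10), K=8):
    return p.RaggedDataset(
        matrices=[
            rng.standard_normal((int(j), K))
            for j in rng.integers(J[0], J[1] + 1, size=I)
        ],
        condition_ids=[f"c{i}" for i in range(I)],
        gene_ids=[f"g{k}" for k in range(K)],
    )


class TestInitFactors:
    def test_construction(self):
        ds = _random_ds(np.random.default_rng(0))
        dec = init_factors(ds, 3)
        np.testing.assert_array_equal(dec.condition_factors, np.ones((3, 3)))
        np.testing.assert_array_equal(dec.eigenstate_factors, np.eye(3))
        np.testing.assert_allclose(
            dec.gene_factors.T @ dec.gene_factors, np.eye(3), atol=1e-10
        )

    def test_full_rank_gives_complete_basis(self):
        ds = _random_ds(np.random.default_rng(1), K=5, J=(6, 8))
        dec = init_factors(ds, 5)
        np.testing.assert_allclose(
            dec.gene_factors.T @ dec.gene_factors, np.eye(5), atol=1e-10
        )

    def test_low_rank_data_spans_row_space(self):
        """Rank-2 data: init C spans the exact row space (vs full SVD oracle)."""
        rng = np.random.default_rng(2)
        basis = rng.standard_normal((2, 8))
        ds = p.RaggedDataset(
            matrices=[rng.standard_normal((j, 2)) @ basis for j in (5, 6)],
            condition_ids=["a", "b"],
            gene_ids=[f"g{k}" for k in range(8)],
        )
        dec = init_factors(ds, 2)
        _, _, Vt = np.linalg.svd(np.vstack(ds.dense_matrices()))
        # principal angles between span(C) and oracle top-2 right space
        s = np.linalg.svd(dec.gene_factors.T @ Vt[:2].T, compute_uv=False)
        assert np.all(np.arccos(np.clip(s, -1, 1)) < 1e-8)

    def test_rank_too_large_raises(self):
        ds = _random_ds(np.random.default_rng(3), J=(4, 5), K=8)
        with pytest.raises(ValidationError, match="rank"):
            init_factors(ds, 6)

    def test_randomized_svd_seeded(self):
        ds = _random_ds(np.random.default_rng(4))
        d1 = init_factors(ds, 3, seed=7, svd_method="randomized")
        d2 = init_factors(ds, 3, seed=7, svd_method="randomized")
        np.testing.assert_array_equal(d1.gene_factors, d2.gene_factors)


class TestUpdateProjections:
    def test_identity_when_data_equals_target(self):
        rng = np.random.default_rng(0)
        R, K = 3, 6
        B = np.eye(R) + 0.1 * rng.standard_normal((R, R))
        C = random_orthonormal(rng, K, R)
        A = rng.uniform(0.5, 1, (1, R))
        M = (B * A[0]) @ C.T
        ds = p.RaggedDataset(
            matrices=[M], condition_ids=["a"], gene_ids=[f"g{k}" for k in range(K)]
        )
        (P,) = update_projections(ds, A, B, C)
        np.testing.assert_allclose(P, np.eye(R), atol=1e-10)

    def test_recovers_planted_rotation(self):
        rng = np.random.default_rng(1)
        R, K, J = 2, 7, 5
        B = np.eye(R) + 0.05 * rng.standard_normal((R, R))
        C = random_orthonormal(rng, K, R)
        A = rng.uniform(0.5, 1, (1, R))
        Q = random_orthonormal(rng, J, R)
        M = (B * A[0]) @ C.T
        ds = p.RaggedDataset(
            matrices=[Q @ M], condition_ids=["a"], gene_ids=[f"g{k}" for k in range(K)]
        )
        (P,) = update_projections(ds, A, B, C)
        np.testing.assert_allclose(P, Q, atol=1e-8)

    def test_columns_orthonormal(self):
        rng = np.random.default_rng(2)
        ds = _random_ds(rng)
        A = rng.uniform(0.2, 1, (3, 2))
        B = np.eye(2)
        C = random_orthonormal(rng, 8, 2)
        for P in update_projections(ds, A, B, C):
            np.testing.assert_allclose(P.T @ P, np.eye(2), atol=1e-8)

    def test_beats_random_orthonormal_candidates(self):
        """Procrustes optimality vs a 1000-candidate random search."""
        rng = np.random.default_rng(3)
        J, K, R = 6, 4, 2
        X = rng.standard_normal((J, K))
        A = rng.uniform(0.5, 1, (1, R))
        B = np.eye(R) + 0.1 * rng.standard_normal((R, R))
        C = random_orthonormal(rng, K, R)
        M = (B * A[0]) @ C.T
        ds = p.RaggedDataset(
            matrices=[X], condition_ids=["a"], gene_ids=list("abcd")
        )
        (P,) = update_projections(ds, A, B, C)
        err_opt = np.linalg.norm(X - P @ M)
        for _ in range(1000):
            Pc = random_orthonormal(rng, J, R)
            assert err_opt <= np.linalg.norm(X - Pc @ M) + 1e-12

    def test_too_few_cells_raises(self):
        rng = np.random.default_rng(4)
        ds = p.RaggedDataset(
            matrices=[rng.standard_normal((2, 5))],
            condition_ids=["a"],
            gene_ids=[f"g{k}" for k in range(5)],
        )
        with pytest.raises(ValidationError):
            update_projections(
                ds, np.ones((1, 3)), np.eye(3), random_orthonormal(rng, 5, 3)
            )

    def test_degenerate_all_zero_raises(self):
        ds = p.RaggedDataset(
            matrices=[np.zeros((4, 5))],
            condition_ids=["a"],
            gene_ids=[f"g{k}" for k in range(5)],
        )
        rng = np.random.default_rng(5)
        with pytest.raises(NumericError):
            update_projections(
                ds, np.ones((1, 2)), np.eye(2), random_orthonormal(rng, 5, 2)
            )


class TestProjectData:
    def test_identity_projection(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((3, 5))
        ds = p.RaggedDataset(
            matrices=[X], condition_ids=["a"], gene_ids=[f"g{k}" for k in range(5)]
        )
        T = project_data(ds, [np.eye(3)])
        np.testing.assert_array_equal(T[0], X)

    def test_matches_direct_product(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((5, 3))
        P = random_orthonormal(rng, 5, 2)
        ds = p.RaggedDataset(
            matrices=[X], condition_ids=["a"], gene_ids=["g1", "g2", "g3"]
        )
        np.testing.assert_allclose(project_data(ds, [P])[0], P.T @ X, atol=1e-12)

    def test_shape_mismatch_raises(self):
        ds = _random_ds(np.random.default_rng(2), I=2)
        with pytest.raises(ValidationError):
            project_data(ds, [np.eye(3)])


class TestCpdAls:
    def test_rank1_exact_recovery(self):
        rng = np.random.default_rng(0)
        a, b, c = rng.standard_normal(4), rng.standard_normal(3), rng.standard_normal(6)
        T = np.einsum("i,r,k->irk", a, b, c)
        A0 = a[:, None] + 0.3 * rng.standard_normal((4, 1))
        B0 = b[:, None] + 0.3 * rng.standard_normal((3, 1))
        C0 = c[:, None] + 0.3 * rng.standard_normal((6, 1))
        A, B, C, _ = cpd_als(T, 1, 20, init=(A0, B0, C0))
        recon = np.einsum("ij,rj,kj->irk", A, B, C)
        assert np.linalg.norm(T - recon) < 1e-8

    def test_superdiagonal_identity_init(self):
        T = np.zeros((3, 3, 3))
        for r in range(3):
            T[r, r, r] = 1.0
        A, B, C, _ = cpd_als(T, 3, 20, init=(np.eye(3), np.eye(3), np.eye(3)))
        recon = np.einsum("ij,rj,kj->irk", A, B, C)
        assert np.linalg.norm(T - recon) < 1e-10

    def test_zero_tensor(self):
        rng = np.random.default_rng(1)
        A, B, C, _ = cpd_als(
            np.zeros((2, 3, 4)),
            2,
            5,
            init=(
                rng.standard_normal((2, 2)),
                rng.standard_normal((3, 2)),
                rng.standard_normal((4, 2)),
            ),
        )
        recon = np.einsum("ij,rj,kj->irk", A, B, C)
        assert np.linalg.norm(recon) < 1e-10

    def test_fit_non_increasing_error(self):
        rng = np.random.default_rng(2)
        T = rng.standard_normal((4, 3, 5))
        init = (
            rng.standard_normal((4, 2)),
            rng.standard_normal((3, 2)),
            rng.standard_normal((5, 2)),
        )
        errs = []
        factors = init
        for _ in range(10):
            factors = cpd_als(T, 2, 1, init=factors)[:3]
            recon = np.einsum("ij,rj,kj->irk", *factors)
            errs.append(np.linalg.norm(T - recon))
        assert all(e2 <= e1 + 1e-10 for e1, e2 in zip(errs, errs[1:]))


class TestFit:
    def test_noiseless_planted_r2x(self, small_planted, small_fit):
        assert small_fit.r2x >= 0.999
        assert small_fit.converged

    def test_single_condition_rank1_matches_svd(self):
        """One condition at rank 1 reduces to the truncated SVD share."""
        rng = np.random.default_rng(3)
        X = rng.standard_normal((12, 7))
        ds = p.RaggedDataset(
            matrices=[X],
            condition_ids=["a"],
            gene_ids=[f"g{k}" for k in range(7)],
        )
        dec = p.fit(ds, p.FitConfig(rank=1, seed=0, accelerate=False))
        s = np.linalg.svd(X, compute_uv=False)
        expected = s[0] ** 2 / np.sum(s**2)
        assert dec.r2x == pytest.approx(expected, abs=1e-6)

    def test_monotone_r2x_without_acceleration(self):
        rng = np.random.default_rng(4)
        for seed in range(3):
            spec = p.SyntheticSpec(
                n_conditions=4,
                cells_per_condition=(10, 16),
                n_genes=12,
                rank=2,
                noise_sd=0.3,
                seed=seed,
            )
            ds, _ = p.make_synthetic(spec)
            dec = p.fit(ds, p.FitConfig(rank=2, seed=0, accelerate=False))
            h = dec.r2x_history
            assert all(b >= a - 1e-10 for a, b in zip(h, h[1:]))

    def test_accelerated_path_reaches_same_quality(self, small_planted):
        ds, truth = small_planted
        acc = p.fit(ds, p.FitConfig(rank=3, seed=0, accelerate=True))
        assert acc.r2x >= 0.999
        assert p.fms(p.standardize(acc), truth) >= 0.98

    def test_deterministic_given_seed(self, small_planted):
        ds, _ = small_planted
        cfg = p.FitConfig(rank=3, seed=5)
        d1, d2 = p.fit(ds, cfg), p.fit(ds, cfg)
        np.testing.assert_array_equal(d1.condition_factors, d2.condition_factors)
        np.testing.assert_array_equal(d1.gene_factors, d2.gene_factors)
        for P1, P2 in zip(d1.projections, d2.projections):
            np.testing.assert_array_equal(P1, P2)

    def test_rank_exceeding_cells_raises(self, small_planted):
        ds, _ = small_planted
        with pytest.raises(ValidationError):
            p.fit(ds, p.FitConfig(rank=100))


class TestReconstructAndR2X:
    def test_noiseless_reconstruction_exact(self, small_planted):
        ds, truth = small_planted
        for X, Xh in zip(ds.dense_matrices(), p.reconstruct(truth)):
            assert np.linalg.norm(X - Xh) < 1e-6

    def test_standardize_preserves_reconstruction(self, small_fit):
        before = p.reconstruct(small_fit)
        after = p.reconstruct(p.standardize(small_fit))
        for X1, X2 in zip(before, after):
            np.testing.assert_allclose(X1, X2, atol=1e-10)

    def test_exact_reconstruction_gives_one(self, small_planted):
        ds, truth = small_planted
        assert p.r2x(ds, truth) == pytest.approx(1.0, abs=1e-12)

    def test_zero_model_gives_zero(self, small_planted):
        ds, truth = small_planted
        zero = truth.copy()
        zero.component_weights = np.zeros(truth.rank)
        assert p.r2x(ds, zero) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_toy(self):
        """X = [[2,0],[0,0]], X_hat = [[1,0],[0,0]] -> 1 - 1/4 = 0.75."""
        ds = p.RaggedDataset(
            matrices=[np.array([[2.0, 0.0], [0.0, 0.0]])],
            condition_ids=["a"],
            gene_ids=["g1", "g2"],
        )
        dec = p.Pf2Decomposition(
            rank=1,
            condition_factors=np.array([[1.0]]),
            eigenstate_factors=np.array([[1.0]]),
            gene_factors=np.array([[1.0], [0.0]]),
            projections=[np.array([[1.0], [0.0]])],
        )
        assert p.r2x(ds, dec) == pytest.approx(0.75, abs=1e-12)

    def test_all_zero_data_raises(self):
        ds = p.RaggedDataset(
            matrices=[np.zeros((2, 2))], condition_ids=["a"], gene_ids=["g1", "g2"]
        )
        dec = p.Pf2Decomposition(
            rank=1,
            condition_factors=np.ones((1, 1)),
            eigenstate_factors=np.ones((1, 1)),
            gene_factors=np.ones((2, 1)),
            projections=[np.eye(2)[:, :1]],
        )
        with pytest.raises(ValidationError):
            p.r2x(ds, dec)


class TestCpdEquivalenceLimit:
    def test_pf2_matches_cp_when_slices_share_frame(self):
        """J_i = R with a shared cell frame: Pf2 R2X equals direct CP-ALS."""
        rng = np.random.default_rng(7)
        I, R, K = 5, 3, 10
        A = rng.uniform(0.3, 1.0, (I, R))
        B = np.eye(R) + 0.1 * rng.standard_normal((R, R))
        C = random_orthonormal(rng, K, R)
        slices = [(B * A[i]) @ C.T for i in range(I)]
        ds = p.RaggedDataset(
            matrices=slices,
            condition_ids=[f"c{i}" for i in range(I)],
            gene_ids=[f"g{k}" for k in range(K)],
        )
        dec = p.fit(
            ds,
            p.FitConfig(rank=R, seed=0, r2x_tolerance=1e-10, max_iterations=1000),
        )
        # direct CP on the stacked I x R x K tensor
        T = np.stack(slices)
        rng2 = np.random.default_rng(8)
        factors = (
            rng2.standard_normal((I, R)),
            rng2.standard_normal((R, R)),
            rng2.standard_normal((K, R)),
        )
        A2, B2, C2, _ = cpd_als(T, R, 1000, init=factors)
        recon = np.einsum("ij,rj,kj->irk", A2, B2, C2)
        cp_r2x = 1.0 - np.sum((T - recon) ** 2) / np.sum(T**2)
        assert dec.r2x == pytest.approx(cp_r2x, abs=1e-6)
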