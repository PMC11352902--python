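"""OPNMF: initialization, update rule, fitting and winner-takes-all."""

import warnings

import numpy as np
import pytest

from crossmorph import (
    adjusted_rand_index,
    fit_opnmf,
    nndsvd_init,
    opnmf_step,
    reconstruction_error,
    winner_takes_all,
)
from crossmorph.opnmf import EPS, mean_reconstruction_error


def nndsvd_oracle(X, k):
    """Independent NNDSVD from a dense SVD, written against the published
    positive/negative-section rule only (no shared code with the package)."""
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    m = X.shape[0]
    W = np.zeros((m, k))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    for j in range(1, k):
        u, v = U[:, j], Vt[j]
        up = np.where(u > 0, u, 0.0)
        un = np.where(u < 0, -u, 0.0)
        vp = np.where(v > 0, v, 0.0)
        vn = np.where(v < 0, -v, 0.0)
        mp = np.linalg.norm(up) * np.linalg.norm(vp)
        mn = np.linalg.norm(un) * np.linalg.norm(vn)
        if mp >= mn:
            W[:, j] = np.sqrt(S[j] * mp) * up / np.linalg.norm(up)
        else:
            W[:, j] = np.sqrt(S[j] * mn) * un / np.linalg.norm(un)
    return W


class TestNNDSVDInit:
    def test_disjoint_blocks_supported_separately(self):
        X = np.zeros((6, 4))
        X[:3, :2] = [[1, 2], [2, 1], [1, 1]]
        X[3:, 2:] = [[3, 1], [1, 3], [2, 2]]
        W0 = nndsvd_init(X, 2)
        supports = [np.flatnonzero(W0[:, j] > 1e-12) for j in range(2)]
        assert {tuple(s) for s in supports} == {(0, 1, 2), (3, 4, 5)}

    def test_non_negative_for_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            X = rng.random((12, 7))
            assert np.min(nndsvd_init(X, 4)) >= 0

    def test_matches_dense_svd_oracle(self):
        X = np.array([[1.0, 0.2, 0.0],
                      [0.8, 1.1, 0.1],
                      [0.0, 0.3, 2.0],
                      [0.5, 0.0, 1.5]])
        assert np.allclose(nndsvd_init(X, 3), nndsvd_oracle(X, 3), atol=1e-12)

    def test_k_beyond_rank_zero_padded_with_warning(self):
        X = np.outer(np.ones(6), np.arange(1.0, 5.0))  # rank 1
        with pytest.warns(RuntimeWarning, match="rank"):
            W0 = nndsvd_init(X, 3)
        assert np.allclose(W0[:, 1:], 0.0)

    def test_k_larger_than_dims_rejected(self):
        with pytest.raises(ValueError):
            nndsvd_init(np.ones((4, 3)), 5)


class TestOpnmfStep:
    def test_exact_solution_is_fixed_point(self, block_factor_fixture):
        W, _, X = block_factor_fixture
        assert np.allclose(opnmf_step(W, X), W, atol=1e-12)

    def test_scalar_identity_case(self):
        W = opnmf_step(np.array([[1.0]]), np.array([[2.0]]))
        assert np.allclose(W, [[1.0]])

    def test_matches_naive_formula_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.random((6, 4))
        W = rng.random((6, 2))
        got = opnmf_step(W, X)
        XXt = X @ X.T
        expect = W * (XXt @ W) / np.maximum(W @ W.T @ XXt @ W, EPS)
        expect /= np.linalg.norm(expect, 2)
        assert np.allclose(got, expect, rtol=1e-10)

    def test_preserves_non_negativity_exactly(self):
        rng = np.random.default_rng(9)
        X = rng.random((20, 10))
        W = nndsvd_init(X, 3)
        for _ in range(50):
            W = opnmf_step(W, X)
            assert np.min(W) >= 0.0


class TestFitOpnmf:
    def test_error_vanishes_on_exactly_representable_data(self, block_factor_fixture):
        _, _, X = block_factor_fixture
        model = fit_opnmf(X, 3, max_iter=500)
        assert model.recon_error / np.sum(X * X) <= 1e-8
        assert model.orthogonality_residual <= 1e-3

    def test_k1_matches_power_iteration_oracle(self):
        rng = np.random.default_rng(10)
        X = rng.random((30, 12))
        model = fit_opnmf(X, 1, max_iter=2000, tol=1e-10)
        # leading non-negative direction by power iteration on X X^T
        v = np.ones(30)
        for _ in range(500):
            v = X @ (X.T @ v)
            v /= np.linalg.norm(v)
        w = model.W[:, 0] / np.linalg.norm(model.W[:, 0])
        assert np.allclose(np.abs(w), np.abs(v), atol=1e-5)
        s2 = v @ (X @ (X.T @ v))
        assert np.isclose(model.recon_error, np.sum(X * X) - s2, rtol=1e-6)

    def test_loss_monotone_non_increasing(self, small_species):
        _, stack, _ = small_species
        model = fit_opnmf(stack, 5, max_iter=800, tol=0.0)
        increases = np.diff(model.loss_history)
        assert increases.max() <= 1e-10 * model.loss_history[0]

    def test_block_recovery_ari(self, small_species):
        """SNR-10 block data: winner-takes-all recovers the planted parcels."""
        spec, stack, truth = small_species
        model = fit_opnmf(stack, spec.k_true, max_iter=3000, tol=1e-5)
        parc = winner_takes_all(model.W)
        ari = adjusted_rand_index(parc.labels, truth.label_volume[stack.mask])
        assert ari >= 0.9

    def test_subject_order_invariance_of_parcellation(self, small_species):
        _, stack, _ = small_species
        rng = np.random.default_rng(0)
        perm = rng.permutation(stack.n_subjects)
        a = winner_takes_all(fit_opnmf(stack.data, 4, max_iter=1500).W)
        b = winner_takes_all(fit_opnmf(stack.data[:, perm], 4, max_iter=1500).W)
        assert adjusted_rand_index(a.labels, b.labels) == 1.0

    def test_h_is_projection_of_x(self, block_factor_fixture):
        _, _, X = block_factor_fixture
        model = fit_opnmf(X, 3, max_iter=200)
        assert np.allclose(model.H, model.W.T @ X)

    def test_nonfinite_input_rejected(self):
        X = np.ones((6, 4))
        X[0, 0] = -1.0
        with pytest.raises(ValueError):
            fit_opnmf(X, 2)


class TestReconstructionError:
    def test_zero_for_perfect_reconstruction(self, block_factor_fixture):
        W, _, X = block_factor_fixture
        assert reconstruction_error(X, W) <= 1e-20

    def test_two_by_two_hand_computation(self):
        X = np.eye(2)
        W = np.array([[1.0], [0.0]])
        assert np.isclose(reconstruction_error(X, W), 1.0)

    def test_mre_is_error_per_entry(self):
        rng = np.random.default_rng(1)
        X = rng.random((8, 5))
        W = rng.random((8, 2))
        assert np.isclose(mean_reconstruction_error(X, W),
                          reconstruction_error(X, W) / 40)

    def test_fitted_error_non_increasing_in_k(self, small_species):
        _, stack, _ = small_species
        errors = [fit_opnmf(stack, k, max_iter=1500, tol=1e-5).recon_error
                  for k in (2, 3, 4, 5, 6)]
        assert np.all(np.diff(errors) <= 1e-8 * errors[0])


class TestWinnerTakesAll:
    def test_single_nonzero_per_row(self):
        W = np.zeros((4, 3))
        W[0, 2] = W[1, 0] = W[2, 1] = W[3, 0] = 1.0
        parc = winner_takes_all(W)
        assert list(parc.labels) == [3, 1, 2, 1]

    def test_tie_breaks_to_lowest_index(self):
        parc = winner_takes_all(np.array([[0.3, 0.3]]))
        assert parc.labels[0] == 1

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        W = rng.random((30, 4))
        perm = np.array([2, 0, 3, 1])
        a = winner_takes_all(W).labels
        b = winner_takes_all(W[:, perm]).labels
        # label j in permuted W corresponds to perm[j-1]+1 in original
        assert np.array_equal(perm[b - 1] + 1, a)

    def test_zero_row_unassigned_with_warning(self):
        W = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 2.0]])
        with pytest.warns(RuntimeWarning, match="all-zero"):
            parc = winner_takes_all(W)
        assert parc.labels[1] == 0

    def test_empty_factor_reported_dropped(self):
        W = np.array([[1.0, 0.1], [0.9, 0.2]])
        parc = winner_takes_all(W)
        assert parc.dropped == (2,)
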