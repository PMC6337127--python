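"""Diffusion states, log/SVD embedding and the KL diagnostic."""

import numpy as np
import pytest

from conftest import random_graph
from difforest.diffusion import (
    DiffusionStates,
    concat_embeddings,
    embed_network,
    kl_objective,
    log_transform,
    rwr_closed_form,
    rwr_diffusion,
    svd_embed,
)
from difforest.network_io import from_adjacency, to_transition


class TestRWR:
    def test_alpha_one_is_identity(self, path_graph):
        M = to_transition(path_graph)
        np.testing.assert_array_equal(rwr_diffusion(M, alpha=1.0).S, np.eye(3))
        np.testing.assert_array_equal(rwr_closed_form(M, alpha=1.0).S, np.eye(3))

    def test_two_node_hand_solution(self):
        # one edge, alpha=0.5: fixed point gives s_0 = (2/3, 1/3)
        M = to_transition(from_adjacency(np.array([[0, 1.0], [1.0, 0]])))
        S = rwr_closed_form(M, alpha=0.5).S
        np.testing.assert_allclose(S[0], [2 / 3, 1 / 3], atol=1e-12)
        Si = rwr_diffusion(M, alpha=0.5, tol=1e-12).S
        np.testing.assert_allclose(Si[0], [2 / 3, 1 / 3], atol=1e-8)

    def test_path_graph_matches_linear_system(self, path_graph):
        M = to_transition(path_graph)
        S_it = rwr_diffusion(M, alpha=0.5, tol=1e-12).S
        S_cf = rwr_closed_form(M, alpha=0.5).S
        np.testing.assert_allclose(S_it, S_cf, atol=1e-8)

    @pytest.mark.parametrize("alpha", [0.1, 0.5, 0.9])
    def test_oracle_equivalence_random_graphs(self, alpha):
        rng = np.random.default_rng(42)
        for _ in range(10):
            g = random_graph(20, rng)
            M = to_transition(g)
            S_it = rwr_diffusion(M, alpha=alpha, tol=1e-10).S
            S_cf = rwr_closed_form(M, alpha=alpha).S
            assert np.abs(S_it - S_cf).max() < 1e-8

    def test_rows_are_distributions_with_dangling_nodes(self):
        # node 3 isolated: its row is exactly the restart distribution and
        # mass landing there from other sources is redirected to restart
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 1.0
        a[1, 2] = a[2, 1] = 0.5
        M = to_transition(from_adjacency(a))
        assert M.dangling == {3}
        S = rwr_diffusion(M, alpha=0.4, tol=1e-12).S
        np.testing.assert_allclose(S.sum(axis=1), 1.0, atol=1e-8)
        np.testing.assert_allclose(S[3], [0, 0, 0, 1], atol=1e-12)
        S_cf = rwr_closed_form(M, alpha=0.4).S
        np.testing.assert_allclose(S, S_cf, atol=1e-8)

    def test_row_stochastic_every_iteration(self, path_graph):
        M = to_transition(path_graph)
        for it in range(1, 6):
            S = rwr_diffusion(M, alpha=0.5, tol=0.0, max_iter=it).S
            np.testing.assert_allclose(S.sum(axis=1), 1.0, atol=1e-10)

    def test_nonconvergence_warns_and_flags(self, path_graph):
        M = to_transition(path_graph)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            out = rwr_diffusion(M, alpha=0.1, tol=1e-15, max_iter=2)
        assert not out.converged

    def test_alpha_bounds_rejected(self, path_graph):
        M = to_transition(path_graph)
        for bad in (0.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                rwr_diffusion(M, alpha=bad)

    def test_closed_form_size_cap(self):
        g = random_graph(12, np.random.default_rng(0))
        with pytest.raises(ValueError, match="capped"):
            rwr_closed_form(to_transition(g), 0.5, max_n=10)

    def test_locality_increases_with_alpha(self):
        # self-visitation S_ii is non-decreasing in the restart probability
        rng = np.random.default_rng(7)
        g = random_graph(15, rng)
        M = to_transition(g)
        diags = [
            np.diag(rwr_closed_form(M, a).S) for a in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        for lo, hi in zip(diags, diags[1:]):
            assert (hi >= lo - 1e-12).all()


class TestLogTransform:
    def test_single_entry(self):
        states = DiffusionStates(S=np.array([[1.0]]), alpha=0.5)
        np.testing.assert_allclose(log_transform(states), [[np.log(2.0)]])

    def test_zero_entry_uses_pseudocount(self):
        S = np.eye(4)
        R = log_transform(DiffusionStates(S=S, alpha=0.5))
        assert R[0, 1] == pytest.approx(np.log(0.25))
        assert np.isfinite(R).all()

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(5)
        S = rng.dirichlet(np.ones(6), size=6)
        R = log_transform(DiffusionStates(S=S, alpha=0.5))
        for i in range(6):
            for j in range(6):
                assert R[i, j] == pytest.approx(np.log(S[i, j] + 1 / 6))


class TestSVDEmbed:
    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(2)
        R = rng.normal(size=(12, 12))
        e = svd_embed(R, d=12)
        err = np.linalg.norm(e.X @ e.W.T - R) / np.linalg.norm(R)
        assert err < 1e-8

    def test_rank_one_exact_at_d_one(self):
        rng = np.random.default_rng(3)
        u, v = rng.normal(size=10), rng.normal(size=10)
        R = np.outer(u, v)
        e = svd_embed(R, d=1)
        np.testing.assert_allclose(e.X @ e.W.T, R, atol=1e-10)

    def test_eckart_young_tail_energy(self):
        rng = np.random.default_rng(4)
        R = rng.normal(size=(15, 15))
        s_all = np.linalg.svd(R, compute_uv=False)  # dense-SVD oracle
        for d in (1, 4, 9, 15):
            e = svd_embed(R, d=d)
            err2 = np.linalg.norm(e.X @ e.W.T - R) ** 2
            assert err2 == pytest.approx(np.sum(s_all[d:] ** 2), rel=1e-8, abs=1e-8)

    def test_error_nonincreasing_in_d(self):
        rng = np.random.default_rng(6)
        R = rng.normal(size=(10, 10))
        errs = [
            np.linalg.norm(svd_embed(R, d).X @ svd_embed(R, d).W.T - R)
            for d in range(1, 11)
        ]
        assert all(b <= a + 1e-10 for a, b in zip(errs, errs[1:]))

    def test_singular_values_nonincreasing_and_sign_fixed(self):
        rng = np.random.default_rng(9)
        R = rng.normal(size=(8, 8))
        e = svd_embed(R, d=5)
        assert (np.diff(e.singular_values) <= 1e-12).all()
        for k in range(5):
            j = np.argmax(np.abs(e.X[:, k]))
            assert e.X[j, k] >= 0

    def test_invalid_d_rejected(self):
        R = np.eye(5)
        for bad in (0, 6):
            with pytest.raises(ValueError):
                svd_embed(R, bad)


class TestKLObjective:
    def test_zero_when_model_reproduces_states(self):
        # logits ln(S) give softmax rows equal to S exactly (rows sum to 1)
        S = np.array([[0.7, 0.3], [0.4, 0.6]])
        states = DiffusionStates(S=S, alpha=0.5)
        X = np.log(S)
        W = np.eye(2)
        assert kl_objective(states, X, W) == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative(self):
        rng = np.random.default_rng(11)
        S = rng.dirichlet(np.ones(8), size=8)
        states = DiffusionStates(S=S, alpha=0.5)
        X, W = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        assert kl_objective(states, X, W) >= 0.0

    def test_larger_d_fits_better(self):
        # median over random graphs: full-dimensional SVD embedding explains
        # the walks at least as well as a 2-dimensional one
        rng = np.random.default_rng(12)
        deltas = []
        for _ in range(10):
            g = random_graph(10, rng)
            states = rwr_closed_form(to_transition(g), 0.5)
            R = log_transform(states)
            e_hi, e_lo = svd_embed(R, 10), svd_embed(R, 2)
            deltas.append(
                kl_objective(states, e_lo.X, e_lo.W)
                - kl_objective(states, e_hi.X, e_hi.W)
            )
        assert np.median(deltas) >= 0.0

    def test_shape_mismatch_rejected(self):
        states = DiffusionStates(S=np.eye(3), alpha=0.5)
        with pytest.raises(ValueError):
            kl_objective(states, np.zeros((2, 2)), np.zeros((3, 2)))


class TestEmbedConcat:
    def test_embed_shape_contract(self):
        g = random_graph(20, np.random.default_rng(13))
        e = embed_network(g, alpha=0.5, d=5)
        assert e.X.shape == (20, 5) and e.W.shape == (20, 5)

    def test_embed_deterministic(self):
        g = random_graph(15, np.random.default_rng(14))
        e1 = embed_network(g, alpha=0.5, d=4)
        e2 = embed_network(g, alpha=0.5, d=4)
        np.testing.assert_array_equal(e1.X, e2.X)

    def test_concat_width_and_block_identity(self):
        rng = np.random.default_rng(15)
        embs = [embed_network(random_graph(12, rng), d=3) for _ in range(4)]
        fm = concat_embeddings(embs)
        assert fm.X_full.shape == (12, 12)  # K*d columns
        for k, e in enumerate(embs):
            np.testing.assert_array_equal(fm.block(k), e.X)

    def test_concat_single_is_identity(self):
        e = embed_network(random_graph(10, np.random.default_rng(16)), d=3)
        fm = concat_embeddings([e])
        np.testing.assert_array_equal(fm.X_full, e.X)

    def test_concat_mismatched_n_rejected(self):
        rng = np.random.default_rng(17)
        e1 = embed_network(random_graph(10, rng), d=2)
        e2 = embed_network(random_graph(11, rng), d=2)
        with pytest.raises(ValueError):
            concat_embeddings([e1, e2])
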