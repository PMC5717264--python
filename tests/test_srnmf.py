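import numpy as np
import pytest
import scipy.sparse as sp

from biplink import (
    SRNMF,
    LatentFactors,
    SRNMFConfig,
    init_factors,
    objective,
    predict_scores,
    select_k,
    split_edges,
    update_step,
)
from biplink.similarity import similarity_matrix
from biplink.synthetic import latent_block_network

from oracles import plain_nmf_trace


def _dense_objective(A, S, X, Y, gamma, lam):
    """Reference objective evaluated with full dense residuals."""
    A = np.asarray(A, dtype=float)
    S = np.asarray(S, dtype=float)
    R = A - X @ Y
    return (
        0.5 * (R**2).sum()
        + 0.5 * gamma * ((R**2) * S).sum()
        + 0.5 * lam * ((X**2).sum() + (Y**2).sum())
    )


class TestSelectK:
    def test_rank_one_matrix(self):
        A = np.outer([1, 0, 1, 1], [0, 1, 1])
        assert select_k(A, 0.95) == 1
        assert select_k(A, 1.0) == 1

    def test_diagonal_two_one(self):
        A = np.diag([2.0, 1.0])  # squared-spectrum contributions 0.8, 1.0
        assert select_k(A, 0.95) == 2
        assert select_k(A, 0.8) == 1

    def test_threshold_one_full_rank(self):
        rng = np.random.default_rng(0)
        A = (rng.random((6, 9)) < 0.5).astype(float)
        A += np.eye(6, 9)  # ensure nonzero
        A = (A > 0).astype(float)
        assert select_k(A, 1.0) == np.linalg.matrix_rank(A)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            select_k(np.zeros((3, 3)))


class TestInitFactors:
    def test_deterministic_and_positive(self):
        f1 = init_factors(5, 4, 3, seed=9)
        f2 = init_factors(5, 4, 3, seed=9)
        np.testing.assert_array_equal(f1.X, f2.X)
        np.testing.assert_array_equal(f1.Y, f2.Y)
        assert (f1.X > 0).all() and (f1.Y > 0).all()
        assert f1.X.shape == (5, 3) and f1.Y.shape == (3, 4)

    def test_tiny_dimensions(self):
        f = init_factors(1, 1, 1, seed=0)
        assert f.X.shape == (1, 1) and f.Y.shape == (1, 1)

    def test_overcomplete_warns(self):
        with pytest.warns(UserWarning, match="over-complete"):
            init_factors(3, 3, 5, seed=0)


class TestObjective:
    def test_hand_value(self):
        A = np.eye(2)
        X = np.array([[1.0], [0.0]])
        Y = np.array([[1.0, 0.0]])
        S = np.ones((2, 2))
        assert objective(A, S, X, Y, 0.5, 2.0) == pytest.approx(2.75)

    def test_exact_factorization_zero(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(size=(4, 2))
        Y = rng.uniform(size=(2, 5))
        A = X @ Y
        S = rng.uniform(size=(4, 5))
        assert objective(A, S, X, Y, 3.0, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_reduces_to_plain_frobenius_loss(self):
        rng = np.random.default_rng(2)
        A = (rng.random((5, 6)) < 0.4).astype(float)
        X = rng.uniform(size=(5, 2))
        Y = rng.uniform(size=(2, 6))
        S = rng.uniform(size=(5, 6))
        want = 0.5 * ((A - X @ Y) ** 2).sum()
        assert objective(A, S, X, Y, 0.0, 0.0) == pytest.approx(want)

    def test_sparse_path_matches_dense_reference(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            A = (rng.random((7, 5)) < 0.4).astype(float)
            S = similarity_matrix(A, "cn").S
            X = rng.uniform(size=(7, 3))
            Y = rng.uniform(size=(3, 5))
            g, l = rng.uniform(0, 2), rng.uniform(0, 3)
            got = objective(sp.csr_matrix(A), sp.csr_matrix(S), X, Y, g, l)
            assert got == pytest.approx(_dense_objective(A, S, X, Y, g, l))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            objective(np.eye(2), np.ones((3, 3)), np.ones((2, 1)), np.ones((1, 2)), 0, 0)


class TestUpdateStep:
    def test_fixed_point_at_exact_factorization(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0.5, 1.5, size=(4, 2))
        Y = rng.uniform(0.5, 1.5, size=(2, 5))
        A = X @ Y
        f = LatentFactors(X=X, Y=Y)
        out = update_step(A, np.zeros_like(A), f, gamma=0.0, lam=0.0)
        np.testing.assert_allclose(out.X, X, rtol=1e-9)
        np.testing.assert_allclose(out.Y, Y, rtol=1e-9)

    def test_exact_zero_entries_stay_zero(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(size=(4, 2))
        X[1, 0] = 0.0
        Y = rng.uniform(size=(2, 5))
        A = (rng.random((4, 5)) < 0.5).astype(float)
        out = update_step(A, np.ones_like(A), LatentFactors(X=X, Y=Y), 0.7, 1.1)
        assert out.X[1, 0] == 0.0

    def test_objective_never_increases(self):
        """Multiplicative updates are monotone for all γ, λ ≥ 0."""
        rng = np.random.default_rng(6)
        for _ in range(30):
            n, m = rng.integers(3, 16, size=2)
            A = (rng.random((n, m)) < 0.4).astype(float)
            S = similarity_matrix(A, "cn").S
            k = int(rng.integers(1, min(n, m) + 1))
            g = float(rng.uniform(0, 2))
            l = float(rng.uniform(0, 3))
            f = init_factors(n, m, k, seed=int(rng.integers(2**31)))
            before = objective(A, S, f.X, f.Y, g, l)
            for _ in range(5):
                f = update_step(A, S, f, g, l)
                after = objective(A, S, f.X, f.Y, g, l)
                assert after <= before + 1e-8 * (1 + before)
                before = after


class TestFit:
    def test_low_rank_network_is_recovered(self):
        planted = latent_block_network(20, 18, 2, p_in=1.0, p_out=0.0, seed=0)
        A = planted.network.A
        model = SRNMF(A, similarity=None, gamma=0.0, lam=0.0, k=2, max_iter=500)
        res = model.fit(seed=1)
        zero_obj = 0.5 * A.nnz  # objective of all-zero factors
        assert res.objective_trace[-1] < 0.01 * zero_obj

    def test_max_iter_zero_returns_initial_factors(self):
        A = np.eye(3)
        res = SRNMF(A, similarity="cn", max_iter=0, k=2).fit(seed=0)
        assert res.n_iter == 0
        assert len(res.objective_trace) == 1
        np.testing.assert_array_equal(res.X, init_factors(3, 3, 2, 0).X)

    def test_identical_seed_gives_bitwise_identical_traces(self):
        planted = latent_block_network(15, 15, 3, 0.5, 0.05, seed=2)
        m1 = SRNMF(planted.network.A, similarity="cra", k=3, max_iter=40)
        m2 = SRNMF(planted.network.A, similarity="cra", k=3, max_iter=40)
        t1 = m1.fit(seed=5).objective_trace
        t2 = m2.fit(seed=5).objective_trace
        assert t1 == t2

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="no edges"):
            SRNMF(np.zeros((3, 3)))

    def test_trace_is_monotone_and_summary_prints(self):
        planted = latent_block_network(20, 20, 2, 0.5, 0.05, seed=3)
        res = SRNMF(planted.network.A, similarity="cn", k=4, max_iter=60).fit(seed=0)
        trace = np.array(res.objective_trace)
        assert (np.diff(trace) <= 1e-8 * (1 + trace[:-1])).all()
        text = res.summary()
        assert "latent dimension" in text and "final objective" in text

    def test_auto_k_uses_spectral_selection(self):
        planted = latent_block_network(20, 20, 2, 1.0, 0.0, seed=4)
        model = SRNMF(planted.network.A, similarity="cn", k="auto")
        assert model.k_ == select_k(planted.network.A)


class TestReductionToPlainNMF:
    def test_trace_matches_independent_implementation(self):
        """γ=λ=0 must reproduce plain Euclidean multiplicative-update NMF."""
        rng = np.random.default_rng(7)
        A = (rng.random((12, 10)) < 0.35).astype(float)
        A[0, 0] = 1.0
        f0 = init_factors(12, 10, 4, seed=8)
        model = SRNMF(A, similarity=None, gamma=0.0, lam=0.0, k=4,
                      max_iter=50, tol=1e-300)
        res = model.fit(seed=8, init=LatentFactors(X=f0.X.copy(), Y=f0.Y.copy()))
        ref = plain_nmf_trace(A, f0.X, f0.Y, n_iter=50, eps=1e-12)
        assert len(res.objective_trace) == len(ref)
        for a, b in zip(res.objective_trace, ref):
            assert abs(a - b) <= 1e-10 * (1 + b)


class TestPredictScores:
    def test_mask_counts_and_nonnegativity(self):
        planted = latent_block_network(12, 14, 2, 0.6, 0.1, seed=9)
        split = split_edges(planted.network, 0.9, seed=1)
        res = SRNMF(split, similarity="cn", k=3, max_iter=30).fit(seed=0)
        sm = predict_scores(res.factors, split)
        assert (sm.A_star >= 0).all()
        assert int(sm.mask.sum()) == 12 * 14 - split.n_train
        # mask is zero exactly on training edges
        assert not sm.mask[split.train.toarray().astype(bool)].any()

    def test_planted_edges_outrank_random_nonedges(self):
        """Held-out links of a rank-1 propensity model score above non-links.

        Link probabilities are an outer product a_i b_j (rank-1 expected
        adjacency with heterogeneous propensities), so held-out edges sit
        in high-propensity cells while never-linked pairs concentrate in
        low-propensity ones.
        """
        from biplink import BipartiteNetwork

        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = rng.choice([0.2, 0.9], size=20)
            b = rng.choice([0.2, 0.9], size=20)
            A = (rng.random((20, 20)) < np.outer(a, b)).astype(float)
            net = BipartiteNetwork([f"v{i}" for i in range(20)],
                                   [f"w{j}" for j in range(20)],
                                   sp.csr_matrix(A))
            split = split_edges(net, 0.8, seed=seed)
            res = SRNMF(split, similarity="cn", k=1, max_iter=100).fit(seed=seed)
            A_star = res.predict()
            probe = split.probe.toarray().astype(bool)
            never = ~A.astype(bool)
            size = min(int(probe.sum()), int(never.sum()))
            if size == 0:
                continue
            sample = rng.choice(int(never.sum()), size=size, replace=False)
            if A_star[probe].mean() > A_star[never][sample].mean():
                wins += 1
        assert wins >= 18
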