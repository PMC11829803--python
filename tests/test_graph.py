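import numpy as np
import pytest
from scipy import sparse
from scipy.spatial.distance import pdist

from ccitraj.graph import (
    FuzzyKNNGraph,
    _calibrate_sigma,
    apply_cci_weights,
    conditional_probabilities,
    joint_probabilities,
    pca_embed,
)


class TestPCA:
    def test_rank_one_matrix_has_single_component(self):
        u = np.arange(10.0)[:, None]
        v = np.ones((1, 5))
        emb = pca_embed(u @ v, n_components=2)
        assert emb.explained_variance[1] <= 1e-8 * emb.explained_variance[0]

    def test_full_rank_embedding_preserves_distances(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 4))
        emb = pca_embed(X, n_components=4)
        assert np.allclose(pdist(emb.coords), pdist(X), atol=1e-8)

    def test_duplicated_cells_map_identically(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 5))
        X = np.vstack([X, X[2]])
        emb = pca_embed(X, n_components=3)
        assert np.allclose(emb.coords[2], emb.coords[-1], atol=1e-8)

    def test_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            emb = pca_embed(np.random.default_rng(2).normal(size=(4, 3)), n_components=10)
        assert emb.coords.shape[1] == 3


class TestConditionalProbabilities:
    def test_nearest_neighbor_has_probability_one(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 3))
        p, rho, sigma = conditional_probabilities(X, k=5)
        assert np.allclose(p.max(axis=1).toarray().ravel(), 1.0, atol=1e-9)

    def test_row_sums_hit_log2k(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 3))
        p, _, _ = conditional_probabilities(X, k=8)
        sums = np.asarray(p.sum(axis=1)).ravel()
        assert np.allclose(sums, np.log2(8), atol=1e-4)

    def test_k2_sigma_matches_scalar_root(self):
        """k = 2 target log2(2) = 1: sigma must push the farther term to ~0."""
        dists = np.array([1.0, 1.5])
        sigma, ok = _calibrate_sigma(dists, rho=1.0, target=1.0)
        total = np.exp(-(dists - 1.0) / sigma).sum()
        assert total == pytest.approx(1.0, abs=1e-5)
        # independent bisection oracle on f(s) = 1 + exp(-0.5/s) - 1
        lo, hi = 1e-12, 10.0
        for _ in range(200):
            mid = (lo + hi) / 2
            if 1 + np.exp(-0.5 / mid) < 1 + 1e-6:
                lo = mid
            else:
                hi = mid
        assert sigma <= hi * 1.1

    def test_equidistant_neighbors_saturate(self):
        # origin sees all 4 simplex vertices at the same distance: its row
        # sum is pinned at k and the sigma search cannot reach log2(k)
        X = np.vstack([np.eye(4), np.zeros(4)]) * 3.0
        with pytest.warns(UserWarning, match="saturated"):
            p, _, _ = conditional_probabilities(X, k=3)
        rows = np.asarray(p.sum(axis=1)).ravel()
        assert rows[4] == pytest.approx(3.0, abs=1e-6)  # all p = 1, retained
        assert np.allclose(rows[:4], np.log2(3), atol=1e-4)

    def test_k_validation(self):
        X = np.random.default_rng(5).normal(size=(10, 2))
        with pytest.raises(ValueError):
            conditional_probabilities(X, k=1)
        with pytest.raises(ValueError):
            conditional_probabilities(X, k=10)


class TestJointProbabilities:
    @pytest.mark.parametrize("a, b, expected", [(0.5, 0.5, 0.75), (1.0, 0.0, 1.0), (0.0, 0.0, 0.0)])
    def test_union_formula(self, a, b, expected):
        p = sparse.csr_matrix(np.array([[0.0, a], [b, 0.0]]))
        j = joint_probabilities(p).toarray()
        assert j[0, 1] == pytest.approx(expected)
        assert j[1, 0] == pytest.approx(expected)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(25, 3))
        p, _, _ = conditional_probabilities(X, k=5)
        j = joint_probabilities(p)
        assert abs(j - j.T).max() == 0
        assert j.min() >= 0 and j.max() <= 1 + 1e-12


class TestCCIWeights:
    def test_additive_formula(self):
        pj = sparse.csr_matrix(np.array([[0.0, 0.3], [0.3, 0.0]]))
        S = sparse.csr_matrix(np.array([[0.0, 0.1], [0.1, 0.0]]))
        ph = apply_cci_weights(pj, S, 2.0)
        assert ph[0, 1] == pytest.approx(0.5)

    def test_k_zero_bypasses_cci(self):
        pj = sparse.random(15, 15, density=0.3, random_state=0)
        pj = pj + pj.T
        S = sparse.random(15, 15, density=0.3, random_state=1)
        S = S + S.T
        assert (apply_cci_weights(pj, S, 0.0) != pj).nnz == 0

    def test_zero_cci_is_identity(self):
        pj = sparse.csr_matrix(np.array([[0.0, 0.4], [0.4, 0.0]]))
        ph = apply_cci_weights(pj, sparse.csr_matrix((2, 2)), 5.0)
        assert (ph != pj).nnz == 0

    def test_restricted_to_support_and_monotone_in_k(self):
        pj = sparse.csr_matrix(np.array([[0.0, 0.3, 0.0], [0.3, 0.0, 0.0], [0.0, 0.0, 0.0]]))
        S = sparse.csr_matrix(np.full((3, 3), 0.5) - 0.5 * np.eye(3))
        ph1 = apply_cci_weights(pj, S, 1.0).toarray()
        ph2 = apply_cci_weights(pj, S, 3.0).toarray()
        assert ph1[0, 2] == 0.0  # no p_joint edge -> no CCI edge
        assert np.all(ph2 >= ph1)

    def test_negative_k_rejected(self):
        pj = sparse.eye(3).tocsr()
        with pytest.raises(ValueError):
            apply_cci_weights(pj, None, -1.0)


class TestEstimator:
    def test_fit_sets_symmetric_graph(self, small_lineage):
        est = FuzzyKNNGraph(n_pcs=20, n_neighbors=8, random_state=0)
        est.fit(small_lineage.matrix.values)
        assert abs(est.p_hat_ - est.p_hat_.T).max() == 0
        assert est.p_hat_.shape == (180, 180)

    def test_reweight_equals_refit(self, small_lineage):
        from ccitraj.cci import symmetrize_cci
        rng = np.random.default_rng(8)
        P = sparse.csr_matrix(rng.uniform(0, 1, size=(180, 180)) * (rng.uniform(size=(180, 180)) < 0.05))
        S = symmetrize_cci(P)
        cold = FuzzyKNNGraph(n_pcs=20, n_neighbors=8, cci_weight=2.0, random_state=0)
        cold.fit(small_lineage.matrix.values, cci=S)
        warm = FuzzyKNNGraph(n_pcs=20, n_neighbors=8, cci_weight=0.0, random_state=0)
        warm.fit(small_lineage.matrix.values, cci=S)
        assert abs(cold.p_hat_ - warm.reweight(2.0)).max() < 1e-12
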