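"""Landmark rate matrix, Kronecker BM likelihood, model selection, Q-mode test."""

import numpy as np
import pytest

import evomorph as em
from evomorph.rates import _constrained_R

from conftest import dense_bm_loglik, pic_contrasts, star_cov


def _random_instance(rng, n=6, k=4, d=3, tree_seed=0):
    tree = em.simulate_tree(n, seed=tree_seed)
    C = em.phylo_cov(tree)
    A = rng.standard_normal((k, k))
    R = A @ A.T + k * np.eye(k)
    L = np.linalg.cholesky(R)
    root = rng.standard_normal((k, d))
    X = root[None, :, :] + np.einsum(
        "ij,jkd->ikd", C.chol, np.einsum("kl,jld->jkd", L, rng.standard_normal((n, k, d)))
    )
    return tree, C, R, X


class TestLandmarkRateMatrix:
    def test_identity_tree_single_landmark_reduction(self, rng):
        # C = I, one landmark, one dimension → (N−1)/N × sample variance
        n = 20
        x = rng.standard_normal((n, 1, 1))
        R = em.landmark_rate_matrix(x, star_cov(n))
        assert R[0, 0] == pytest.approx((n - 1) / n * np.var(x.ravel(), ddof=1))

    def test_duplicated_landmark_rows_identical(self, rng):
        n = 15
        base = rng.standard_normal((n, 1, 3))
        X = np.concatenate([base, base, rng.standard_normal((n, 1, 3))], axis=1)
        R = em.landmark_rate_matrix(X, star_cov(n))
        assert R[0, 0] == pytest.approx(R[1, 1])
        assert R[0, 1] == pytest.approx(R[0, 0])

    def test_diagonal_matches_contrasts_oracle(self, rng):
        tree = em.simulate_tree(6, seed=3)
        C = em.phylo_cov(tree)
        X = rng.standard_normal((6, 3, 2))
        R = em.landmark_rate_matrix(X, C)
        for lm in range(3):
            total = 0.0
            for dim in range(2):
                vals = dict(zip(C.species, X[:, lm, dim]))
                u, _ = pic_contrasts(tree, vals)
                # GLS quadratic form equals the sum of squared standardized
                # contrasts; Eq-style divisor is 1/N
                total += np.sum(u**2)
            assert R[lm, lm] == pytest.approx(total / 6, rel=1e-8)

    def test_block_trace_bookkeeping_against_coordinate_matrix(self, rng):
        # landmark diagonal sums the coordinate-level matrix blocks up to the
        # divisor convention: R_L[i,i] = trace(block ii of Eq-1 R) × (N−1)/N
        tree = em.simulate_tree(10, seed=4)
        C = em.phylo_cov(tree)
        X = rng.standard_normal((10, 4, 3))
        R_L = em.landmark_rate_matrix(X, C)
        R_coord = em.evol_rate_matrix(X.reshape(10, -1), C, divisor="n_minus_1")
        for i in range(4):
            tr = np.trace(R_coord[i * 3 : (i + 1) * 3, i * 3 : (i + 1) * 3])
            assert R_L[i, i] == pytest.approx(tr * 9 / 10, rel=1e-10)


class TestBMLoglik:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dense_mvn_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tree, C, R, X = _random_instance(rng, n=6, k=4, d=3, tree_seed=seed)
        ours = em.bm_loglik(X, C, R)
        # oracle must use the same (GLS) root states
        root = np.stack([em.phylo_mean(X[:, :, dim], C) for dim in range(3)], axis=1)
        oracle = dense_bm_loglik(X, C.matrix, R, root)
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_univariate_closed_form(self, rng):
        tree = em.simulate_tree(8, seed=9)
        C = em.phylo_cov(tree)
        x = rng.standard_normal((8, 1, 1))
        sigma2 = 1.7
        ours = em.bm_loglik(x, C, np.array([[sigma2]]))
        a = em.phylo_mean(x[:, 0, :], C)[0]
        resid = x[:, 0, 0] - a
        quad = resid @ C.solve(resid) / sigma2
        closed = -0.5 * (quad + 8 * np.log(sigma2) + C.logdet() + 8 * np.log(2 * np.pi))
        assert ours == pytest.approx(closed, rel=1e-12)

    def test_scale_identifiability(self, rng):
        tree, C, R, X = _random_instance(rng, n=6, k=3)
        c = 2.5
        C2 = em.PhyloCovariance(C.species, C.matrix / c)
        ll1 = em.bm_loglik(X, C, R)
        ll2 = em.bm_loglik(X, C2, c * R)
        # R⊗C unchanged → identical likelihood
        assert ll1 == pytest.approx(ll2, rel=1e-10)

    def test_centered_data_uses_degenerate_subspace_likelihood(self, rng):
        """Procrustes-centered configurations make the centroid direction a
        null space; the likelihood must match a dense oracle evaluated on the
        Helmert (centroid-free) subspace."""
        from scipy.linalg import helmert
        from scipy.stats import multivariate_normal

        n, k, d = 6, 4, 3
        tree = em.simulate_tree(n, seed=13)
        C = em.phylo_cov(tree)
        X = rng.standard_normal((n, k, d))
        X -= X.mean(axis=1, keepdims=True)  # center each configuration
        A = rng.standard_normal((k, k))
        R = A @ A.T + k * np.eye(k)
        ours = em.bm_loglik(X, C, R)
        U = helmert(k).T
        Rt = U.T @ R @ U
        big = np.kron(Rt, C.matrix)
        dense = 0.0
        for dim in range(d):
            a = em.phylo_mean(X[:, :, dim] @ U, C)
            dense += multivariate_normal.logpdf(
                (X[:, :, dim] @ U).T.ravel(), mean=np.repeat(a, n), cov=big
            )
        assert ours == pytest.approx(dense, abs=1e-8)

    def test_rate_models_finite_and_ordered_on_procrustes_data(self):
        """Model comparison stays sane on aligned (centered) configurations."""
        cfg = em.SimulationConfig(
            n_tips=60, k=10, module_sizes=(5, 5), sigma2_modules=(0.004, 0.001),
            size_rate=0.3, seed=21,
        )
        tree = em.simulate_tree(60, seed=21)
        data = em.simulate_shapes(tree, cfg, seed=21)
        aligned = em.gpa(data.landmarks)
        C = em.phylo_cov(tree)
        fits = {f.model: f for f in em.fit_rate_models(aligned.coords, C, cfg.hypothesis)}
        assert all(np.isfinite(f.loglik) for f in fits.values())
        assert fits["all_rates"].loglik >= fits["per_module_2"].loglik - 1e-6
        assert fits["per_module_2"].loglik >= fits["one_rate"].loglik - 1e-6

    def test_nonsquare_r_rejected(self, rng):
        tree, C, R, X = _random_instance(rng)
        with pytest.raises(ValueError):
            em.bm_loglik(X, C, R[:2, :2])


class TestRateModelSelection:
    def test_nesting_of_plugin_likelihoods(self, rng):
        cfg = em.SimulationConfig(
            n_tips=60, k=8, module_sizes=(4, 4), sigma2_modules=(4.0, 1.0), seed=2
        )
        tree = em.simulate_tree(60, seed=2)
        data = em.simulate_shapes(tree, cfg, seed=2)
        C = em.phylo_cov(tree)
        fits = {f.model: f for f in em.fit_rate_models(data.shapes, C, cfg.hypothesis)}
        assert fits["all_rates"].loglik >= fits["per_module_2"].loglik - 1e-6
        assert fits["per_module_2"].loglik >= fits["one_rate"].loglik - 1e-6

    def test_rate_ratio_recovered(self):
        cfg = em.SimulationConfig(
            n_tips=100, k=12, module_sizes=(6, 6), sigma2_modules=(4.0, 1.0), seed=3
        )
        tree = em.simulate_tree(100, seed=3)
        data = em.simulate_shapes(tree, cfg, seed=3)
        C = em.phylo_cov(tree)
        R_L = em.landmark_rate_matrix(data.shapes, C)
        r1 = np.diag(R_L)[:6].mean()
        r2 = np.diag(R_L)[6:].mean()
        assert max(r1, r2) / min(r1, r2) == pytest.approx(4.0, rel=0.5)

    def test_constrained_matrix_preserves_correlations(self, rng):
        A = rng.standard_normal((5, 5))
        R = A @ A.T + 5 * np.eye(5)
        diag = rng.uniform(0.5, 2.0, 5)
        Rc = _constrained_R(R, diag)
        np.testing.assert_allclose(np.diag(Rc), diag, rtol=1e-12)
        corr = lambda M: M / np.sqrt(np.outer(np.diag(M), np.diag(M)))
        np.testing.assert_allclose(corr(Rc), corr(R), rtol=1e-10)

    def test_missing_hypothesis_means_no_module_model(self, rng):
        tree, C, R, X = _random_instance(rng, n=8, k=4)
        fits = em.fit_rate_models(X, C, hyp=None)
        assert {f.model for f in fits} == {"one_rate", "all_rates"}


class TestQmode:
    def test_single_module_rejected(self, rng):
        tree, C, _, X = _random_instance(rng)
        with pytest.raises(ValueError, match="2 modules"):
            em.qmode_rate_test(X, C, em.ModuleHypothesis("one", np.ones(4, dtype=int)))

    def test_rate_difference_detected(self):
        cfg = em.SimulationConfig(
            n_tips=100, k=12, module_sizes=(6, 6), sigma2_modules=(4.0, 1.0), seed=6
        )
        tree = em.simulate_tree(100, seed=6)
        data = em.simulate_shapes(tree, cfg, seed=6)
        C = em.phylo_cov(tree)
        res = em.qmode_rate_test(data.shapes, C, cfg.hypothesis, n_sim=99, seed=1)
        assert res.ratio > 1.5
        assert res.p_value <= 0.05

    def test_landmark_level_units(self, rng):
        tree, C, _, X = _random_instance(rng, n=10, k=4)
        res = em.qmode_rate_test(X, C, hyp=None, n_sim=49, seed=0)
        assert res.unit == "landmark"
        assert res.rates.size == 4
        assert res.ratio >= 1.0
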