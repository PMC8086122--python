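"""Congruence coefficients, broken-stick counts, constrained Ward clustering."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

import evomorph as em
from evomorph.congruence import _corr_to_dist

from conftest import naive_congruence, star_cov


class TestCongruenceMatrix:
    def test_perfectly_correlated_landmarks(self):
        # landmark 2 = 2 × landmark 1 → proportional positive blocks → r = 1
        rng = np.random.default_rng(0)
        X1 = rng.standard_normal((30, 3))
        X = np.hstack([X1, 2.0 * X1])
        R = em.evol_rate_matrix(X, star_cov(30))
        cm = em.congruence_matrix(R, 3)
        assert cm.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_block_diagonal_independent_landmarks(self):
        R = np.zeros((6, 6))
        R[:3, :3] = np.diag([1.0, 2.0, 3.0])
        R[3:, 3:] = np.diag([2.0, 2.0, 1.0])
        cm = em.congruence_matrix(R, 3)
        assert cm.values[0, 1] == pytest.approx(0.0)
        np.testing.assert_allclose(np.diag(cm.values), 1.0)

    def test_star_tree_equals_dot_product_oracle(self, rng):
        k, d, n = 4, 3, 25
        X = rng.standard_normal((n, k * d))
        R = em.evol_rate_matrix(X, star_cov(n))
        cm = em.congruence_matrix(R, d)
        np.testing.assert_allclose(cm.values, naive_congruence(X, k, d), atol=1e-10)

    def test_zero_variance_landmark_flagged(self):
        R = np.eye(6)
        R[0, 0] = R[1, 1] = R[2, 2] = 0.0  # first landmark, d = 3
        with pytest.warns(UserWarning, match="zero variance"):
            cm = em.congruence_matrix(R, 3)
        assert np.isnan(cm.values[0, 1])
        assert cm.valid_mask().tolist() == [False, True]

    def test_species_relabeling_invariance(self, rng):
        tree = em.simulate_tree(20, seed=2)
        C = em.phylo_cov(tree)
        X = rng.standard_normal((20, 9))
        cm1 = em.congruence_matrix(em.evol_rate_matrix(X, C), 3)
        perm = rng.permutation(20)
        C2 = em.PhyloCovariance(
            [C.species[i] for i in perm], C.matrix[np.ix_(perm, perm)]
        )
        cm2 = em.congruence_matrix(em.evol_rate_matrix(X[perm], C2), 3)
        np.testing.assert_allclose(cm1.values, cm2.values, atol=1e-10)


class TestBrokenStick:
    def test_hand_computed_count(self):
        # k=4, proportions (0.75, 0.125, ...) vs b=(0.5208, 0.2708, ...)
        assert em.broken_stick_modules(np.array([3.0, 0.5, 0.25, 0.25])) == 1

    def test_two_dominant_axes(self):
        evals = np.array([5.1, 3.9] + [0.3] * 10)
        assert em.broken_stick_modules(evals) == 2

    def test_degenerate_equal_eigenvalues_floor_at_one(self):
        with pytest.warns(UserWarning, match="m = 1"):
            assert em.broken_stick_modules(np.ones(5)) == 1

    def test_contiguous_leading_run_only(self):
        # third axis exceeds expectation but second does not → count stops at 1
        k = 4
        inv = 1.0 / np.arange(1, k + 1)
        b = np.cumsum(inv[::-1])[::-1] / k
        props = np.array([0.60, 0.155, 0.155, 0.09])
        assert props[0] > b[0] and props[1] < b[1] and props[2] > b[2]
        assert em.broken_stick_modules(props * 4) == 1

    def test_simulated_two_block_matrix(self, rng):
        hits = 0
        for rep in range(10):
            cfg = em.SimulationConfig(n_tips=64, k=12, seed=rep)
            X = rng.standard_normal((400, 36)) @ np.linalg.cholesky(
                cfg.coordinate_covariance()
            ).T
            R = em.evol_rate_matrix(X, star_cov(400))
            cm = em.congruence_matrix(R, 3)
            if em.broken_stick_modules(cm.eigenvalues()) == 2:
                hits += 1
        assert hits >= 8


class TestConstrainedWard:
    def _setup(self, rng, k=10):
        r = np.clip(rng.uniform(-0.5, 0.9, (k, k)), -0.99, 0.99)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        cm = em.CongruenceMatrix([f"L{i}" for i in range(k)], r)
        coords = rng.standard_normal((k, 3))
        return cm, coords

    def test_alpha_zero_matches_plain_ward_on_congruence(self, rng):
        cm, coords = self._setup(rng)
        det = em.constrained_ward(cm, coords, m=3, alpha=0.0)
        D0 = _corr_to_dist(cm.values)
        Z = linkage(squareform(D0 / D0.max(), checks=False), method="ward")
        ref = fcluster(Z, t=3, criterion="maxclust")
        assert adjusted_rand_score(ref, det.hypothesis.assignment) == pytest.approx(1.0)

    def test_alpha_one_matches_plain_ward_on_geometry(self, rng):
        cm, coords = self._setup(rng)
        det = em.constrained_ward(cm, coords, m=3, alpha=1.0)
        diff = coords[:, None, :] - coords[None, :, :]
        D1 = np.sqrt((diff**2).sum(-1))
        Z = linkage(squareform(D1 / D1.max(), checks=False), method="ward")
        ref = fcluster(Z, t=3, criterion="maxclust")
        assert adjusted_rand_score(ref, det.hypothesis.assignment) == pytest.approx(1.0)

    def test_landmark_order_invariance(self, rng):
        cm, coords = self._setup(rng, k=8)
        det = em.constrained_ward(cm, coords, m=3, alpha=0.5)
        perm = rng.permutation(8)
        cm2 = em.CongruenceMatrix(
            [cm.labels[i] for i in perm], cm.values[np.ix_(perm, perm)]
        )
        det2 = em.constrained_ward(cm2, coords[perm], m=3, alpha=0.5)
        assert (
            adjusted_rand_score(det.hypothesis.assignment[perm], det2.hypothesis.assignment)
            == pytest.approx(1.0)
        )

    def test_deterministic_under_exact_ties(self):
        # four identical landmarks: every merge cost ties; result must be stable
        r = np.full((4, 4), 0.5)
        np.fill_diagonal(r, 1.0)
        cm = em.CongruenceMatrix(list("abcd"), r)
        coords = np.zeros((4, 3))
        a = em.constrained_ward(cm, coords, m=2, alpha=0.5).hypothesis.assignment
        b = em.constrained_ward(cm, coords, m=2, alpha=0.5).hypothesis.assignment
        np.testing.assert_array_equal(a, b)
        # lowest-index pair (a,b) merges first, then the remaining singletons
        # (Ward prefers the cheaper singleton pair over growing a cluster)
        np.testing.assert_array_equal(a, [1, 1, 2, 2])

    def test_parameter_validation(self, rng):
        cm, coords = self._setup(rng, k=5)
        with pytest.raises(ValueError):
            em.constrained_ward(cm, coords, m=3, alpha=1.5)
        with pytest.raises(ValueError):
            em.constrained_ward(cm, coords, m=6, alpha=0.5)


class TestChoiceAlpha:
    def test_identical_matrices_give_coincident_curves(self, rng):
        D = np.abs(rng.standard_normal((8, 8)))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        table = em.choice_alpha(D, D.copy(), alphas=[0.0, 0.5, 1.0], m=3)
        np.testing.assert_allclose(table["explained_D0"], table["explained_D1"], atol=1e-12)

    def test_tradeoff_between_conflicting_structures(self, rng):
        # D0 groups {0..3}/{4..7}; D1 groups evens/odds
        n = 8
        g0 = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        g1 = np.arange(n) % 2
        D0 = np.where(g0[:, None] == g0[None, :], 0.1, 1.0)
        D1 = np.where(g1[:, None] == g1[None, :], 0.1, 1.0)
        np.fill_diagonal(D0, 0)
        np.fill_diagonal(D1, 0)
        table = em.choice_alpha(D0, D1, alphas=[0.0, 0.25, 0.5, 0.75, 1.0], m=2)
        assert table["explained_D0"].iloc[0] >= table["explained_D0"].iloc[-1]
        assert table["explained_D1"].iloc[-1] >= table["explained_D1"].iloc[0]

    def test_two_block_simulation_alpha_half_loses_little(self):
        cfg = em.SimulationConfig(n_tips=64, k=12, seed=11)
        tree = em.simulate_tree(64, seed=11)
        data = em.simulate_shapes(tree, cfg, seed=11)
        C = em.phylo_cov(tree)
        R = em.evol_rate_matrix(data.shapes.reshape(64, -1), C)
        cm = em.congruence_matrix(R, 3)
        D0 = _corr_to_dist(cm.values)
        G = data.truth["mean_configuration"]
        diff = G[:, None, :] - G[None, :, :]
        D1 = np.sqrt((diff**2).sum(-1))
        table = em.choice_alpha(D0, D1, alphas=[0.0, 0.5], m=2)
        loss = table["explained_D0"].iloc[0] - table["explained_D0"].iloc[1]
        assert loss < 0.10


class TestDetectModules:
    def test_full_detection_recovers_planted_modules(self):
        cfg = em.SimulationConfig(n_tips=64, k=12, seed=5)
        tree = em.simulate_tree(64, seed=5)
        data = em.simulate_shapes(tree, cfg, seed=5)
        C = em.phylo_cov(tree)
        R = em.evol_rate_matrix(data.shapes.reshape(64, -1), C)
        cm = em.congruence_matrix(R, 3)
        det = em.detect_modules(cm, data.truth["mean_configuration"], alpha=0.5)
        assert det.n_modules == 2
        truth = data.truth["hypothesis"].assignment
        assert adjusted_rand_score(truth, det.hypothesis.assignment) == pytest.approx(1.0)
        # eigenvalues of a unit-diagonal matrix sum to k
        assert det.eigenvalues.sum() == pytest.approx(12.0)
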