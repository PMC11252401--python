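import numpy as np
import pytest
from scipy.stats import kstest, spearmanr

from hippogradients.matching import (
    best_map_combination,
    dice_at_quantile,
    lasso_select,
    ols_fit,
    quantile_gaussianize,
    spin_test,
)
from hippogradients.synth import make_cortex


class TestQuantileGaussianize:
    def test_preserves_order(self, rng):
        x = np.sort(rng.standard_normal(50))
        y = quantile_gaussianize(x)
        assert spearmanr(x, y).statistic == pytest.approx(1.0)
        assert (np.diff(y) > 0).all()

    def test_output_close_to_normal_at_large_n(self, rng):
        x = rng.exponential(size=10_000)  # heavily skewed input
        y = quantile_gaussianize(x)
        d = kstest(y, "norm").statistic
        assert d < 0.02

    def test_idempotent(self, rng):
        x = rng.standard_normal(200)
        once = quantile_gaussianize(x)
        twice = quantile_gaussianize(once)
        assert np.allclose(once, twice, atol=1e-12)

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError):
            quantile_gaussianize(np.ones(10))


class TestLassoSelect:
    def test_exact_candidate_selected_alone(self, rng):
        n = 500
        X = np.linalg.qr(rng.standard_normal((n, 10)))[0]  # orthogonal candidates
        target = X[:, 3].copy()
        coefs = lasso_select(target, [X[:, i] for i in range(10)])
        nz = np.flatnonzero(np.abs(coefs) > 1e-10)
        assert list(nz) == [3]

    def test_pure_noise_target_gives_all_zero(self, rng):
        n = 1000
        X = rng.standard_normal((n, 10))
        target = rng.standard_normal(n)
        coefs = lasso_select(target, [X[:, i] for i in range(10)])
        assert np.abs(coefs).max() == 0.0

    def test_vanishing_penalty_recovers_ols(self, rng):
        n = 300
        X = rng.standard_normal((n, 4))
        target = X @ np.array([0.5, -0.2, 0.0, 0.8]) + 0.1 * rng.standard_normal(n)
        coefs = lasso_select(target, [X[:, i] for i in range(4)], penalty=1e-8)
        # closed-form OLS on the standardized variables
        Xs = (X - X.mean(0)) / X.std(0)
        ys = (target - target.mean()) / target.std()
        beta = np.linalg.lstsq(
            np.column_stack([Xs, np.ones(n)]), ys, rcond=None
        )[0][:4]
        assert np.abs(coefs - beta).max() < 1e-4

    def test_coefficients_shrink_with_penalty(self, rng):
        n = 400
        X = rng.standard_normal((n, 5))
        target = X @ np.array([1.0, 0.5, 0.3, -0.4, 0.2]) + rng.standard_normal(n)
        norms = [
            np.abs(lasso_select(target, [X[:, i] for i in range(5)], penalty=p)).sum()
            for p in (0.01, 0.1, 0.3, 0.6)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))


class TestOlsFit:
    def test_exact_linear_relation(self, rng):
        x = rng.standard_normal(100)
        beta, r2 = ols_fit(2 * x + 1, x)
        assert beta == pytest.approx(2.0)
        assert r2 == pytest.approx(1.0)
        beta, r2 = ols_fit(-x, x)
        assert beta == pytest.approx(-1.0)
        assert r2 == pytest.approx(1.0)

    def test_independent_maps_have_tiny_r2(self, rng):
        x = rng.standard_normal(100_000)
        y = rng.standard_normal(100_000)
        _, r2 = ols_fit(y, x)
        assert r2 < 0.001

    def test_constant_candidate_rejected(self, rng):
        with pytest.raises(ValueError):
            ols_fit(rng.standard_normal(10), np.ones(10))


@pytest.fixture(scope="module")
def sphere():
    return make_cortex(150, 5, "H", 0).sphere_coords


class TestSpinTest:
    def test_self_match_is_significant(self, sphere, rng):
        # a smooth non-constant map correlates perfectly with itself but
        # imperfectly with any rotated copy
        cos = np.clip(sphere @ sphere.T, -1, 1)
        K = np.exp(-np.arccos(cos) ** 2 / (2 * 0.3**2))
        m = K @ rng.standard_normal(150)
        p = spin_test(m, m, sphere, n_perm=1000, seed=1)
        assert p <= 0.05

    def test_counting_formula_smallest_possible_p(self, sphere, rng):
        m = sphere[:, 2]  # perfectly smooth latitude map
        p = spin_test(m, m, sphere, n_perm=19, seed=2)
        assert p == pytest.approx(1 / 20)

    def test_degenerate_coordinates_rejected(self, rng):
        coords = np.tile([0.0, 0.0, 1.0], (10, 1))
        with pytest.raises(ValueError):
            spin_test(rng.standard_normal(10), rng.standard_normal(10), coords, 10, 0)


class TestDice:
    def test_identical_maps_give_one(self, rng):
        a = rng.standard_normal(40)
        assert dice_at_quantile(a, a, 0.7) == 1.0

    def test_disjoint_supports_give_zero(self):
        a = np.r_[np.ones(5), np.zeros(5)]
        b = np.r_[np.zeros(5), np.ones(5)]
        assert dice_at_quantile(a, b, 0.5) == 0.0

    def test_hand_enumerated_example(self):
        assert dice_at_quantile([1, 2, 3, 4], [4, 3, 2, 1], 0.5) == 0.0

    def test_symmetric(self, rng):
        for _ in range(10):
            a, b = rng.standard_normal((2, 30))
            assert dice_at_quantile(a, b, 0.75) == dice_at_quantile(b, a, 0.75)


class TestBestMapCombination:
    def test_target_equal_to_candidate_wins_everywhere(self, rng):
        c1 = rng.standard_normal(60)
        c2 = rng.standard_normal(60)
        rep = best_map_combination(c1, [c1.copy(), c2])
        assert rep.best_set == (0,)
        assert rep.best_dice == 1.0
        for q in (0.7, 0.75, 0.8, 0.85, 0.9, 0.95):
            assert rep.dice_table[((0,), q)] == 1.0

    def test_union_structured_target_prefers_the_pair(self, rng):
        n = 300
        cands = [np.zeros(n) for _ in range(4)]
        blocks = [slice(0, 75), slice(75, 150), slice(150, 225), slice(225, 300)]
        for c, b in zip(cands, blocks):
            c[b] = 1.0 + rng.random(75)
        target = np.zeros(n)
        target[blocks[1]] = 1.0 + rng.random(75)
        target[blocks[2]] = 1.0 + rng.random(75)
        rep = best_map_combination(target, cands, q_grid=(0.75,))
        assert set(rep.best_set) == {1, 2}
        pair_dice = rep.dice_table[((1, 2), 0.75)]
        for i in range(4):
            assert pair_dice > rep.dice_table[((i,), 0.75)]

    def test_exhaustive_enumeration_matches_brute_force(self, rng):
        import itertools

        target = rng.standard_normal(50)
        cands = [rng.standard_normal(50) for _ in range(4)]
        rep = best_map_combination(target, cands, q_grid=(0.7, 0.8))
        for q in (0.7, 0.8):
            tm = target > np.quantile(target, q)
            masks = [c > np.quantile(c, q) for c in cands]
            for size in (1, 2, 3):
                for sub in itertools.combinations(range(4), size):
                    u = np.logical_or.reduce([masks[i] for i in sub])
                    expect = 2 * (tm & u).sum() / (tm.sum() + u.sum())
                    assert rep.dice_table[(sub, q)] == pytest.approx(expect)
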