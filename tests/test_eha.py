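import numpy as np
import pytest

from tumorherd.eha import (EHAParams, cartesian_distance_scores, clan_update,
                           eha_optimize, matriarch_update, replace_worst,
                           select_at, select_features)


class _FixedRng:
    """Stand-in RNG whose uniform() returns queued values."""

    def __init__(self, *draws):
        self.draws = list(draws)

    def uniform(self, low=0.0, high=1.0, size=None):
        v = self.draws.pop(0)
        return np.full(size, v) if size is not None else v


LO, HI = np.zeros(2), np.ones(2)


class TestUpdateRules:
    def test_zero_attraction_is_identity(self):
        x = np.array([0.3, 0.7])
        out = clan_update(x, np.array([0.9, 0.1]), _FixedRng(0.0, 0.8), LO, HI)
        np.testing.assert_array_equal(out, x)

    def test_matriarch_position_is_fixed_point(self):
        x = np.array([0.4, 0.6])
        out = clan_update(x, x, _FixedRng(0.7, 0.2), LO, HI)
        np.testing.assert_allclose(out, x)

    def test_direct_substitution(self):
        out = clan_update(np.zeros(2), np.ones(2), _FixedRng(0.5, 1.0), LO, HI)
        np.testing.assert_allclose(out, [0.5, 0.5])

    def test_matriarch_moves_to_scaled_centroid(self):
        clan = np.array([[0.0, 0.0], [2.0, 2.0]])
        np.testing.assert_allclose(
            matriarch_update(clan, 1.0, np.zeros(2), 2 * np.ones(2)), [1.0, 1.0])
        np.testing.assert_allclose(
            matriarch_update(np.array([[2.0, 2.0]]), 0.5, np.zeros(2), 2 * np.ones(2)),
            [1.0, 1.0])
        np.testing.assert_allclose(
            matriarch_update(np.array([[0.3, 0.9]]), 1.0, LO, HI), [0.3, 0.9])
        with pytest.raises(ValueError):
            matriarch_update(np.empty((0, 2)), 0.5, LO, HI)

    def test_replacement_formula_and_clamping(self):
        np.testing.assert_allclose(replace_worst(LO, HI, _FixedRng(0.0)), LO)
        np.testing.assert_allclose(replace_worst(LO, HI, _FixedRng(0.25)), [0.5, 0.5])
        # rand=1 overshoots to 2 and clamps to the upper bound
        np.testing.assert_allclose(replace_worst(LO, HI, _FixedRng(1.0)), HI)


class TestOptimizer:
    def test_constant_objective(self):
        p = EHAParams(max_iter=20, seed=0)
        res = eha_optimize(lambda x: 3.25, p)
        assert res.best_value == 3.25
        assert np.all(res.trace == 3.25)

    def test_trace_monotone_and_bounds_respected(self):
        seen = []
        p = EHAParams(bounds=(-5.0, 5.0), max_iter=100, seed=1)
        def obj(x):
            seen.append(x.copy())
            return -np.sum(x * x)
        res = eha_optimize(obj, p)
        assert np.all(np.diff(res.trace) >= 0)
        seen = np.array(seen)
        assert seen.min() >= -5.0 and seen.max() <= 5.0
        assert res.n_evaluations == len(seen)

    def test_seeded_determinism(self):
        p = EHAParams(bounds=(-5.0, 5.0), max_iter=50, seed=9)
        r1 = eha_optimize(lambda x: -np.sum(x * x), p)
        r2 = eha_optimize(lambda x: -np.sum(x * x), p)
        np.testing.assert_array_equal(r1.trace, r2.trace)
        np.testing.assert_array_equal(r1.best_position, r2.best_position)

    def test_sphere_convergence_short_run(self):
        hits = 0
        for seed in range(3):
            p = EHAParams(bounds=(-5.0, 5.0), max_iter=300, seed=seed)
            res = eha_optimize(lambda x: -np.sum(x * x), p)
            hits += res.best_value >= -0.05
        assert hits >= 2

    def test_non_finite_objective_rejected(self):
        p = EHAParams(max_iter=5, seed=0)
        with pytest.raises(ValueError):
            eha_optimize(lambda x: np.nan, p)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            EHAParams(n_members=31, n_clans=5)
        with pytest.raises(ValueError):
            EHAParams(beta=0.0)
        with pytest.raises(ValueError):
            EHAParams(bounds=(1.0, 1.0))


class TestCdScores:
    def test_constant_feature_scores_zero(self, rng):
        X = np.c_[np.full(40, 2.0), rng.standard_normal(40)]
        y = np.r_[np.ones(20, int), 2 * np.ones(20, int)]
        scores = cartesian_distance_scores(X, y)
        assert scores[0] == 0.0

    def test_balanced_indicator_scores_two(self):
        y = np.r_[np.ones(30, int), 2 * np.ones(30, int)]
        X = (y == 2).astype(float)[:, None]
        assert cartesian_distance_scores(X, y)[0] == pytest.approx(2.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cartesian_distance_scores(np.zeros((10, 2)), np.ones(10))

    def test_monte_carlo_shift_recovery(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = 500
            x = np.r_[rng.standard_normal(n), rng.standard_normal(n) + 1.0]
            y = np.r_[np.ones(n, int), 2 * np.ones(n, int)]
            # pooled z-scoring shrinks a unit within-class shift by
            # sqrt(1 + 1/4); the population value is 1/sqrt(1.25)
            target = 1.0 / np.sqrt(1.25)
            score = cartesian_distance_scores(x[:, None], y)[0]
            hits += abs(score - target) < 0.15
        assert hits >= 47


def _planted(seed, n=300, n_feat=100, shift=2.0, n_inf=5):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((2 * n, n_feat))
    y = np.r_[np.ones(n, int), 2 * np.ones(n, int)]
    X[y == 2, :n_inf] += shift
    return X, y


class TestSelection:
    def test_recovers_planted_features_single_run(self):
        X, y = _planted(0)
        res = select_features(X, y, EHAParams(max_iter=300, seed=0))
        planted = np.sum(res.selected_indices < 5)
        noise = np.sum(res.selected_indices >= 5)
        assert planted >= 4 and noise <= 10

    def test_pure_noise_falls_back_to_nonempty(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((60, 20))
        y = np.r_[np.ones(30, int), 2 * np.ones(30, int)]
        res = select_features(X, y, EHAParams(max_iter=100, seed=1))
        assert res.selected_indices.size >= 1
        assert res.fitness < 1.0

    def test_duplicate_column_pruned_below_rho_one(self):
        X, y = _planted(2, n_feat=20, n_inf=1)
        X = np.c_[X[:, :1], X]  # duplicate the informative column
        kept = select_at(X, y, q=0.5, rho=0.99)
        assert np.sum(np.isin(kept, [0, 1])) == 1

    def test_selection_scores_respect_quantile(self):
        X, y = _planted(3)
        res = select_features(X, y, EHAParams(max_iter=200, seed=3))
        thr = np.quantile(res.cd_scores, res.threshold_quantile)
        assert np.all(res.cd_scores[res.selected_indices] >= thr)
        assert res.selected_indices.size <= X.shape[1]

    def test_full_selection_is_fixed_point_at_permissive_settings(self):
        X, y = _planted(4, n_feat=30)
        kept = select_at(X, y, q=0.0, rho=1.0)
        assert kept.size == 30
        again = select_at(X[:, kept], y, q=0.0, rho=1.0)
        np.testing.assert_array_equal(again, np.arange(30))
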