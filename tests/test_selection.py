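"""FPcRF selector: Lévy steps, pollination moves, wrapper fitness,
regula falsi, threshold refinement, and the full loop."""

import numpy as np
import pytest
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from mammocad import (
    FeatureFixtureSpec,
    FeatureMatrix,
    FPcRFConfig,
    binarize,
    fitness,
    fpcrf_select,
    global_pollination,
    knn_cv_error,
    levy_step,
    local_pollination,
    make_features,
    refine_threshold,
    regula_falsi,
)
from mammocad.selection import BracketError


class TestLevyStep:
    def test_seeded_sequence_repeats(self):
        a = levy_step(1.5, 100, np.random.default_rng(0))
        b = levy_step(1.5, 100, np.random.default_rng(0))
        np.testing.assert_array_equal(a, b)

    def test_zero_count_gives_empty(self, rng):
        assert levy_step(1.5, 0, rng).size == 0

    @pytest.mark.parametrize("lam", [0.5, 1.0, 3.0, 3.5])
    def test_exponent_out_of_range_rejected(self, lam, rng):
        with pytest.raises(ValueError):
            levy_step(lam, 10, rng)

    def test_heavy_tail_index_near_target(self):
        s = np.abs(levy_step(1.5, 100_000, np.random.default_rng(7)))
        x = np.sort(s)[::-1]
        k = 1000
        hill = 1.0 / np.mean(np.log(x[:k] / x[k]))
        assert 1.2 <= hill <= 1.8


class TestPollinationMoves:
    def test_global_at_best_is_fixed_point(self, rng):
        y = rng.uniform(size=8)
        np.testing.assert_array_equal(global_pollination(y, y, 0.1, 1.5, rng), y)

    def test_global_zero_scaling_is_identity(self, rng):
        y, best = rng.uniform(size=8), rng.uniform(size=8)
        np.testing.assert_array_equal(global_pollination(y, best, 0.0, 1.5, rng), y)

    def test_global_stays_in_unit_cube(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            y, best = rng.uniform(size=50), rng.uniform(size=50)
            out = global_pollination(y, best, 1.0, 1.5, rng)
            assert out.min() >= 0.0 and out.max() <= 1.0

    def test_canonical_orientation_flips_displacement(self):
        y = np.full(4, 0.5)
        best = np.full(4, 0.25)
        a = global_pollination(y, best, 0.5, 1.5, np.random.default_rng(1))
        b = global_pollination(y, best, 0.5, 1.5, np.random.default_rng(1), canonical=True)
        np.testing.assert_allclose(a - y, -(b - y), atol=1e-12)

    def test_local_identical_partners_is_fixed_point(self, rng):
        y, z = rng.uniform(size=6), rng.uniform(size=6)
        np.testing.assert_array_equal(local_pollination(y, z, z, rng), y)

    def test_local_with_unit_mixing_coefficient(self):
        class UnitRng:
            def uniform(self):
                return 1.0

        y = np.zeros(4)
        y_z = np.full(4, 0.3)
        y_k = np.zeros(4)
        np.testing.assert_allclose(local_pollination(y, y_z, y_k, UnitRng()), 0.3)

    def test_local_stays_in_unit_cube(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            y, z, k = (rng.uniform(size=20) for _ in range(3))
            out = local_pollination(y, 2 * z, -k, rng)  # exaggerated displacement
            assert out.min() >= 0.0 and out.max() <= 1.0


class TestBinarize:
    def test_threshold_at_half(self):
        np.testing.assert_array_equal(
            binarize(np.array([0.2, 0.8]), 0.5), [False, True]
        )

    def test_empty_mask_forces_argmax(self):
        mask = binarize(np.array([0.1, 0.3, 0.3, 0.2]), 0.5)
        np.testing.assert_array_equal(mask, [False, True, False, False])

    def test_never_empty(self, rng):
        for _ in range(50):
            assert binarize(rng.uniform(size=10), 0.99).sum() >= 1


class TestWrapperFitness:
    def test_separable_clouds_zero_error(self, separable_matrix):
        mask = np.array([True, False])
        cfg = FPcRFConfig(seed=0)
        assert fitness(mask, separable_matrix, cfg) == 0.0

    def test_permuted_labels_near_chance(self, separable_matrix):
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            shuffled = FeatureMatrix(
                separable_matrix.values, rng.permutation(separable_matrix.labels)
            )
            errs.append(knn_cv_error(shuffled.values[:, :1], shuffled.labels, 5, seed))
        assert abs(np.mean(errs) - 0.5) < 0.15

    def test_single_class_rejected(self, rng):
        X = FeatureMatrix(rng.standard_normal((10, 3)), ["only"] * 10)
        with pytest.raises(ValueError):
            fitness(np.ones(3, bool), X, FPcRFConfig())

    def test_empty_mask_rejected(self, small_feature_matrix):
        with pytest.raises(ValueError):
            fitness(np.zeros(6, bool), small_feature_matrix, FPcRFConfig())

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_sklearn_knn_oracle(self, seed):
        """Vectorized leave-fold-out 1-NN equals per-fold sklearn fits."""
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((40, 4))
        y = np.array(["a", "b"] * 20)
        folds, fseed = 5, seed
        mine = knn_cv_error(X, y, folds=folds, seed=fseed)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=fseed)
        wrong = 0
        for train, test in skf.split(X, y):
            clf = KNeighborsClassifier(n_neighbors=1).fit(X[train], y[train])
            wrong += int(np.sum(clf.predict(X[test]) != y[test]))
        assert mine == pytest.approx(wrong / len(y))


class TestRegulaFalsi:
    def test_linear_function_exact_in_one_step(self):
        root, hist = regula_falsi(lambda x: x - 3.0, 0.0, 10.0, return_history=True)
        assert root == pytest.approx(3.0, abs=1e-15)
        assert len(hist) == 1

    def test_quadratic_matches_bisection_oracle(self):
        f = lambda x: x * x - 4.0

        def bisect(f, lo, hi, tol=1e-12):
            flo = f(lo)
            for _ in range(200):
                mid = (lo + hi) / 2
                fm = f(mid)
                if fm == 0 or hi - lo < tol:
                    return mid
                if flo * fm < 0:
                    hi = mid
                else:
                    lo, flo = mid, fm
            return (lo + hi) / 2

        root = regula_falsi(f, 0.0, 4.0, tol=1e-10, max_iter=200)
        assert abs(root - bisect(f, 0.0, 4.0)) < 1e-8
        assert abs(root - 2.0) < 1e-8

    def test_sign_constant_bracket_rejected(self):
        with pytest.raises(BracketError):
            regula_falsi(lambda x: x * x + 1.0, 0.0, 4.0)

    @pytest.mark.parametrize(
        "f,lo,hi,true_root",
        [
            (np.tanh, -1.0, 2.0, 0.0),
            (lambda x: np.exp(x) - 2.0, 0.0, 2.0, np.log(2.0)),
            (lambda x: x**3 - 1.0, 0.0, 3.0, 1.0),
        ],
    )
    def test_root_within_bracket_and_accurate(self, f, lo, hi, true_root):
        root = regula_falsi(f, lo, hi, tol=1e-12, max_iter=500)
        assert lo <= root <= hi
        assert abs(root - true_root) < 1e-8


class TestRefineThreshold:
    def test_constant_best_vector_degenerates_to_tau0(self, small_feature_matrix):
        cfg = FPcRFConfig(folds=2, seed=0)
        best = np.full(6, 0.7)
        vn, mask, bracket, iterates = refine_threshold(best, small_feature_matrix, cfg)
        assert vn == cfg.tau0
        np.testing.assert_array_equal(mask, binarize(best, cfg.tau0))
        assert iterates == []

    def test_planted_gap_selects_exactly_the_high_block(self, planted_small):
        X, planted = planted_small
        cfg = FPcRFConfig(folds=5, seed=0)
        best = np.full(X.n_features, 0.05)
        best[planted] = 0.95
        vn, mask, _, _ = refine_threshold(best, X, cfg)
        np.testing.assert_array_equal(np.flatnonzero(mask), planted)

    def test_never_degrades_fitness(self, rng, planted_small):
        X, _ = planted_small
        cfg = FPcRFConfig(folds=3, seed=1)
        for _ in range(5):
            best = rng.uniform(size=X.n_features)
            base = fitness(binarize(best, cfg.tau0), X, cfg)
            _, mask, _, _ = refine_threshold(best, X, cfg)
            assert fitness(mask, X, cfg) <= base


class TestFpcrfSelect:
    def test_bit_identical_reruns(self, planted_small):
        X, _ = planted_small
        cfg = FPcRFConfig(n_pollens=4, max_iter=3, folds=3, seed=5)
        a = fpcrf_select(X, cfg)
        b = fpcrf_select(X, cfg)
        np.testing.assert_array_equal(a.mask, b.mask)
        np.testing.assert_array_equal(a.fitness_trace, b.fitness_trace)
        assert a.threshold == b.threshold
        assert a.to_dict() == b.to_dict()

    def test_trace_non_increasing_and_mask_non_empty(self, planted_small):
        X, _ = planted_small
        for seed in range(3):
            res = fpcrf_select(X, FPcRFConfig(n_pollens=6, max_iter=10, folds=3, seed=seed))
            assert np.all(np.diff(res.fitness_trace) <= 0)
            assert res.mask.sum() >= 1
            assert res.final_fitness <= res.baseline_fitness

    def test_recovers_planted_columns_on_easy_problem(self):
        spec = FeatureFixtureSpec(
            n_per_class=40, d_informative=3, d_noise=12, effect_size=3.0, seed=2
        )
        X, planted = make_features(spec)
        res = fpcrf_select(X, FPcRFConfig(n_pollens=10, max_iter=15, folds=5, seed=2))
        assert set(planted) <= set(res.selected_indices)

    def test_single_feature_matrix_rejected(self, rng):
        X = FeatureMatrix(rng.standard_normal((10, 1)), ["a", "b"] * 5)
        with pytest.raises(ValueError):
            fpcrf_select(X, FPcRFConfig())
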