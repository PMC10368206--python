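import numpy as np
import pandas as pd
import pytest

from tpsd import decoding


def _xor_free_data(rng, n=60, informative=True):
    """Balanced binary labels with one (optionally) informative feature."""
    y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
    X = rng.random((3, n, 1))
    if informative:
        X[:, :, 0] += 2.0 * y[None, :]
    return X, y


class TestBinning:
    def test_bin_count_convention(self):
        assert decoding.n_decoding_bins(2.0, 0.067) == 29  # floor, partial dropped
        assert decoding.n_decoding_bins(2.0) == 30  # 1/15 s frames map 1:1

    def test_empty_licks_zero_features(self):
        licks = pd.DataFrame({"trial_id": [], "time": []})
        X = decoding.bin_licks(licks, [0, 1], horizon=1.0)
        assert X.shape == (15, 2, 1) and not X.any()

    def test_lick_counts_per_bin(self):
        licks = pd.DataFrame({"trial_id": [0, 0, 1], "time": [0.01, 0.02, 0.5]})
        X = decoding.bin_licks(licks, [0, 1], horizon=1.0)
        assert X[0, 0, 0] == 2.0
        assert X[decoding.n_decoding_bins(0.5), 1, 0] == 1.0

    def test_raster_bins_map_one_to_one(self, learned_bundle):
        F = decoding.raster_features(learned_bundle.raster)
        r = learned_bundle.raster
        assert F.shape == (r.n_bins, r.n_trials, r.n_cells)
        assert np.array_equal(F[3, :, 5], r.activity[5, 3, :])


class TestBootstrapCurve:
    def test_perfect_separation(self, rng):
        X, y = _xor_free_data(rng)
        curve = decoding.bootstrap_svm_curve(X, y, n_machines=40, seed=0)
        assert (curve.mean >= 0.95).all()

    def test_uninformative_near_chance(self, rng):
        # pure-noise features: the RBF SVM overfits the training split and
        # lands slightly below chance, but never decodes
        X, y = _xor_free_data(rng, informative=False)
        curve = decoding.bootstrap_svm_curve(X, y, n_machines=60, seed=0)
        assert np.all(np.abs(curve.mean - 0.5) <= 0.1)

    def test_single_class_rejected(self, rng):
        X, _ = _xor_free_data(rng)
        with pytest.raises(ValueError):
            decoding.bootstrap_svm_curve(X, np.ones(60, dtype=int), n_machines=2)

    def test_constant_features_record_chance(self):
        X = np.zeros((2, 20, 1))
        y = np.r_[np.ones(10), np.zeros(10)].astype(int)
        curve = decoding.bootstrap_svm_curve(X, y, n_machines=5, seed=0)
        assert (curve.accuracies == 0.5).all()

    def test_seed_reproducibility(self, rng):
        X, y = _xor_free_data(rng)
        a = decoding.bootstrap_svm_curve(X, y, n_machines=3, seed=7)
        b = decoding.bootstrap_svm_curve(X, y, n_machines=3, seed=7)
        assert np.array_equal(a.accuracies, b.accuracies)

    def test_mean_stable_in_n_machines(self, rng):
        X, y = _xor_free_data(rng)
        X[:, :, 0] += rng.normal(0, 2.0, size=X.shape[:2])  # partial overlap
        small = decoding.bootstrap_svm_curve(X, y, n_machines=100, seed=1)
        large = decoding.bootstrap_svm_curve(X, y, n_machines=400, seed=2)
        se = small.accuracies.std(axis=1, ddof=1) / np.sqrt(100)
        assert np.all(np.abs(small.mean - large.mean) < 4 * se + 0.01)

    def test_scale_invariance_with_median_heuristic(self, rng):
        X, y = _xor_free_data(rng)
        a = decoding.bootstrap_svm_curve(X, y, n_machines=20, seed=3)
        b = decoding.bootstrap_svm_curve(X * 7.0, y, n_machines=20, seed=3)
        assert np.allclose(a.mean, b.mean, atol=0.02)


class TestShuffledControl:
    def test_separable_input_at_chance(self, rng):
        X, y = _xor_free_data(rng)
        ctrl = decoding.shuffled_control(X, y, n_machines=100, seed=0)
        se = ctrl.accuracies.std(axis=1, ddof=1) / np.sqrt(100)
        assert np.all(np.abs(ctrl.mean - 0.5) <= 3 * se)

    def test_band_covers_chance(self, rng):
        X, y = _xor_free_data(rng, n=100)
        ctrl = decoding.shuffled_control(X, y, n_machines=100, seed=1)
        lo, hi = ctrl.band()
        assert np.mean((lo <= 0.5) & (0.5 <= hi)) >= 0.9

    def test_empty_features_rejected(self):
        with pytest.raises(ValueError):
            decoding.shuffled_control(np.empty((0, 0, 0)), np.array([0, 1]), 2)


class TestTuning:
    def test_budget_one_returns_defaults(self, rng):
        X, y = _xor_free_data(rng)
        params = decoding.tune_hyperparameters(X[0], y, budget=1, seed=0)
        assert params["C"] == 1.0

    def test_noise_cv_at_chance(self, rng):
        X = rng.random((40, 3))
        y = np.r_[np.ones(20), np.zeros(20)].astype(int)
        params = decoding.tune_hyperparameters(X, y, budget=8, seed=0)
        assert abs(params["cv_accuracy"] - 0.5) <= 3 * 0.5 / np.sqrt(40) + 0.1

    def test_tuned_not_worse_than_default(self, rng):
        X, y = _xor_free_data(rng)
        default = decoding.tune_hyperparameters(X[0], y, budget=1, seed=0)
        tuned = decoding.tune_hyperparameters(X[0], y, budget=10, seed=0)
        assert tuned["cv_accuracy"] >= default["cv_accuracy"] - 0.02

    def test_insufficient_data_falls_back(self):
        X = np.random.default_rng(0).random((6, 2))
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.warns(UserWarning):
            params = decoding.tune_hyperparameters(X, y, folds=5, seed=0)
        assert params["C"] == 1.0


class TestForwardSelection:
    def test_k_equals_n_cells_selects_all(self, rng):
        n = 24
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
        X = rng.random((2, n, 4))
        curve, smap = decoding.kcell_selection_curve(X, y, k=4, n_machines=10, seed=0)
        # forced selection: each cell fills exactly 1/4 of the slots
        assert np.allclose(smap.fractions, 0.25)

    def test_single_informative_cell_dominates(self, rng):
        n = 60
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
        X = rng.random((2, n, 6))
        X[:, :, 3] += 3.0 * y[None, :]
        curve, smap = decoding.kcell_selection_curve(X, y, k=1, n_machines=20, seed=0)
        assert (smap.fractions[:, 3] > 0.5).all()
        assert (curve.mean > 0.9).all()

    def test_zero_variance_cell_never_selected(self, rng):
        n = 40
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
        X = rng.random((1, n, 5))
        X[:, :, 2] = 0.0
        _, smap = decoding.kcell_selection_curve(X, y, k=3, n_machines=10, seed=0)
        assert smap.fractions[0, 2] == 0.0

    def test_k_too_large_rejected(self, rng):
        X, y = _xor_free_data(rng)
        with pytest.raises(ValueError):
            decoding.kcell_selection_curve(X, y, k=5, n_machines=1)

    def test_shuffled_labels_at_chance(self, rng):
        n = 60
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
        X = rng.random((1, n, 4))
        X[:, :, 0] += 2.0 * y[None, :]
        ys = rng.permutation(y)
        curve, _ = decoding.kcell_selection_curve(X, ys, k=2, n_machines=30, seed=0)
        assert abs(curve.mean.mean() - 0.5) < 0.12


class TestPairwiseOutcomes:
    def test_empty_class_skipped(self, rng):
        X = rng.random((2, 20, 3))
        outcomes = pd.DataFrame({"outcome": ["Hit"] * 10 + ["CR"] * 10})
        curves = decoding.pairwise_outcome_decoding(
            X, outcomes, n_machines=5, seed=0
        )
        assert set(curves) == {("Hit", "CR")}

    def test_identical_generators_at_chance(self, rng):
        X = rng.random((2, 60, 3))
        outcomes = pd.DataFrame({"outcome": ["Hit"] * 30 + ["CR"] * 30})
        curves = decoding.pairwise_outcome_decoding(
            X, outcomes, n_machines=40, seed=0
        )
        c = curves[("Hit", "CR")]
        se = c.accuracies.std(axis=1, ddof=1) / np.sqrt(c.n_machines)
        assert np.all(np.abs(c.mean - 0.5) <= 3 * np.maximum(se, 0.02))

    def test_learned_hit_cr_separable_before_reward(
        self, learned_bundle, learned_outcomes
    ):
        """Hit-vs-CR population decoding beats its control before the reward."""
        F = decoding.raster_features(learned_bundle.raster)
        curves = decoding.pairwise_outcome_decoding(
            F, learned_outcomes, pairs=(("Hit", "CR"),), n_machines=30, seed=0
        )
        c = curves[("Hit", "CR")]
        _, hi = c.control.band()
        reward_bin = int(1.2 / decoding.BIN_WIDTH)
        assert (c.mean[:reward_bin] > hi[:reward_bin]).any()
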