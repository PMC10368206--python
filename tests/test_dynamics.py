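import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tpsd import behavior, dynamics, synth, task
from tpsd.raster import SpikeRaster


def _raster(act):
    return SpikeRaster(activity=np.asarray(act, dtype=np.uint8))


class TestBootstrapActivity:
    def test_constant_raster(self):
        r = _raster(np.ones((3, 4, 5)))
        s = dynamics.bootstrap_mean_activity(r, n_iter=50, seed=0)
        lo, hi = s.ci()
        assert np.allclose(s.mean, 1.0) and np.allclose(lo, hi)

    def test_single_trial_degenerate(self):
        rng = np.random.default_rng(0)
        r = _raster(rng.integers(0, 2, (4, 6, 1)))
        s = dynamics.bootstrap_mean_activity(r, n_iter=20, seed=0)
        assert np.all(s.iterations == s.iterations[0])

    def test_empty_condition_rejected(self):
        r = _raster(np.ones((2, 2, 3)))
        with pytest.raises(ValueError):
            dynamics.bootstrap_mean_activity(r, np.zeros(3, dtype=bool))

    def test_grand_mean_converges_to_plugin(self, learned_bundle):
        r = learned_bundle.raster
        s = dynamics.bootstrap_mean_activity(r, n_iter=1000, seed=0)
        plugin = r.activity.mean(axis=(0, 2))
        assert np.all(np.abs(s.mean - plugin) < 0.01)

    def test_pooling_stacks_iterations(self):
        r = _raster(np.ones((2, 3, 4)))
        a = dynamics.bootstrap_mean_activity(r, n_iter=10, seed=0)
        b = dynamics.bootstrap_mean_activity(r, n_iter=15, seed=1)
        assert dynamics.pool_summaries([a, b]).n_iterations == 25


class TestStimulusCorrelation:
    def _summary(self, mat):
        return dynamics.NetworkSummary(
            bin_times=np.arange(mat.shape[1]) / 15.0, iterations=mat
        )

    def test_identity_and_inversion(self):
        ind = np.array([1, 0, 1, 0, 1], dtype=float)
        s = self._summary(np.tile(ind, (20, 1)) + np.random.default_rng(0).normal(0, 1e-9, (20, 5)))
        r, _ = dynamics.stimulus_correlation(s, ind)
        assert r == pytest.approx(1.0, abs=1e-6)
        s2 = self._summary(np.tile(1 - ind, (20, 1)) + np.random.default_rng(1).normal(0, 1e-9, (20, 5)))
        r2, _ = dynamics.stimulus_correlation(s2, ind)
        assert r2 == pytest.approx(-1.0, abs=1e-6)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(2)
        s = self._summary(rng.normal(size=(1000, 10)))
        ind = rng.integers(0, 2, 10).astype(float)
        ind[0] = 1 - ind[1]  # guarantee variance
        r, _ = dynamics.stimulus_correlation(s, ind)
        assert abs(r) < 0.05

    def test_zero_variance_rejected(self):
        s = self._summary(np.ones((5, 4)))
        with pytest.raises(ValueError):
            dynamics.stimulus_correlation(s, np.array([1, 0, 1, 0.0]))

    def test_sign_matches_planted_drive(self, learned_bundle):
        """Stim-locked drive makes activity covary with the indicator."""
        r = learned_bundle.raster
        keep = ~r.lick_flags
        sub = SpikeRaster(activity=r.activity[keep])
        s = dynamics.bootstrap_mean_activity(sub, n_iter=300, seed=0)
        ind = task.stimulus_indicator(
            task.build_timeline("TPSD", "P"), r.bin_width, 2.0
        )[: r.n_bins]
        corr, p = dynamics.stimulus_correlation(s, ind)
        assert corr > 0 and p < 0.05


def brute_force_ks(a, b):
    """Independent oracle: max ECDF gap over the pooled sample points."""
    pts = np.concatenate([a, b])
    gaps = [
        abs(np.mean(a <= x) - np.mean(b <= x)) for x in pts
    ]
    return max(gaps)


class TestPeakTimes:
    def test_single_firing_bin(self):
        act = np.zeros((1, 6, 2))
        act[0, 4, :] = 1
        d = dynamics.peak_times(_raster(act), period=(0.0, 0.4))
        assert d.times[0] == pytest.approx(4 / 15.0)

    def test_flat_cell_earliest_bin(self):
        d = dynamics.peak_times(_raster(np.zeros((2, 6, 2))), period=(0.1, 0.4))
        # earliest bin whose midpoint is inside the period (bin 1: mid 0.1 s)
        assert np.all(d.times == d.times[0])
        assert d.times[0] == pytest.approx(1 / 15.0)

    def test_empty_period_rejected(self):
        with pytest.raises(ValueError):
            dynamics.peak_times(_raster(np.zeros((2, 6, 2))), period=(5.0, 6.0))

    def test_learned_np_left_shifted(self, learned_bundle, naive_bundle,
                                     learned_outcomes, naive_outcomes):
        """Suppression pulls nonpreferred peak times earlier with learning."""
        ml = (learned_outcomes["stimulus"] == "NP").to_numpy()
        mn = (naive_outcomes["stimulus"] == "NP").to_numpy()
        learned = dynamics.peak_times(learned_bundle.raster, ml, (0.0, 1.4))
        naive = dynamics.peak_times(naive_bundle.raster, mn, (0.0, 1.4))
        assert np.median(learned.times) < np.median(naive.times)


class TestKS:
    @pytest.mark.parametrize("n_pairs, alpha", [(6, 0.0083), (3, 0.0167)])
    def test_bonferroni_alpha(self, n_pairs, alpha, rng):
        dists = {
            str(i): dynamics.PeakTimeDist(rng.random(20), (0, 1)) for i in range(4)
        }
        names = sorted(dists)
        pairs = [(names[0], names[1])] * n_pairs
        out = dynamics.compare_peak_distributions(dists, pairs)
        assert round(out["alpha_adj"].iloc[0], 4) == alpha

    def test_identical_samples(self):
        x = np.arange(10.0)
        dists = {
            "a": dynamics.PeakTimeDist(x, (0, 10)),
            "b": dynamics.PeakTimeDist(x.copy(), (0, 10)),
        }
        out = dynamics.compare_peak_distributions(dists, [("a", "b")])
        assert out["D"].iloc[0] == 0.0 and not out["significant"].iloc[0]

    @given(
        na=st.integers(3, 50),
        nb=st.integers(3, 50),
        seed=st.integers(0, 1000),
    )
    def test_ks_statistic_matches_brute_force(self, na, nb, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.random(na), rng.random(nb) + rng.normal(0, 0.3)
        dists = {
            "a": dynamics.PeakTimeDist(a, (0, 2)),
            "b": dynamics.PeakTimeDist(b, (0, 2)),
        }
        out = dynamics.compare_peak_distributions(dists, [("a", "b")])
        assert out["D"].iloc[0] == pytest.approx(brute_force_ks(a, b), abs=1e-12)


class TestSorting:
    def test_identity_and_reversal(self):
        eye = np.eye(5)
        assert dynamics.sort_by_peak_time(eye).tolist() == [0, 1, 2, 3, 4]
        assert dynamics.sort_by_peak_time(eye[::-1]).tolist() == [4, 3, 2, 1, 0]

    @given(seed=st.integers(0, 500))
    def test_matches_argsort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        traces = rng.random((12, 8))
        order = dynamics.sort_by_peak_time(traces)
        oracle = np.argsort(np.argmax(traces, axis=1), kind="stable")
        assert np.array_equal(order, oracle)


class TestTrajectories:
    def _outcomes(self, labels):
        return pd.DataFrame({"outcome": labels})

    def test_planar_data_two_components(self, rng):
        # two cell groups with distinct binary time courses: the mean matrix
        # has rank 2, so the first two components carry all the variance
        a = rng.integers(0, 2, 10).astype(float)
        b = rng.integers(0, 2, 10).astype(float)
        act = np.zeros((6, 10, 4))
        act[:3] = a[None, :, None]
        act[3:] = b[None, :, None]
        t = dynamics.outcome_trajectories(
            _raster(act), self._outcomes(["Hit", "CR", "Hit", "CR"])
        )
        assert t.variance_explained[:2].sum() > 99.9

    def test_identical_outcomes_zero_divergence(self, rng):
        act = rng.integers(0, 2, (5, 8, 6))
        act[:, :, 3:] = act[:, :, :3]
        r = _raster(act)
        t = dynamics.outcome_trajectories(
            r, self._outcomes(["Hit"] * 3 + ["CR"] * 3)
        )
        assert t.divergence("Hit", "CR") == pytest.approx(0.0, abs=1e-9)

    def test_variance_permutation_invariant(self, rng):
        act = rng.integers(0, 2, (10, 6, 8))
        r1 = _raster(act)
        r2 = _raster(act[rng.permutation(10)])
        oc = self._outcomes(["Hit"] * 4 + ["CR"] * 4)
        v1 = dynamics.outcome_trajectories(r1, oc).variance_explained
        v2 = dynamics.outcome_trajectories(r2, oc).variance_explained
        assert np.allclose(v1, v2, atol=1e-9)

    def test_learned_divergence_ordering(self, learned_bundle, learned_outcomes):
        """Hit/CR trajectories separate more than Hit/FA in the learned regime."""
        t = dynamics.outcome_trajectories(learned_bundle.raster, learned_outcomes)
        assert t.divergence("Hit", "CR") > t.divergence("Hit", "FA")
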