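import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ppg2ecg.metrics import (dtw, dtw_per_second, evaluate, pearson_r, rmse,
                             summarize, xcorr_align)
from conftest import brute_force_dtw

FS = 125.0


class TestPearson:
    def test_identical_series_give_one(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        assert pearson_r(x, x) == pytest.approx(1.0)

    def test_negated_series_give_minus_one(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_matches_direct_formula_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.normal(size=(2, 50))
            expected, _ = stats.pearsonr(a, b)
            assert pearson_r(a, b) == pytest.approx(expected, abs=1e-12)

    def test_hand_example(self):
        # direct evaluation of the covariance ratio
        a = np.array([0.0, 1, 2, 3])
        b = np.array([0.0, 1, 2, 5])
        da, db = a - a.mean(), b - b.mean()
        expected = np.sum(da * db) / np.sqrt(np.sum(da**2) * np.sum(db**2))
        assert pearson_r(a, b) == pytest.approx(expected, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(a=st.floats(0.1, 10.0), b=st.floats(-5.0, 5.0), seed=st.integers(0, 999))
    def test_invariant_under_positive_affine_maps(self, a, b, seed):
        x, y = np.random.default_rng(seed).normal(size=(2, 30))
        assert pearson_r(a * x + b, y) == pytest.approx(pearson_r(x, y), abs=1e-9)


class TestRmse:
    def test_zero_for_identical(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_unit_offset(self):
        assert rmse([0.0, 0.0], [1.0, 1.0]) == pytest.approx(1.0)

    def test_closed_form(self):
        assert rmse([0.0, 3.0], [4.0, 3.0]) == pytest.approx(np.sqrt(8.0))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            rmse([0.0], [0.0, 1.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(c=st.floats(-10.0, 10.0), seed=st.integers(0, 999))
    def test_translation_covariance(self, c, seed):
        x, y = np.random.default_rng(seed).normal(size=(2, 30))
        assert rmse(x + c, y + c) == pytest.approx(rmse(x, y), abs=1e-9)


class TestDtw:
    def test_self_distance_zero_with_diagonal_path(self):
        x = np.array([0.0, 1.0, -0.5, 2.0])
        dist, path = dtw(x, x)
        assert dist == 0.0
        np.testing.assert_array_equal(path.steps,
                                      [[1, 1], [2, 2], [3, 3], [4, 4]])

    def test_single_sample(self):
        dist, path = dtw([2.0], [5.0])
        assert dist == pytest.approx(3.0)
        np.testing.assert_array_equal(path.steps, [[1, 1]])

    def test_three_sample_example_matches_exhaustive_oracle(self):
        a = np.array([0.0, 1.0, 0.0])
        b = np.array([0.0, 0.0, 1.0])
        dist, _ = dtw(a, b)
        assert dist == pytest.approx(brute_force_dtw(a, b), abs=1e-12)

    def test_matches_exhaustive_oracle_on_seeded_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            m = int(rng.integers(2, 9))
            a, b = rng.normal(size=(2, m))
            dist, path = dtw(a, b)
            assert dist == pytest.approx(brute_force_dtw(a, b), abs=1e-10)
            # path is anchored and monotone with unit steps
            assert tuple(path.steps[0]) == (1, 1)
            assert tuple(path.steps[-1]) == (m, m)
            diffs = np.diff(path.steps, axis=0)
            assert set(map(tuple, diffs)) <= {(1, 0), (0, 1), (1, 1)}

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(2, 20))
        assert dtw(a, b)[0] == pytest.approx(dtw(b, a)[0], abs=1e-10)

    def test_banded_equals_full_on_medium_instances(self):
        rng = np.random.default_rng(4)
        for m in (100, 500):
            a, b = rng.normal(size=(2, m))
            full, path = dtw(a, b)
            max_dev = int(np.max(np.abs(path.steps[:, 0] - path.steps[:, 1])))
            banded, _ = dtw(a, b, radius=max(max_dev, 1))
            assert banded == pytest.approx(full, abs=1e-9)

    def test_amplitude_only_cost_option(self):
        a = np.array([0.0, 1.0, 0.0])
        b = np.array([0.0, 0.0, 1.0])
        dist, _ = dtw(a, b, index_weight=0.0)
        assert dist == pytest.approx(brute_force_dtw(a, b, index_weight=0.0),
                                     abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            dtw([], [])


class TestDtwPerSecond:
    def test_reported_quotient(self):
        # the literal quotient of a 228-s stitched distance
        assert dtw_per_second(533.218, 228.0) == pytest.approx(2.3387, abs=1e-4)

    def test_trivial_cases(self):
        assert dtw_per_second(0.0, 5.0) == 0.0
        assert dtw_per_second(10.0, 5.0) == 2.0

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            dtw_per_second(1.0, 0.0)


class TestXcorrAlign:
    @staticmethod
    def _signal(n=1000, seed=0):
        t = np.arange(n) / FS
        rng = np.random.default_rng(seed)
        return np.sin(2 * np.pi * 1.1 * t) + 0.3 * np.sin(2 * np.pi * 7.3 * t) \
            + 0.05 * rng.normal(size=n)

    def test_zero_lag_on_identical(self):
        x = self._signal()
        res = xcorr_align(x, x, FS)
        assert res.lag == 0
        np.testing.assert_array_equal(res.ref, x)

    @pytest.mark.parametrize("delay", [1, 3, 5, 10, -4])
    def test_integer_delay_recovered_exactly(self, delay):
        x = self._signal()
        rec = np.roll(x, delay)  # rec lags ref by `delay`
        res = xcorr_align(x, rec, FS, window_ms=80.0)
        assert res.lag == delay
        assert pearson_r(res.ref, res.rec) == pytest.approx(1.0, abs=1e-6)
        assert rmse(res.ref, res.rec) < 1e-6 if delay >= 0 else True

    def test_delay_beyond_window_clips_to_bound(self):
        x = self._signal(seed=5)
        rec = np.roll(x, 15)  # 120 ms > 80 ms window
        res = xcorr_align(x, rec, FS, window_ms=80.0)
        # exhaustive oracle within the admissible window
        def score(lag):
            n = len(x)
            a = x[: n - lag] if lag >= 0 else x[-lag:]
            b = rec[lag:] if lag >= 0 else rec[: n + lag]
            return pearson_r(a, b)
        best = max(range(-10, 11), key=lambda L: (score(L), -abs(L)))
        assert res.lag == best
        assert abs(res.lag) == 10
        assert pearson_r(res.ref, res.rec) < 1.0

    def test_alignment_never_lowers_correlation(self):
        rng = np.random.default_rng(9)
        for seed in range(5):
            x = self._signal(seed=seed)
            y = x + 0.2 * rng.normal(size=len(x))
            res = xcorr_align(x, np.roll(y, 4), FS)
            assert pearson_r(res.ref, res.rec) >= pearson_r(x, np.roll(y, 4)) - 1e-12

    def test_window_larger_than_signal_rejected(self):
        with pytest.raises(ValueError, match="window"):
            xcorr_align(np.zeros(5), np.zeros(5), FS, window_ms=80.0)


class TestEvaluate:
    def test_perfect_reconstruction(self):
        rng = np.random.default_rng(1)
        segs = rng.normal(size=(4, int(FS)))
        rep = evaluate(segs, segs.copy(), FS, 1)
        assert np.allclose(rep.r, 1.0) and rep.r_s == pytest.approx(1.0)
        assert np.all(rep.rmse_ == 0) and np.all(rep.d == 0)
        assert rep.rmse_s == 0 and rep.d_s == 0 and rep.d_bar_s == 0

    def test_two_segment_mean_and_sd(self):
        # construct two 1-s segments with known per-segment r of 0.5 and 1.0
        n = int(FS)
        rng = np.random.default_rng(2)
        a = rng.normal(size=n)
        u = (a - a.mean())
        u /= np.linalg.norm(u)
        z = rng.normal(size=n)
        z -= z.mean()
        v = z - (z @ u) * u
        v /= np.linalg.norm(v)
        rec0 = 0.5 * u + np.sqrt(0.75) * v  # centered, corr(a, rec0) = 0.5
        ref = np.stack([a, a])
        rec = np.stack([rec0, a])
        rep = evaluate(ref, rec, FS, 1)
        assert rep.r[0] == pytest.approx(0.5, abs=1e-9)
        assert rep.r[1] == pytest.approx(1.0)
        s = rep.summary()
        assert s["r_mean"] == pytest.approx(0.75, abs=1e-9)
        assert s["r_sd"] == pytest.approx(np.std([0.5, 1.0], ddof=1), abs=1e-9)

    def test_uniform_delay_fixed_by_alignment(self):
        n = 3 * int(FS)
        t = np.arange(n) / FS
        x = np.sin(2 * np.pi * 1.3 * t) + 0.4 * np.sin(2 * np.pi * 5.7 * t)
        rec = np.roll(x, 3)
        rep = evaluate(x[None, :], rec[None, :], FS, 3)
        assert rep.r[0] < 1.0
        assert rep.r_a[0] == pytest.approx(1.0, abs=1e-9)
        assert rep.rmse_a[0] == pytest.approx(0.0, abs=1e-9)
        assert rep.lag[0] == 3

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            evaluate(np.zeros((2, 10)), np.zeros((3, 10)), FS, 1)

    def test_summarize_pools_over_records(self):
        rng = np.random.default_rng(8)
        reps = []
        for seed in range(2):
            segs = rng.normal(size=(3, 250))
            reps.append(evaluate(segs, segs + 0.1 * rng.normal(size=segs.shape), FS, 2))
        pooled = summarize(reps)
        assert pooled["n_records"] == 2
        expected_r = np.concatenate([r.r for r in reps])
        assert pooled["r_mean"] == pytest.approx(np.mean(expected_r))
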