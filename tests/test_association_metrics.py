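import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import branchtf as bt
from branchtf.association_metrics import ZeroVarianceError, score_pair
from branchtf.io_formats import Mode, Regulon


# ---------------------------------------------------------------- oracles

def dtw_oracle(x, y):
    """Exhaustive enumeration of all monotone warping paths.

    Minimizes (total |difference| cost, path length) lexicographically on the
    fractional-rescaled series and returns cost / length.
    """
    def frac(v):
        v = np.asarray(v, dtype=float)
        s = v.sum()
        return v / s if s > 0 else np.full(len(v), 1.0 / len(v))

    fx, fy = frac(x), frac(y)
    n, m = len(fx), len(fy)
    best = [np.inf, np.inf]  # cost, length

    def walk(i, j, cost, length):
        cost = cost + abs(fx[i] - fy[j])
        length += 1
        if i == n - 1 and j == m - 1:
            if (cost, length) < tuple(best):
                best[0], best[1] = cost, length
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, cost, length)
        if i + 1 < n:
            walk(i + 1, j, cost, length)
        if j + 1 < m:
            walk(i, j + 1, cost, length)

    walk(0, 0, 0.0, 0)
    return best[0] / best[1]


def mi_entropy_oracle(n, b):
    """MI of a perfectly diagonal joint histogram with n points in b bins."""
    counts = np.bincount((np.arange(n)) * b // n, minlength=b) / n
    return float(-(counts[counts > 0] * np.log(counts[counts > 0])).sum())


# ---------------------------------------------------------------- correlations

class TestCorrelations:
    def test_perfect_linear(self):
        x = np.array([0.0, 1, 2, 3])
        assert bt.pearson_sq(x, 2 * x + 1) == pytest.approx((1.0, 1))

    def test_sign_preserved_for_negative_slope(self):
        x = np.array([0.0, 1, 2, 3])
        score, sign = bt.pearson_sq(x, -x)
        assert score == pytest.approx(1.0)
        assert sign == -1

    def test_pearson_hand_value(self):
        score, sign = bt.pearson_sq(np.array([1.0, 2, 3, 4]), np.array([1.0, 3, 2, 4]))
        assert score == pytest.approx(0.64)
        assert sign == 1

    def test_spearman_monotone_nonlinear(self):
        x = np.array([0.0, 1, 2, 3, 4])
        assert bt.spearman_sq(x, np.exp(x)) == pytest.approx((1.0, 1))
        assert bt.spearman_sq(x, -(x**3)) == pytest.approx((1.0, -1))

    def test_spearman_hand_value(self):
        score, sign = bt.spearman_sq(np.array([1.0, 2, 3, 4]), np.array([1.0, 3, 2, 4]))
        assert score == pytest.approx(0.64)
        assert sign == 1

    def test_zero_variance_raises(self):
        with pytest.raises(ZeroVarianceError):
            bt.pearson_sq(np.ones(5), np.arange(5.0))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=8), rng.normal(size=8)
        for f in (bt.pearson_sq, bt.spearman_sq):
            s_xy, sign_xy = f(x, y)
            s_yx, sign_yx = f(y, x)
            assert s_xy == pytest.approx(s_yx, abs=1e-12)
            assert sign_xy == sign_yx


# ---------------------------------------------------------------- DTW

class TestDTW:
    def test_self_distance_zero(self, rng):
        x = rng.uniform(0, 5, 12)
        assert bt.dtw_distance(x, x) == 0.0

    def test_two_by_two_hand_dp(self):
        # fractional x = (1, 0), y = (0, 1); cost matrix [[1,0],[0,1]]
        # best path: (0,0)->(0,1)->(1,1) or (0,0)->(1,0)->(1,1), cost 2, len 3
        # vs diagonal (0,0)->(1,1): cost 2, len 2 -> 2/2 = 1.0
        got = bt.dtw_distance(np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        assert got == pytest.approx(dtw_oracle([1.0, 0.0], [0.0, 1.0]))

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 100_000), st.integers(2, 8), st.integers(2, 8))
    def test_matches_exhaustive_path_oracle(self, seed, n, m):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 10, n)
        y = rng.uniform(0, 10, m)
        assert bt.dtw_distance(x, y) == pytest.approx(dtw_oracle(x, y), abs=1e-10)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_symmetric_and_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.uniform(0, 3, 6), rng.uniform(0, 3, 6)
        d = bt.dtw_distance(x, y)
        assert d >= 0
        assert d == pytest.approx(bt.dtw_distance(y, x), abs=1e-12)

    def test_all_zero_series_becomes_uniform(self):
        # all-zero vs constant: both fractional-uniform -> distance 0
        assert bt.dtw_distance(np.zeros(5), np.full(5, 3.0)) == pytest.approx(0.0)


# ---------------------------------------------------------------- MI

class TestMutualInformation:
    def test_identity_reaches_log_bins(self):
        x = np.arange(16.0)
        assert bt.mutual_information(x, x, n_mi_bins=8) == pytest.approx(np.log(8))

    def test_diagonal_matches_entropy_oracle_uneven(self):
        x = np.arange(13.0)  # not divisible by bins
        assert bt.mutual_information(x, x, n_mi_bins=4) == pytest.approx(
            mi_entropy_oracle(13, 4)
        )

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(7)
        x, y = rng.uniform(size=10_000), rng.uniform(size=10_000)
        assert bt.mutual_information(x, y) < 0.1

    def test_constant_series_zero(self):
        assert bt.mutual_information(np.arange(10.0), np.ones(10)) == 0.0

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 10_000), st.integers(4, 30))
    def test_bounded_and_symmetric(self, seed, n):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=n), rng.normal(size=n)
        mi = bt.mutual_information(x, y)
        assert 0 <= mi <= np.log(8) + 1e-9
        assert mi == pytest.approx(bt.mutual_information(y, x), abs=1e-12)


# ---------------------------------------------------------------- rolling

class TestRolling:
    def test_zero_lag_equals_base_metric(self, rng):
        x, y = rng.uniform(0, 5, 12), rng.uniform(0, 5, 12)
        for metric in bt.BASE_METRICS:
            base = score_pair(metric, x, y)
            rolled = score_pair(f"rolling_{metric}", x, y, max_lag=0)
            assert rolled == base

    def test_exact_lag_recovery_on_noise_free_shift(self):
        t = np.linspace(0, 1, 20)
        x = 1.0 / (1.0 + np.exp(-10 * (t - 0.5)))
        y = np.concatenate([np.full(2, x[0]), x[:-2]])  # shifted right by 2 bins
        score, sign, lag = bt.rolling_best("pearson", x, y, max_lag=5)
        assert lag == 2
        assert score == pytest.approx(1.0, abs=1e-9)
        assert sign == 1

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 10_000), st.integers(0, 5))
    def test_matches_brute_force_over_lags(self, seed, max_lag):
        rng = np.random.default_rng(seed)
        x, y = rng.uniform(0, 5, 14), rng.uniform(0, 5, 14)
        for metric in bt.BASE_METRICS:
            got = bt.rolling_best(metric, x, y, max_lag)
            best = None
            for k in range(max_lag + 1):
                xs, ys = x[: len(x) - k] if k else x, y[k:]
                s, sg = score_pair(metric, xs, ys)[:2]
                better = best is None or (
                    s > best[0] if metric != "dtw" else s < best[0]
                )
                if better:
                    best = (s, sg, k)
            assert got == best

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_wider_scan_never_worse(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.uniform(0, 5, 16), rng.uniform(0, 5, 16)
        for metric in bt.BASE_METRICS:
            s_small = bt.rolling_best(metric, x, y, 2)[0]
            s_large = bt.rolling_best(metric, x, y, 6)[0]
            if metric == "dtw":
                assert s_large <= s_small + 1e-12
            else:
                assert s_large >= s_small - 1e-12


# ---------------------------------------------------------------- regulon scoring

class TestScoreRegulon:
    @pytest.fixture()
    def smoothed(self, rng):
        import pandas as pd

        genes = ["TF1", "A", "B", "C", "D", "E"]
        return pd.DataFrame(rng.uniform(0, 5, (6, 10)), index=genes)

    def test_absent_targets_dropped(self, smoothed):
        reg = Regulon("TF1", [(g, Mode.UNKNOWN) for g in ["A", "B", "C", "GHOST"]])
        scores = bt.score_regulon("TF1", reg, smoothed, "pearson")
        assert {s.target for s in scores} == {"A", "B", "C"}

    def test_self_edge_excluded(self, smoothed):
        reg = Regulon("TF1", [(g, Mode.UNKNOWN) for g in ["TF1", "A", "B", "C"]])
        scores = bt.score_regulon("TF1", reg, smoothed, "mi")
        assert "TF1" not in {s.target for s in scores}

    def test_metric_id_carried(self, smoothed):
        reg = Regulon("TF1", [(g, Mode.UNKNOWN) for g in "ABCDE"])
        for metric in bt.ALL_METRICS:
            scores = bt.score_regulon("TF1", reg, smoothed, metric)
            assert all(s.metric == metric for s in scores)

    def test_absent_tf_is_untestable(self, smoothed):
        reg = Regulon("GHOST", [(g, Mode.UNKNOWN) for g in "ABC"])
        with pytest.raises(KeyError):
            bt.score_regulon("GHOST", reg, smoothed, "pearson")
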