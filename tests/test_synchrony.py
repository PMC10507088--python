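import numpy as np
import pytest

from leadsync.synchrony import (
    DegenerateSeriesError,
    DyadRecording,
    extract_excerpts,
    leading_scores,
    remove_outliers,
    scale_series,
    windowed_lagged_ccf,
)
from leadsync.synthetic import DyadSimConfig, simulate_dyad_motion
from leadsync.videomotion import MotionEnergySeries


def series(values, fps=25.0):
    return MotionEnergySeries(np.asarray(values, dtype=float), fps=fps)


def naive_lagged_pearson(g, w, max_lag, use_abs=True, fisher_z=True):
    """Brute-force single-window oracle: plain Pearson at every lag."""
    n = len(g)
    out = {}
    for lag in range(-max_lag, max_lag + 1):
        xs, ys = [], []
        for t in range(n):
            if 0 <= t + lag < n and np.isfinite(g[t]) and np.isfinite(w[t + lag]):
                xs.append(g[t])
                ys.append(w[t + lag])
        if len(xs) < 3 or np.std(xs) == 0 or np.std(ys) == 0:
            out[lag] = np.nan
            continue
        r = np.corrcoef(xs, ys)[0, 1]
        if use_abs:
            r = abs(r)
        if fisher_z:
            r = np.arctanh(np.clip(r, -0.9999, 0.9999))
        out[lag] = r
    return out


class TestRemoveOutliers:
    def test_constant_series_unchanged(self):
        s = series([1, 1, 1, 1, 1])
        out = remove_outliers(s)
        np.testing.assert_array_equal(out.values, s.values)

    def test_single_extreme_spike_removed(self, rng):
        base = np.abs(rng.standard_normal(1000))
        sd = np.std(base, ddof=1)
        vals = np.append(base, 50 * sd)
        out = remove_outliers(series(vals))
        thresh = 10 * np.std(vals, ddof=1)
        # brute-force check: exactly the values above the threshold are gone
        expected_nan = vals > thresh
        assert expected_nan.sum() == 1
        np.testing.assert_array_equal(np.isnan(out.values), expected_nan)

    def test_identity_when_no_outliers(self, rng):
        vals = np.abs(rng.standard_normal(200))
        out = remove_outliers(series(vals))
        np.testing.assert_array_equal(out.values, vals)

    def test_threshold_uses_original_sd(self):
        # two spikes: the threshold must come from the full series SD,
        # not be recomputed after removing the first spike
        vals = np.array([0.1] * 500 + [100.0, 9.0])
        sd = np.std(vals, ddof=1)
        out = remove_outliers(series(vals))
        assert np.isnan(out.values[-2])
        assert not np.isnan(out.values[-1])  # 9.0 < 10*sd on the original


class TestScaleSeries:
    def test_unit_sd_and_ratio_preserved(self):
        out = scale_series(series([0, 2, 4]))
        assert np.isclose(np.std(out.values, ddof=1), 1.0)
        assert np.isclose(out.values[2] / out.values[1], 2.0)

    def test_idempotence(self, rng):
        s = series(np.abs(rng.standard_normal(100)))
        once = scale_series(s)
        twice = scale_series(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_burst_series_sd_one(self, uncoupled_dyad):
        out = scale_series(uncoupled_dyad.green)
        assert abs(np.std(out.values, ddof=1) - 1.0) < 1e-12

    def test_zero_sd_raises(self):
        with pytest.raises(DegenerateSeriesError):
            scale_series(series([3, 3, 3]))


class TestExtractExcerpts:
    def test_default_spans_arithmetic(self):
        s = series(np.arange(300 * 25, dtype=float))
        intro, body = extract_excerpts(s)
        assert len(intro) == 250 and intro.values[0] == 2250
        assert len(body) == 250 and body.values[0] == 6000

    def test_span_past_end_raises(self):
        s = series(np.zeros(int(245 * 25)))
        with pytest.raises(ValueError, match="exceeds series duration"):
            extract_excerpts(s, [(240.0, 250.0)])

    def test_tiling_spans_partition_series(self):
        s = series(np.arange(300 * 25, dtype=float))
        spans = [(t, t + 10.0) for t in range(0, 300, 10)]
        parts = extract_excerpts(s, spans)
        np.testing.assert_array_equal(
            np.concatenate([p.values for p in parts]), s.values
        )


class TestWindowedLaggedCcf:
    def test_self_correlation_clamped(self, rng):
        vals = np.abs(rng.standard_normal(250))
        s = series(vals)
        ccf = windowed_lagged_ccf(s, s, max_lag_s=0.2)
        lag0 = ccf.z[0, list(ccf.lags).index(0)]
        assert np.isclose(lag0, np.arctanh(0.9999))

    def test_shifted_copy_peaks_at_shift_lag(self, rng):
        g = np.abs(rng.standard_normal(250))
        w = np.zeros(250)
        w[12:] = g[:-12]  # white repeats green 12 frames later
        ccf = windowed_lagged_ccf(series(g), series(w), max_lag_s=2.0)
        best_lag = ccf.lags[np.nanargmax(ccf.z[0])]
        assert best_lag == 12

    def test_matches_naive_oracle(self, rng):
        for _ in range(10):
            g = np.abs(rng.standard_normal(250))
            w = np.abs(rng.standard_normal(250))
            # inject some missing values to exercise pairwise deletion
            g[rng.integers(0, 250, size=5)] = np.nan
            gs = MotionEnergySeries(g, 25.0)
            ccf = windowed_lagged_ccf(gs, series(w), max_lag_s=1.0)
            oracle = naive_lagged_pearson(g, w, max_lag=25)
            for li, lag in enumerate(ccf.lags):
                got, want = ccf.z[0, li], oracle[lag]
                if np.isnan(want):
                    assert np.isnan(got)
                else:
                    assert abs(got - want) < 1e-10

    def test_white_noise_null_correlations_small(self, rng):
        exceed = 0
        n_pairs = 200
        for _ in range(n_pairs):
            g = np.abs(rng.standard_normal(250))
            w = np.abs(rng.standard_normal(250))
            ccf = windowed_lagged_ccf(series(g), series(w), max_lag_s=0.2, fisher_z=False)
            if np.nanmax(np.abs(ccf.z)) >= 0.25:
                exceed += 1
        assert exceed <= 0.01 * n_pairs + 2

    def test_scale_invariance(self, uncoupled_dyad):
        g, w = uncoupled_dyad.green, uncoupled_dyad.white
        a = windowed_lagged_ccf(g, w, max_lag_s=1.0)
        b = windowed_lagged_ccf(g.copy_with(g.values * 7.3), w, max_lag_s=1.0)
        np.testing.assert_allclose(a.z, b.z, atol=1e-12)

    def test_constant_window_yields_missing_not_error(self):
        g = series(np.ones(250))
        w = series(np.abs(np.sin(np.arange(250.0))) + 0.1)
        ccf = windowed_lagged_ccf(g, w, max_lag_s=0.2)
        assert np.all(np.isnan(ccf.z))


class TestLeadingScores:
    def test_symmetric_matrix_gives_equal_scores(self, uncoupled_dyad):
        ccf = windowed_lagged_ccf(uncoupled_dyad.green, uncoupled_dyad.white)
        ccf.z = (ccf.z + ccf.z[:, ::-1]) / 2  # symmetrize over lags
        scores = leading_scores(ccf)
        assert np.isclose(scores.green_leading, scores.white_leading)

    def test_swap_exchanges_green_and_white(self, coupled_dyad):
        d = coupled_dyad
        fwd = leading_scores(windowed_lagged_ccf(d.green, d.white))
        rev = leading_scores(windowed_lagged_ccf(d.white, d.green))
        assert np.isclose(fwd.green_leading, rev.white_leading)
        assert np.isclose(fwd.white_leading, rev.green_leading)
        assert np.isclose(fwd.zero_lag, rev.zero_lag)

    def test_null_coupling_centred_difference(self):
        diffs = []
        for seed in range(300):
            d = simulate_dyad_motion(DyadSimConfig(n_frames=250, coupling=0.0, seed=seed))
            s = leading_scores(windowed_lagged_ccf(d.green, d.white))
            diffs.append(s.green_leading - s.white_leading)
        diffs = np.array(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 2 * se + 1e-9

    def test_strong_coupling_green_leads(self):
        wins = 0
        n = 100
        for seed in range(n):
            d = simulate_dyad_motion(
                DyadSimConfig(n_frames=250, coupling=0.8, influence_lag=12, seed=seed)
            )
            s = leading_scores(windowed_lagged_ccf(d.green, d.white))
            wins += s.green_leading > s.white_leading
        assert wins >= 0.95 * n

    def test_log_transform_epsilon_rule(self, coupled_dyad):
        s = leading_scores(windowed_lagged_ccf(coupled_dyad.green, coupled_dyad.white))
        assert np.isclose(s.green_leading_log, np.log(s.green_leading + 1e-6))

    def test_peak_aggregation_at_least_mean(self, coupled_dyad):
        ccf = windowed_lagged_ccf(coupled_dyad.green, coupled_dyad.white)
        mean_s = leading_scores(ccf, aggregate="mean")
        peak_s = leading_scores(ccf, aggregate="peak")
        assert peak_s.green_leading >= mean_s.green_leading


def test_dyad_recording_validation(uncoupled_dyad):
    with pytest.raises(ValueError, match="equal length"):
        DyadRecording(
            "d", uncoupled_dyad.green,
            uncoupled_dyad.white.copy_with(uncoupled_dyad.white.values[:-1]),
            "autistic", "A",
        )
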