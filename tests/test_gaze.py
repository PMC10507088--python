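import numpy as np
import pandas as pd
import pytest

from leadsync.gaze import (
    GazeTrial,
    compare_gaze,
    gaze_metrics,
    iqr_filter,
    preprocess_gaze,
)


def make_trial(sides, tracked=None, pid="p0", tid="t0", diagnosis="autistic"):
    n = len(sides)
    if tracked is None:
        tracked = np.ones(n, dtype=bool)
    return GazeTrial(
        participant_id=pid,
        trial_id=tid,
        t_ms=np.arange(n) * (1000.0 / 60.0),
        sides=np.array(sides, dtype=object),
        tracked=np.asarray(tracked, dtype=bool),
        diagnosis=diagnosis,
    )


class TestGazeMetrics:
    def test_constant_gaze(self):
        m = gaze_metrics(make_trial(["target"] * 600))
        assert m.fixation_proportion_target == 1.0
        assert m.switches_per_100 == 0.0

    def test_alternating_samples(self):
        sides = ["target", "other"] * 300
        m = gaze_metrics(make_trial(sides))
        assert m.switches_per_100 == pytest.approx(599 * 100 / 600)
        assert m.switches_per_100 == pytest.approx(99.8333, abs=1e-3)

    def test_switch_count_matches_pairwise_scan(self, rng):
        sides = rng.choice(["target", "other"], size=500)
        tracked = rng.random(500) > 0.2
        trial = make_trial(list(sides), tracked=tracked)
        m = gaze_metrics(trial)
        # brute-force oracle over valid samples
        valid_sides = [s for s, tr in zip(sides, tracked) if tr]
        scan = sum(a != b for a, b in zip(valid_sides, valid_sides[1:]))
        assert m.switches_per_100 == pytest.approx(scan * 100 / len(valid_sides))

    def test_proportions_sum_to_one(self, rng):
        sides = list(rng.choice(["target", "other"], size=400))
        m = gaze_metrics(make_trial(sides))
        other = 1.0 - m.fixation_proportion_target
        assert np.isclose(m.fixation_proportion_target + other, 1.0)

    def test_timestamp_shift_invariance(self, rng):
        sides = list(rng.choice(["target", "other"], size=400))
        a = make_trial(sides)
        b = make_trial(sides)
        b.t_ms = b.t_ms + 12345.0
        assert gaze_metrics(a) == gaze_metrics(b)

    def test_missing_gap_does_not_break_same_side_run(self):
        sides = ["target"] * 200 + ["missing"] * 10 + ["target"] * 390
        m = gaze_metrics(make_trial(sides))
        assert m.switches_per_100 == 0.0


class TestPreprocessGaze:
    def test_low_tracking_trial_dropped(self):
        tracked = np.r_[np.ones(300, bool), np.zeros(300, bool)]  # exactly 50%
        trials = [make_trial(["target"] * 600, tracked=tracked)]
        retained, _ = preprocess_gaze(trials)
        assert retained == []

    def test_399_valid_samples_excluded_400_kept(self):
        for n_valid, expect in ((399, 0), (400, 1)):
            sides = ["target"] * n_valid + ["missing"] * (600 - n_valid)
            tracked = np.r_[np.ones(n_valid, bool), np.zeros(600 - n_valid, bool)]
            # tracking fraction must pass the first filter
            if tracked.mean() <= 0.5:
                tracked[:] = True
            retained, _ = preprocess_gaze([make_trial(sides, tracked=tracked)])
            assert len(retained) == expect

    def test_short_fixations_invalidated(self):
        # two-sample blips (33 ms < 50 ms) must not survive
        sides = (["target"] * 300 + ["other"] * 2 + ["target"] * 298)
        retained, _ = preprocess_gaze([make_trial(sides)])
        assert len(retained) == 1
        m = gaze_metrics(retained[0])
        assert m.switches_per_100 == 0.0  # the blip is gone

    def test_participant_retention_boundary(self):
        # 22 of 44 trials retained = exactly 50% -> participant kept
        trials = []
        for i in range(44):
            good = i < 22
            sides = ["target"] * 600
            tracked = np.ones(600, bool) if good else np.zeros(600, bool)
            trials.append(make_trial(sides, tracked=tracked, pid="p1", tid=f"t{i}"))
        retained, excluded = preprocess_gaze(trials)
        assert excluded == []
        assert len(retained) == 22
        # 21 of 44 (< 50%) -> excluded
        trials = []
        for i in range(44):
            good = i < 21
            tracked = np.ones(600, bool) if good else np.zeros(600, bool)
            trials.append(make_trial(["target"] * 600, tracked=tracked, pid="p2", tid=f"t{i}"))
        retained, excluded = preprocess_gaze(trials)
        assert excluded == ["p2"] and retained == []

    def test_filter_order_frozen_fixture(self):
        """Regression fixture: each filter removes its designated trial."""
        trials = [
            make_trial(["target"] * 600, pid="p0", tid="keep"),
            make_trial(["target"] * 600, tracked=np.zeros(600, bool), pid="p0", tid="untracked"),
            make_trial(["target"] * 390 + ["missing"] * 210, pid="p0", tid="short"),
        ]
        retained, excluded = preprocess_gaze(trials, min_trial_fraction=0.3)
        assert [t.trial_id for t in retained] == ["keep"]
        assert excluded == []


class TestIqrFilter:
    def test_hand_computed_fences(self):
        out = iqr_filter(np.array([1, 2, 3, 4, 100.0]))
        np.testing.assert_array_equal(out, [1, 2, 3, 4])

    def test_all_equal_unchanged(self):
        out = iqr_filter(np.full(10, 3.3))
        assert len(out) == 10

    def test_normal_sample_removal_rate(self, rng):
        x = rng.standard_normal(10_000)
        out = iqr_filter(x)
        rate = 1 - len(out) / len(x)
        assert 0.003 < rate < 0.012  # asymptotic ~0.7% for the 1.5 IQR rule

    def test_too_few_values(self):
        with pytest.raises(ValueError, match="at least 4"):
            iqr_filter(np.array([1.0, 2.0]))


class TestCompareGaze:
    def _metrics_frame(self, rng, n=30, shift=0.0):
        rows = []
        for p in range(n):
            for diag in ("autistic", "non-autistic"):
                base = rng.normal(0.65, 0.05)
                rows.append(
                    {
                        "participant_id": f"p{p}",
                        "diagnosis": diag,
                        "fixation_proportion_target": base + (shift if diag == "autistic" else 0),
                        "switches_per_100": rng.normal(5.5, 1.0),
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_conditions_favour_null(self, rng):
        df = self._metrics_frame(rng, shift=0.0)
        # make conditions exactly equal per participant
        piv = df.copy()
        piv["fixation_proportion_target"] = piv.groupby("participant_id")[
            "fixation_proportion_target"
        ].transform("mean") + rng.normal(0, 1e-9, len(piv))
        report = compare_gaze(piv)
        assert report["bf10_diagnosis_fixation_proportion_target"] < 1

    def test_target_preference_detected(self, rng):
        df = self._metrics_frame(rng, n=91)
        report = compare_gaze(df)
        assert report["bf10_proportion_vs_half"] > 100
        assert report["mean_fixation_proportion_target"] > 0.5

    def test_incomplete_participants_dropped(self, rng):
        df = self._metrics_frame(rng, n=5)
        df = df[~((df.participant_id == "p0") & (df.diagnosis == "autistic"))]
        report = compare_gaze(df)
        assert report["n_dropped_incomplete"] == 1
        assert report["n_participants"] == 4
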