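"""Webcam-gaze preprocessing and screen-half metrics.

Gaze was recorded with webcam-based eye tracking at a nominal 60 Hz while
participants watched 10-s clips (600 samples under optimal conditions).
Each sample is classified by screen half: ``target`` (the green
interactant's half), ``other`` or ``missing``.  Quality filtering follows a
fixed order: trial-level face-tracking accuracy, minimum fixation duration,
minimum sample count, then participant-level trial retention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from leadsync.stats import jzs_bf

__all__ = [
    "GazeTrial",
    "GazeMetrics",
    "preprocess_gaze",
    "gaze_metrics",
    "iqr_filter",
    "compare_gaze",
    "MIN_FIXATION_MS",
    "MIN_VALID_SAMPLES",
]

NOMINAL_RATE_HZ = 60.0
MIN_FIXATION_MS = 50.0
#: shortest run (in samples at 60 Hz) that still counts as a fixation
MIN_FIXATION_SAMPLES = 3
MIN_VALID_SAMPLES = 400
SIDES = ("target", "other", "missing")


@dataclass
class GazeTrial:
    """One trial's gaze samples.

    ``sides`` holds "target"/"other"/"missing" per sample; ``tracked``
    flags whether the face-tracking succeeded for that sample.  A sample is
    *valid* when it is tracked and its side is not missing.
    """

    participant_id: str
    trial_id: str
    t_ms: np.ndarray
    sides: np.ndarray
    tracked: np.ndarray
    diagnosis: str = ""

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.sides = np.asarray(self.sides, dtype=object)
        self.tracked = np.asarray(self.tracked, dtype=bool)
        if not (len(self.t_ms) == len(self.sides) == len(self.tracked)):
            raise ValueError("sample arrays must share length")
        if np.any(np.diff(self.t_ms) < 0):
            raise ValueError("timestamps must be non-decreasing")
        bad = set(self.sides) - set(SIDES)
        if bad:
            raise ValueError(f"unknown side labels {bad}")

    @property
    def valid(self) -> np.ndarray:
        return self.tracked & (self.sides != "missing")

    def copy(self) -> "GazeTrial":
        return GazeTrial(
            self.participant_id,
            self.trial_id,
            self.t_ms.copy(),
            self.sides.copy(),
            self.tracked.copy(),
            self.diagnosis,
        )


@dataclass(frozen=True)
class GazeMetrics:
    """Screen-half metrics for one retained trial."""

    fixation_proportion_target: float
    switches_per_100: float


def _invalidate_short_fixations(trial: GazeTrial) -> GazeTrial:
    """Mark runs of same-side valid samples shorter than 50 ms as missing."""
    out = trial.copy()
    valid = out.valid
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        return out
    run_start = 0
    runs = []
    for k in range(1, idx.size + 1):
        if (
            k == idx.size
            or out.sides[idx[k]] != out.sides[idx[k - 1]]
            or idx[k] != idx[k - 1] + 1
        ):
            runs.append(idx[run_start:k])
            run_start = k
    for run in runs:
        if run.size < MIN_FIXATION_SAMPLES:
            out.sides[run] = "missing"
    return out


def preprocess_gaze(
    trials: Sequence[GazeTrial],
    min_track_fraction: float = 0.5,
    min_samples: int = MIN_VALID_SAMPLES,
    min_trial_fraction: float = 0.5,
) -> tuple[list[GazeTrial], list[str]]:
    """Quality filtering; returns (retained trials, excluded participant ids).

    1. trials whose face-tracked fraction is ``min_track_fraction`` *or
       less* are dropped;
    2. fixation runs shorter than 50 ms are invalidated (samples become
       missing);
    3. trials with fewer than ``min_samples`` valid samples are dropped;
    4. participants with fewer than ``min_trial_fraction`` of their trials
       left are excluded entirely.
    """
    per_participant_total: dict[str, int] = {}
    for t in trials:
        per_participant_total[t.participant_id] = (
            per_participant_total.get(t.participant_id, 0) + 1
        )

    surviving: list[GazeTrial] = []
    for t in trials:
        if len(t.t_ms) == 0:
            continue
        if t.tracked.mean() <= min_track_fraction:
            continue
        t = _invalidate_short_fixations(t)
        if int(t.valid.sum()) < min_samples:
            continue
        surviving.append(t)

    per_participant_kept: dict[str, int] = {}
    for t in surviving:
        per_participant_kept[t.participant_id] = (
            per_participant_kept.get(t.participant_id, 0) + 1
        )
    excluded = [
        pid
        for pid, total in per_participant_total.items()
        if per_participant_kept.get(pid, 0) / total < min_trial_fraction
    ]
    retained = [t for t in surviving if t.participant_id not in excluded]
    return retained, sorted(excluded)


def gaze_metrics(trial: GazeTrial) -> GazeMetrics:
    """Fixation proportion on the target half and switches per 100 valid samples.

    Switches are counted over the sequence of valid samples only: a missing
    gap between same-side runs does not create a switch; between
    different-side runs it counts once.
    """
    valid = trial.valid
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("trial has no valid samples (should be filtered out)")
    sides = trial.sides[valid]
    prop = float(np.mean(sides == "target"))
    switches = int(np.sum(sides[1:] != sides[:-1]))
    return GazeMetrics(
        fixation_proportion_target=prop,
        switches_per_100=switches * 100.0 / n_valid,
    )


def iqr_filter(values: np.ndarray) -> np.ndarray:
    """Remove values outside the Tukey fences [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles use linear interpolation; values exactly on a fence are kept.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 values")
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return values[(values >= lo) & (values <= hi)]


def compare_gaze(metrics: pd.DataFrame) -> dict:
    """Group comparisons of gaze metrics by target diagnosis, paired by participant.

    ``metrics`` needs columns participant_id, diagnosis ("autistic" /
    "non-autistic"), fixation_proportion_target and switches_per_100 (one
    row per retained trial).  Returns per-participant condition means, a
    one-sample JZS Bayes factor for the overall target-half proportion
    against 0.5, and paired JZS Bayes factors for the diagnosis contrast on
    both metrics.  Participants missing a condition are dropped (count
    reported).
    """
    wide = metrics.pivot_table(
        index="participant_id",
        columns="diagnosis",
        values=["fixation_proportion_target", "switches_per_100"],
        aggfunc="mean",
    )
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    if len(complete) < 2:
        raise ValueError("need at least 2 participants with both conditions")

    overall_prop = metrics.groupby("participant_id")[
        "fixation_proportion_target"
    ].mean()

    def one_sample_bf(x: np.ndarray, mu: float) -> float:
        x = np.asarray(x, dtype=float)
        sd = x.std(ddof=1)
        t = 0.0 if sd == 0 else (x.mean() - mu) / (sd / np.sqrt(len(x)))
        return jzs_bf(t, n=len(x), kind="one-sample").bf10

    report = {
        "n_participants": int(len(complete)),
        "n_dropped_incomplete": int(n_dropped),
        "mean_fixation_proportion_target": float(overall_prop.mean()),
        "bf10_proportion_vs_half": one_sample_bf(overall_prop.to_numpy(), 0.5),
    }
    for metric in ("fixation_proportion_target", "switches_per_100"):
        diff = (
            complete[(metric, "autistic")] - complete[(metric, "non-autistic")]
        ).to_numpy()
        report[f"bf10_diagnosis_{metric}"] = one_sample_bf(diff, 0.0)
        report[f"mean_autistic_{metric}"] = float(complete[(metric, "autistic")].mean())
        report[f"mean_nonautistic_{metric}"] = float(
            complete[(metric, "non-autistic")].mean()
        )
    return report
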