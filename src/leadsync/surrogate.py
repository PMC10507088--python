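"""Pseudosynchrony surrogates and the two validity checks.

Pseudosynchrony pairs each dyad's target stream with partner streams from
*other* dyads that never interacted; the resulting synchrony statistics form
the null reference against which genuine synchrony is compared.  Two checks
establish that the synchrony measure is meaningful:

1. *time dependency* — shuffling the temporal order of segments within a
   stream should destroy synchrony, so the genuine statistic should exceed
   the segment-shuffled one;
2. *synchrony in 10-s sections* — within short sections, genuine pairings
   should exceed shuffled pairings.

Both checks are summarized by a one-sample JZS Bayes factor on the per-dyad
effects (genuine minus surrogate mean).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from leadsync.stats import jzs_bf
from leadsync.synchrony import DyadRecording, windowed_lagged_ccf
from leadsync.videomotion import MotionEnergySeries

__all__ = [
    "SurrogateEnsemble",
    "mean_absolute_synchrony",
    "build_pseudo_dyads",
    "segment_shuffle",
    "pseudosynchrony_tests",
]

Statistic = Callable[[MotionEnergySeries, MotionEnergySeries], float]


@dataclass
class SurrogateEnsemble:
    """Genuine synchrony statistic of one dyad plus its surrogate null."""

    dyad_id: str
    genuine: float
    surrogates: np.ndarray
    n_iter: int
    scheme: str
    seed: int

    def __post_init__(self) -> None:
        self.surrogates = np.asarray(self.surrogates, dtype=float)
        if len(self.surrogates) != self.n_iter:
            raise ValueError("surrogate count must equal n_iter")
        if self.scheme not in ("pair-shuffle", "segment-shuffle"):
            raise ValueError(f"unknown scheme {self.scheme!r}")

    @property
    def effect(self) -> float:
        """Genuine statistic minus the surrogate mean."""
        return float(self.genuine - np.nanmean(self.surrogates))


def mean_absolute_synchrony(
    green: MotionEnergySeries,
    white: MotionEnergySeries,
    window_s: float = 10.0,
    increment_s: float = 10.0,
    max_lag_s: float = 2.0,
) -> float:
    """Mean Fisher-z |r| over all windows and lags: the default synchrony statistic."""
    ccf = windowed_lagged_ccf(
        green, white, window_s=window_s, increment_s=increment_s, max_lag_s=max_lag_s
    )
    if np.all(np.isnan(ccf.z)):
        return np.nan
    return float(np.nanmean(ccf.z))


def build_pseudo_dyads(
    dyads: Sequence[DyadRecording],
    n_iter: int = 1000,
    statistic: Statistic = mean_absolute_synchrony,
    seed: int = 0,
    replace: bool = True,
) -> list[SurrogateEnsemble]:
    """Pair-shuffle surrogate ensembles, one per dyad.

    For each dyad, the genuine statistic pairs its own green and white
    streams; each of the ``n_iter`` surrogates pairs the green stream with
    the white stream of a different dyad drawn uniformly with replacement
    (or, with ``replace=False``, distinct partners — useful when exact
    exchangeability of genuine and surrogates is wanted, e.g. for rank
    calibration).  Partner streams are drawn from dyads of the same source
    study when any exist (the two source studies differ systematically),
    otherwise from all other dyads.
    """
    if len(dyads) < 2:
        raise ValueError("need at least 2 dyads to form surrogate pairs")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")

    ensembles = []
    for i, dyad in enumerate(dyads):
        rng = np.random.default_rng([seed, i])
        candidates = [
            d for j, d in enumerate(dyads) if j != i and d.source == dyad.source
        ]
        if not candidates:
            candidates = [d for j, d in enumerate(dyads) if j != i]
        genuine = statistic(dyad.green, dyad.white)
        if replace:
            picks = rng.integers(0, len(candidates), size=n_iter)
        else:
            if n_iter > len(candidates):
                raise ValueError("n_iter exceeds candidate count with replace=False")
            picks = rng.permutation(len(candidates))[:n_iter]
        surrogates = np.array(
            [statistic(dyad.green, candidates[p].white) for p in picks]
        )
        ensembles.append(
            SurrogateEnsemble(
                dyad_id=dyad.dyad_id,
                genuine=genuine,
                surrogates=surrogates,
                n_iter=n_iter,
                scheme="pair-shuffle",
                seed=seed,
            )
        )
    return ensembles


def segment_shuffle(
    series: MotionEnergySeries, segment_s: float, seed: int = 0
) -> MotionEnergySeries:
    """Re-order contiguous segments of a series by a random non-identity permutation.

    The series is cut into segments of ``segment_s`` seconds (any trailing
    remainder stays attached to the last segment) and the segments are
    permuted uniformly at random, excluding the identity permutation, so
    the multiset of values is preserved while temporal structure across
    segments is destroyed.
    """
    seg_len = int(round(segment_s * series.fps))
    if seg_len < 1:
        raise ValueError("segment shorter than one frame")
    n_seg = len(series) // seg_len
    if n_seg < 2:
        raise ValueError("series must contain at least 2 segments")

    rng = np.random.default_rng(seed)
    bounds = [k * seg_len for k in range(n_seg)] + [len(series)]
    segments = [series.values[bounds[k] : bounds[k + 1]] for k in range(n_seg)]
    perm = rng.permutation(n_seg)
    while np.array_equal(perm, np.arange(n_seg)):
        perm = rng.permutation(n_seg)
    return series.copy_with(np.concatenate([segments[p] for p in perm]))


def build_segment_shuffle_ensembles(
    dyads: Sequence[DyadRecording],
    segment_s: float = 10.0,
    n_iter: int = 1000,
    statistic: Statistic = mean_absolute_synchrony,
    seed: int = 0,
) -> list[SurrogateEnsemble]:
    """Segment-shuffle ensembles for the time-dependency check.

    Each surrogate pairs the dyad's genuine green stream with a
    segment-shuffled copy of its own white stream: if synchrony depends on
    the shared temporal order, the genuine statistic should exceed the
    shuffled ones.
    """
    ensembles = []
    for i, dyad in enumerate(dyads):
        genuine = statistic(dyad.green, dyad.white)
        child_seeds = np.random.SeedSequence([seed, i]).generate_state(n_iter)
        surrogates = np.array(
            [
                statistic(dyad.green, segment_shuffle(dyad.white, segment_s, int(s)))
                for s in child_seeds
            ]
        )
        ensembles.append(
            SurrogateEnsemble(
                dyad_id=dyad.dyad_id,
                genuine=genuine,
                surrogates=surrogates,
                n_iter=n_iter,
                scheme="segment-shuffle",
                seed=seed,
            )
        )
    return ensembles


def pseudosynchrony_tests(ensembles: Sequence[SurrogateEnsemble]) -> dict:
    """Summarize a surrogate ensemble set as effects plus a one-sample Bayes factor.

    The per-dyad effect is genuine minus surrogate mean; the report carries
    the effects, their mean, the number of usable dyads and BF10 from a
    one-sample JZS t-test of the effects against zero.  Dyads with missing
    statistics are excluded and counted.
    """
    if len(ensembles) < 2:
        raise ValueError("need at least 2 dyads")
    effects = np.array([e.effect for e in ensembles])
    ok = np.isfinite(effects)
    n_excluded = int((~ok).sum())
    effects = effects[ok]
    if len(effects) < 2:
        raise ValueError("fewer than 2 dyads with finite effects")

    mean = float(np.mean(effects))
    sd = float(np.std(effects, ddof=1))
    if sd == 0.0:
        t = 0.0 if mean == 0.0 else np.inf
    else:
        t = mean / (sd / np.sqrt(len(effects)))
    if not np.isfinite(t):
        raise ValueError("degenerate effects: zero variance with nonzero mean")
    bf = jzs_bf(t, n=len(effects), kind="one-sample")
    return {
        "effects": effects,
        "mean_effect": mean,
        "t": t,
        "bf10": bf.bf10,
        "n_dyads": int(len(effects)),
        "n_excluded": n_excluded,
        "scheme": ensembles[0].scheme,
    }
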