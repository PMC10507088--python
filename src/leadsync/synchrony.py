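"""Preprocessing and lead-lag decomposition of motion-energy series.

The synchrony measure is a windowed lagged cross-correlation between the two
interactants' motion-energy series.  Correlations at positive lags, where the
target ("green") interactant's motion precedes their partner's, quantify how
much green leads; negative lags quantify white leading.  Lag-0 captures
simultaneous coordination.

Conventions
-----------
* Missing values are NaN and propagate by pairwise deletion within windows.
* Standard deviations use the sample convention (ddof=1), matching the R
  ecosystem this preprocessing mirrors.
* Positive lag ``l`` correlates green at ``t`` with white at ``t + l``:
  green precedes, hence green leads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from leadsync.videomotion import MotionEnergySeries

__all__ = [
    "DyadRecording",
    "CcfMatrix",
    "LeadingScores",
    "remove_outliers",
    "scale_series",
    "extract_excerpts",
    "windowed_lagged_ccf",
    "leading_scores",
    "dyad_leading_scores",
    "LOG_EPSILON",
]

#: guard added inside the natural log so zero leading scores stay finite
LOG_EPSILON = 1e-6

#: Fisher-z clamp: |r| is capped here before atanh
R_CLAMP = 0.9999


class DegenerateSeriesError(ValueError):
    """Raised when a series has zero variance where variance is required."""


@dataclass
class DyadRecording:
    """Paired motion-energy series for one dyad.

    ``green`` is the target interactant (rated by participants); ``white``
    is the conversation partner.  ``diagnosis_of_target`` is ``"autistic"``
    or ``"non-autistic"``; ``source`` labels the source study ("A" or "B").
    """

    dyad_id: str
    green: MotionEnergySeries
    white: MotionEnergySeries
    diagnosis_of_target: str
    source: str

    def __post_init__(self) -> None:
        if len(self.green) != len(self.white):
            raise ValueError("green and white series must have equal length")
        if self.green.fps != self.white.fps:
            raise ValueError("green and white series must share fps")
        if self.diagnosis_of_target not in ("autistic", "non-autistic"):
            raise ValueError(f"bad diagnosis {self.diagnosis_of_target!r}")
        if self.source not in ("A", "B"):
            raise ValueError(f"bad source {self.source!r}")

    @property
    def fps(self) -> float:
        return self.green.fps


@dataclass
class CcfMatrix:
    """Window x lag matrix of (optionally Fisher-z) cross-correlations.

    ``z[w, i]`` is the correlation of green with white shifted by
    ``lags[i]`` frames within window ``w``; NaN marks undefined entries.
    ``lags`` runs symmetrically from ``-max_lag`` to ``+max_lag``.
    """

    z: np.ndarray
    lags: np.ndarray
    window_spans: list[tuple[int, int]]
    fisher_z: bool = True
    use_abs: bool = True

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.lags = np.asarray(self.lags, dtype=int)
        if self.z.shape != (len(self.window_spans), len(self.lags)):
            raise ValueError("z shape inconsistent with windows and lags")
        if not np.array_equal(self.lags, -self.lags[::-1]):
            raise ValueError("lags must be symmetric about 0")


@dataclass
class LeadingScores:
    """Scalar lead-lag summaries for one excerpt of one dyad."""

    green_leading: float
    white_leading: float
    zero_lag: float
    green_leading_log: float = np.nan
    white_leading_log: float = np.nan
    motion_green: float = np.nan
    motion_white: float = np.nan

    def __post_init__(self) -> None:
        if np.isnan(self.green_leading_log) and np.isfinite(self.green_leading):
            self.green_leading_log = float(np.log(self.green_leading + LOG_EPSILON))
        if np.isnan(self.white_leading_log) and np.isfinite(self.white_leading):
            self.white_leading_log = float(np.log(self.white_leading + LOG_EPSILON))


def _sd(values: np.ndarray) -> float:
    finite = values[np.isfinite(values)]
    if finite.size < 2:
        return 0.0
    return float(np.std(finite, ddof=1))


def remove_outliers(series: MotionEnergySeries, k: float = 10.0) -> MotionEnergySeries:
    """Replace values more than ``k`` standard deviations with NaN.

    The threshold is ``k * SD`` of the original series (sample SD over
    non-missing values).  A constant series (SD = 0) is returned unchanged:
    a zero threshold would mark every positive value an outlier, so zero SD
    is treated as "no finite threshold".
    """
    if len(series) == 0:
        raise ValueError("series is empty")
    if k <= 0:
        raise ValueError("k must be positive")
    sd = _sd(series.values)
    if sd == 0.0:
        return series.copy_with(series.values.copy())
    out = series.values.copy()
    out[out > k * sd] = np.nan
    return series.copy_with(out)


def scale_series(series: MotionEnergySeries) -> MotionEnergySeries:
    """Divide every non-missing value by the series SD (output SD = 1)."""
    sd = _sd(series.values)
    if sd == 0.0:
        raise DegenerateSeriesError(
            f"series {series.roi_label or '<unnamed>'} has zero variance"
        )
    return series.copy_with(series.values / sd)


def extract_excerpts(
    series: MotionEnergySeries,
    spans: list[tuple[float, float]] = ((90.0, 100.0), (240.0, 250.0)),
) -> list[MotionEnergySeries]:
    """Frame-accurate slices for half-open time spans ``[start, end)`` in seconds."""
    out = []
    n = len(series)
    for start_s, end_s in spans:
        if start_s < 0 or end_s <= start_s:
            raise ValueError(f"invalid span ({start_s}, {end_s})")
        i0 = int(round(start_s * series.fps))
        i1 = int(round(end_s * series.fps))
        if i1 > n:
            raise ValueError(
                f"span ({start_s}, {end_s}) s exceeds series duration "
                f"{n / series.fps:.2f} s"
            )
        out.append(series.copy_with(series.values[i0:i1]))
    return out


def _pearson_pairwise(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r over pairwise non-missing samples; NaN if undefined."""
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return np.nan
    xv, yv = x[ok], y[ok]
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return np.nan
    return float((xc @ yc) / denom)


def windowed_lagged_ccf(
    green: MotionEnergySeries,
    white: MotionEnergySeries,
    window_s: float = 10.0,
    increment_s: float = 10.0,
    max_lag_s: float = 2.0,
    use_abs: bool = True,
    fisher_z: bool = True,
) -> CcfMatrix:
    """Windowed lagged cross-correlation matrix between two series.

    For each window and each integer frame lag ``l`` in
    ``[-max_lag, +max_lag]``, computes the Pearson correlation between
    ``green[t]`` and ``white[t + l]`` over the window's overlapping,
    pairwise non-missing samples.  Entries from windows with fewer than
    3 valid pairs, or with a constant segment, are NaN.

    With ``use_abs`` the absolute correlation is taken (synchrony
    regardless of sign); with ``fisher_z`` the result is variance-
    stabilized by atanh after clamping ``|r|`` at 0.9999.
    """
    if len(green) != len(white):
        raise ValueError("series must have equal length")
    if green.fps != white.fps:
        raise ValueError("series must share fps")
    n = len(green)
    fps = green.fps
    window = int(round(window_s * fps))
    increment = int(round(increment_s * fps))
    max_lag = int(round(max_lag_s * fps))
    if window > n:
        raise ValueError("window longer than series")
    if max_lag < 1:
        raise ValueError("max_lag must be at least one frame")
    if increment < 1:
        raise ValueError("increment must be at least one frame")

    lags = np.arange(-max_lag, max_lag + 1)
    starts = range(0, n - window + 1, increment)
    spans = [(s, s + window) for s in starts]
    z = np.full((len(spans), len(lags)), np.nan)

    g = green.values
    w = white.values
    for wi, (s0, s1) in enumerate(spans):
        for li, lag in enumerate(lags):
            t0 = max(s0, -lag)
            t1 = min(s1, n - lag)
            if t1 - t0 < 3:
                continue
            r = _pearson_pairwise(g[t0:t1], w[t0 + lag : t1 + lag])
            if np.isnan(r):
                continue
            if use_abs:
                r = abs(r)
            if fisher_z:
                r = float(np.arctanh(np.clip(r, -R_CLAMP, R_CLAMP)))
            z[wi, li] = r
    return CcfMatrix(z=z, lags=lags, window_spans=spans, fisher_z=fisher_z, use_abs=use_abs)


def leading_scores(
    ccf: CcfMatrix,
    aggregate: str = "mean",
    motion_green: float = np.nan,
    motion_white: float = np.nan,
) -> LeadingScores:
    """Collapse a cross-correlation matrix into per-interactant leading scores.

    ``green_leading`` aggregates entries at positive lags (green precedes),
    ``white_leading`` at negative lags, ``zero_lag`` at lag 0; NaN entries
    are ignored.  ``aggregate`` is ``"mean"`` (default) or ``"peak"``
    (maximum over windows and lags).  Log transforms use
    ``log(score + 1e-6)``.
    """
    if aggregate not in ("mean", "peak"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    agg = np.nanmean if aggregate == "mean" else np.nanmax

    def _side(mask: np.ndarray) -> float:
        vals = ccf.z[:, mask]
        if np.all(np.isnan(vals)):
            warnings.warn("all entries missing on one lag side", stacklevel=2)
            return np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return float(agg(vals))

    return LeadingScores(
        green_leading=_side(ccf.lags > 0),
        white_leading=_side(ccf.lags < 0),
        zero_lag=_side(ccf.lags == 0),
        motion_green=motion_green,
        motion_white=motion_white,
    )


def dyad_leading_scores(
    dyad: DyadRecording,
    spans: list[tuple[float, float]] = ((90.0, 100.0), (240.0, 250.0)),
    outlier_k: float = 10.0,
    window_s: float = 10.0,
    increment_s: float = 10.0,
    max_lag_s: float = 2.0,
    aggregate: str = "mean",
) -> list[LeadingScores]:
    """Full preprocessing chain for one dyad: one LeadingScores per excerpt.

    Applies outlier removal and scaling to each full series, slices the
    configured excerpts, and computes windowed lagged cross-correlations
    per excerpt.  Motion means are taken over each (unscaled) excerpt.
    """
    green_raw = remove_outliers(dyad.green, k=outlier_k)
    white_raw = remove_outliers(dyad.white, k=outlier_k)
    green = scale_series(green_raw)
    white = scale_series(white_raw)

    out = []
    for (g, w, g_raw, w_raw) in zip(
        extract_excerpts(green, spans),
        extract_excerpts(white, spans),
        extract_excerpts(green_raw, spans),
        extract_excerpts(white_raw, spans),
    ):
        ccf = windowed_lagged_ccf(
            g, w, window_s=window_s, increment_s=increment_s, max_lag_s=max_lag_s
        )
        out.append(
            leading_scores(
                ccf,
                aggregate=aggregate,
                motion_green=float(np.nanmean(g_raw.values)),
                motion_white=float(np.nanmean(w_raw.values)),
            )
        )
    return out
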