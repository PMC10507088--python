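"""Synthetic-data generators for every input the pipeline consumes.

The generators emulate the statistical structure the analysis assumes:
non-negative bursty motion-energy series with a lagged linear influence of
one interactant on the other, trial-level ratings from the mixed-model
structure with crossed random effects, two-state gaze streams with dropout,
and participant screening tables.  Every generator is a pure function of its
config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from leadsync.gaze import GazeTrial
from leadsync.impression import RATING_COLUMNS, ParticipantRecord, reverse_awkward
from leadsync.mixedmodel import MAIN_COEFFICIENTS, TrialRecord
from leadsync.synchrony import DyadRecording
from leadsync.videomotion import FrameSequence, MotionEnergySeries

__all__ = [
    "DyadSimConfig",
    "RatingSimConfig",
    "simulate_dyad_motion",
    "simulate_dyad_video",
    "simulate_ratings",
    "simulate_gaze",
    "simulate_participants",
    "trial_records",
]


@dataclass(frozen=True)
class DyadSimConfig:
    """Coupled burst-process model of two interactants' motion energy.

    Stream A (green) is a Poisson burst process: onsets at ``burst_rate``
    per second, exponentially distributed amplitudes decaying with time
    constant ``burst_decay_s``, plus truncated Gaussian noise.  Stream B
    (white) mixes its own independent burst process with A delayed by
    ``influence_lag`` frames, weighted by the coupling ``c``:

        B[t] = (1 - c) * own[t] + c * A[t - lag] + noise,  floored at 0.

    ``c = 0`` gives independent streams; larger ``c`` makes green lead.
    Defaults match the study recordings: 5-minute videos at 25 fps.
    """

    n_frames: int = 7500
    fps: float = 25.0
    burst_rate: float = 0.4
    burst_amplitude: float = 1.0
    burst_decay_s: float = 0.5
    coupling: float = 0.0
    influence_lag: int = 12
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.coupling < 1:
            raise ValueError("coupling must lie in [0, 1) for stability")
        if self.influence_lag < 1:
            raise ValueError("influence lag must be at least one frame")
        if self.fps <= 0 or self.n_frames < 2:
            raise ValueError("invalid frame configuration")


@dataclass(frozen=True)
class RatingSimConfig:
    """Generative twin of the impression mixed model.

    ``beta`` follows the fixed-effect layout of the main model (intercept,
    diagnosis, green leading, white leading, green x white, diagnosis x
    green, diagnosis x white, three-way, motion green, motion white,
    source).  Outcomes are clipped to the 0–100 rating scale; the clipping
    rate is recorded on the returned frame.  ``item_noise_sd`` (default 10
    points) perturbs the six individual ratings around the latent score,
    which keeps large-sample one-factor fits high, as observed for the real
    ratings.
    """

    n_participants: int = 196
    n_stimuli: int = 44
    beta: tuple = (50.0, -4.0, 4.0, -1.0, 0.0, -6.0, 1.0, 0.0, 1.0, 1.0, 2.0)
    sd_participant: float = 5.0
    sd_stimulus: float = 5.0
    sd_slopes: float = 2.0
    sd_residual: float = 15.0
    item_noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.beta) != len(MAIN_COEFFICIENTS):
            raise ValueError(f"beta must have {len(MAIN_COEFFICIENTS)} entries")
        for name in ("sd_participant", "sd_stimulus", "sd_slopes", "sd_residual", "item_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _burst_process(rng: np.random.Generator, cfg: DyadSimConfig) -> np.ndarray:
    n = cfg.n_frames
    p_onset = cfg.burst_rate / cfg.fps
    onsets = rng.random(n) < p_onset
    amps = np.where(onsets, rng.exponential(cfg.burst_amplitude, size=n), 0.0)
    decay = np.exp(-np.arange(int(5 * cfg.burst_decay_s * cfg.fps) + 1) / (cfg.burst_decay_s * cfg.fps))
    series = np.convolve(amps, decay)[:n]
    noise = np.clip(rng.normal(0.0, cfg.noise_sd, size=n), 0.0, None)
    return series + noise


def simulate_dyad_motion(
    config: DyadSimConfig,
    dyad_id: str = "sim",
    diagnosis: str = "non-autistic",
    source: str = "A",
) -> DyadRecording:
    """Simulate one dyad's paired motion-energy series.

    Bit-reproducible under a fixed seed; all values are non-negative.
    """
    rng = np.random.default_rng(config.seed)
    a = _burst_process(rng, config)
    own_b = _burst_process(rng, config)
    c = config.coupling
    lag = config.influence_lag
    shifted = np.zeros_like(a)
    shifted[lag:] = a[:-lag]
    b = np.clip((1.0 - c) * own_b + c * shifted, 0.0, None)
    fps = config.fps
    return DyadRecording(
        dyad_id=dyad_id,
        green=MotionEnergySeries(values=a, fps=fps, roi_label="head-green", person_id=f"{dyad_id}-green"),
        white=MotionEnergySeries(values=b, fps=fps, roi_label="head-white", person_id=f"{dyad_id}-white"),
        diagnosis_of_target=diagnosis,
        source=source,
    )


def _draw_ellipse(frame: np.ndarray, cy: float, cx: float, ry: float, rx: float) -> None:
    h, w = frame.shape
    yy, xx = np.ogrid[:h, :w]
    mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    frame[mask] = 255.0


def simulate_dyad_video(
    green_profile: MotionEnergySeries,
    white_profile: MotionEnergySeries,
    canvas: tuple[int, int] = (64, 128),
    step_scale: float = 1.0,
) -> FrameSequence:
    """Render two ellipses whose per-frame displacement follows the profiles.

    The green ellipse lives on the left half, the white one on the right;
    each frame, an ellipse moves vertically by ``step_scale`` times its
    profile value, bouncing at the frame borders so motion stays inside its
    half.  A zero profile yields a static video (motion energy 0).
    """
    if len(green_profile) != len(white_profile):
        raise ValueError("profiles must share length")
    h, w = canvas
    ry, rx = h / 8.0, w / 12.0
    max_step = h / 2.0 - ry
    steps_g = step_scale * green_profile.values
    steps_w = step_scale * white_profile.values
    if np.nanmax(np.abs(np.concatenate([steps_g, steps_w]))) > max_step:
        raise ValueError("per-frame displacement exceeds half-canvas; lower step_scale")

    n = len(green_profile) + 1
    frames = np.zeros((n, h, w))
    pos = {"g": h / 2.0, "w": h / 2.0}
    direction = {"g": 1.0, "w": 1.0}
    cx = {"g": w / 4.0, "w": 3 * w / 4.0}
    for t in range(n):
        if t > 0:
            for key, steps in (("g", steps_g), ("w", steps_w)):
                new = pos[key] + direction[key] * steps[t - 1]
                if new + ry > h or new - ry < 0:
                    direction[key] *= -1.0
                    new = pos[key] + direction[key] * steps[t - 1]
                pos[key] = float(np.clip(new, ry, h - ry))
        _draw_ellipse(frames[t], pos["g"], cx["g"], ry, rx)
        _draw_ellipse(frames[t], pos["w"], cx["w"], ry, rx)
    return FrameSequence(frames=frames, fps=green_profile.fps)


def simulate_ratings(
    config: RatingSimConfig, predictors: pd.DataFrame
) -> pd.DataFrame:
    """Simulate trial-level ratings from the mixed-model structure.

    ``predictors`` has one row per stimulus with columns stimulus_id,
    diagnosis, green_leading_log, white_leading_log, motion_green,
    motion_white, source.  Continuous predictors are z-scored across
    stimuli before entering the linear predictor, mirroring the model fit.

    Returns a trial frame (participant x stimulus) with the latent score,
    the six derived ratings (item noise added, awkwardness reverse-coded)
    and every TrialRecord column; ``frame.attrs["clip_rate"]`` records the
    fraction of latent scores clipped to [0, 100].
    """
    rng = np.random.default_rng(config.seed)
    pred = predictors.reset_index(drop=True)
    n_stim = len(pred)
    if n_stim != config.n_stimuli:
        raise ValueError("predictor rows must match n_stimuli")

    def z(col: np.ndarray) -> np.ndarray:
        sd = col.std(ddof=1)
        return (col - col.mean()) / sd if sd > 0 else col - col.mean()

    g = z(pred["green_leading_log"].to_numpy(float))
    w = z(pred["white_leading_log"].to_numpy(float))
    mg = z(pred["motion_green"].to_numpy(float))
    mw = z(pred["motion_white"].to_numpy(float))
    d = pred["diagnosis"].to_numpy(float)
    s = pred["source"].to_numpy(float)
    X_stim = np.column_stack([np.ones(n_stim), d, g, w, g * w, d * g, d * w, d * g * w, mg, mw, s])
    stim_lin = X_stim @ np.asarray(config.beta)

    n_p = config.n_participants
    u_p = rng.normal(0, config.sd_participant, n_p)
    u_pd = rng.normal(0, config.sd_slopes, n_p)
    u_ps = rng.normal(0, config.sd_slopes, n_p)
    u_st = rng.normal(0, config.sd_stimulus, n_stim)

    pi = np.repeat(np.arange(n_p), n_stim)
    si = np.tile(np.arange(n_stim), n_p)
    latent = (
        stim_lin[si]
        + u_p[pi]
        + u_pd[pi] * d[si]
        + u_ps[pi] * s[si]
        + u_st[si]
        + rng.normal(0, config.sd_residual, n_p * n_stim)
    )
    clipped = np.clip(latent, 0.0, 100.0)
    clip_rate = float(np.mean(latent != clipped))

    df = pd.DataFrame(
        {
            "participant_id": [f"p{i:03d}" for i in pi],
            "stimulus_id": pred["stimulus_id"].to_numpy()[si],
            "score": clipped,
            "diagnosis": d[si].astype(int),
            "green_leading_log": pred["green_leading_log"].to_numpy(float)[si],
            "white_leading_log": pred["white_leading_log"].to_numpy(float)[si],
            "motion_green": pred["motion_green"].to_numpy(float)[si],
            "motion_white": pred["motion_white"].to_numpy(float)[si],
            "source": s[si].astype(int),
        }
    )
    # six observed ratings around the latent score; awkwardness reverse-coded
    for name in RATING_COLUMNS:
        noisy = np.clip(
            clipped + rng.normal(0, config.item_noise_sd, len(clipped)), 0.0, 100.0
        )
        df[name] = reverse_awkward(noisy) if name == "awkward" else noisy
    df.attrs["clip_rate"] = clip_rate
    return df


def trial_records(df: pd.DataFrame) -> list[TrialRecord]:
    """Convert a simulated trial frame into TrialRecord objects."""
    return [
        TrialRecord(
            participant_id=r.participant_id,
            stimulus_id=r.stimulus_id,
            score=r.score,
            diagnosis=int(r.diagnosis),
            green_leading_log=r.green_leading_log,
            white_leading_log=r.white_leading_log,
            motion_green=r.motion_green,
            motion_white=r.motion_white,
            source=int(r.source),
            aq_group=int(getattr(r, "aq_group", 0)),
        )
        for r in df.itertuples(index=False)
    ]


def simulate_gaze(
    p_target: float = 0.65,
    switch_rate: float = 0.06,
    dropout: float = 0.1,
    n_samples: int = 600,
    seed: int = 0,
    participant_id: str = "p000",
    trial_id: str = "t00",
    diagnosis: str = "non-autistic",
) -> GazeTrial:
    """Two-state Markov gaze stream with dropout.

    The chain over {target, other} has stationary target probability
    ``p_target``; ``switch_rate`` scales the transition propensity (0 means
    the stream never leaves its initial side).  Dropped samples (probability
    ``dropout`` each, independent) are marked untracked and missing.
    Samples are stamped at the nominal 60 Hz.
    """
    for name, v in (("p_target", p_target), ("switch_rate", switch_rate), ("dropout", dropout)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p_leave_target = min(1.0, 2.0 * switch_rate * (1.0 - p_target))
    p_leave_other = min(1.0, 2.0 * switch_rate * p_target)

    sides = np.empty(n_samples, dtype=object)
    state = "target" if rng.random() < p_target else "other"
    for i in range(n_samples):
        sides[i] = state
        leave = p_leave_target if state == "target" else p_leave_other
        if rng.random() < leave:
            state = "other" if state == "target" else "target"
    dropped = rng.random(n_samples) < dropout
    tracked = ~dropped
    sides[dropped] = "missing"
    t_ms = np.arange(n_samples) * (1000.0 / 60.0)
    return GazeTrial(
        participant_id=participant_id,
        trial_id=trial_id,
        t_ms=t_ms,
        sides=sides,
        tracked=tracked,
        diagnosis=diagnosis,
    )


def simulate_participants(
    n: int = 247,
    p_high_aq: float = 49 / 247,
    p_low_wst: float = 1 / 247,
    p_flag: float = 1 / 247,
    seed: int = 0,
) -> list[ParticipantRecord]:
    """Participant screening tables with configurable exclusion rates.

    Defaults reproduce the study's composition in expectation: of 247
    collected datasets, one flagged not-conscientious, one low verbal IQ
    and 49 high AQ-10, leaving about 196 included.
    """
    for name, v in (("p_high_aq", p_high_aq), ("p_low_wst", p_low_wst), ("p_flag", p_flag)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        conscientious = rng.random() >= p_flag
        wst = int(rng.integers(0, 6)) if rng.random() < p_low_wst else int(rng.integers(6, 43))
        aq10 = int(rng.integers(6, 11)) if rng.random() < p_high_aq else int(rng.integers(0, 6))
        out.append(
            ParticipantRecord(
                participant_id=f"p{i:03d}",
                age=float(rng.integers(18, 61)),
                gender=str(rng.choice(["female", "male", "diverse"], p=[0.7, 0.28, 0.02])),
                aq10=aq10,
                wst=wst,
                conscientious=bool(conscientious),
            )
        )
    return out
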