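"""End-to-end orchestration with config, logging and manifest tracking.

The pipeline chains the stages

    simulate -> sync -> surrogate -> score -> fit -> gaze

over either synthetic inputs (generated by the ``simulate`` stage) or
precomputed CSVs.  Every threshold of the analysis has a config key whose
default is the study's value; a JSON manifest records the config hash, the
seeds and per-stage row counts so a rerun with identical config and seeds
reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import leadsync
from leadsync import io as lio
from leadsync.gaze import compare_gaze, gaze_metrics, preprocess_gaze
from leadsync.impression import (
    RATING_COLUMNS,
    RatingRecord,
    composite_impression,
    filter_participants,
    unidimensionality_fit,
)
from leadsync.mixedmodel import build_design, evaluate_hypotheses, fit_bayes_lmm
from leadsync.surrogate import build_pseudo_dyads, pseudosynchrony_tests
from leadsync.synchrony import dyad_leading_scores
from leadsync.synthetic import (
    DyadSimConfig,
    RatingSimConfig,
    simulate_dyad_motion,
    simulate_gaze,
    simulate_participants,
    simulate_ratings,
)

logger = logging.getLogger("leadsync")

ALL_STAGES = ("simulate", "sync", "surrogate", "score", "fit", "gaze")


@dataclass
class PipelineConfig:
    """Every tunable of the analysis, with the study's values as defaults."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    fps: float = 25.0
    # simulation
    n_dyads: int = 22
    recording_s: float = 300.0
    coupling_autistic: float = 0.2
    coupling_nonautistic: float = 0.5
    influence_lag: int = 12
    n_participants: int = 196
    gaze_p_target: float = 0.65
    gaze_switch_rate: float = 0.06
    gaze_dropout: float = 0.15
    # preprocessing (study values)
    outlier_k: float = 10.0
    excerpt_spans: tuple = ((90.0, 100.0), (240.0, 250.0))
    window_s: float = 10.0
    increment_s: float = 10.0
    max_lag_s: float = 2.0
    # surrogates
    n_surrogate_iter: int = 1000
    # model (study values)
    chains: int = 4
    iterations: int = 10000
    warmup_fraction: float = 0.5
    formula_variant: str = "main"
    credibility_threshold: float = 0.975
    export_draws: bool = False
    # gaze thresholds (study values)
    min_track_fraction: float = 0.5
    min_gaze_samples: int = 400
    min_trial_fraction: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.excerpt_spans, list):
            cfg.excerpt_spans = tuple(tuple(s) for s in cfg.excerpt_spans)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _simulate_stage(cfg: PipelineConfig, out: Path) -> dict:
    n_frames = int(cfg.recording_s * cfg.fps)
    dyads, meta = [], []
    for i in range(cfg.n_dyads):
        diagnosis = "autistic" if i % 2 == 0 else "non-autistic"
        source = "A" if i < cfg.n_dyads * 24 // 44 else "B"
        coupling = (
            cfg.coupling_autistic if diagnosis == "autistic" else cfg.coupling_nonautistic
        )
        dyads.append(
            simulate_dyad_motion(
                DyadSimConfig(
                    n_frames=n_frames,
                    fps=cfg.fps,
                    coupling=coupling,
                    influence_lag=cfg.influence_lag,
                    seed=int(np.random.SeedSequence([cfg.seed, 1, i]).generate_state(1)[0] % 2**31),
                ),
                dyad_id=f"d{i:02d}",
                diagnosis=diagnosis,
                source=source,
            )
        )
        meta.append({"dyad_id": f"d{i:02d}", "diagnosis": diagnosis, "source": source})
    lio.write_motion_csv(out / "motion_energy.csv", dyads)
    pd.DataFrame(meta).to_csv(out / "dyads.csv", index=False)

    participants = simulate_participants(seed=cfg.seed + 2)
    lio.write_participants_csv(out / "participants.csv", participants)

    gaze_trials = []
    for p in range(min(cfg.n_participants, 40)):  # gaze table kept small
        for i, m in enumerate(meta):
            gaze_trials.append(
                simulate_gaze(
                    p_target=cfg.gaze_p_target,
                    switch_rate=cfg.gaze_switch_rate,
                    dropout=cfg.gaze_dropout,
                    seed=int(np.random.SeedSequence([cfg.seed, 3, p, i]).generate_state(1)[0] % 2**31),
                    participant_id=f"p{p:03d}",
                    trial_id=m["dyad_id"],
                    diagnosis=m["diagnosis"],
                )
            )
    lio.write_gaze_csv(out / "gaze.csv", gaze_trials)
    return {"n_dyads": len(dyads), "n_participants": len(participants), "n_gaze_trials": len(gaze_trials)}


def _sync_stage(cfg: PipelineConfig, out: Path) -> dict:
    meta = pd.read_csv(out / "dyads.csv")
    dyads = lio.read_motion_csv(out / "motion_energy.csv", fps=cfg.fps, meta=meta)
    rows = []
    for d in dyads:
        for e, scores in enumerate(
            dyad_leading_scores(
                d,
                spans=cfg.excerpt_spans,
                outlier_k=cfg.outlier_k,
                window_s=cfg.window_s,
                increment_s=cfg.increment_s,
                max_lag_s=cfg.max_lag_s,
            )
        ):
            rows.append((d, e, scores))
    df = lio.leading_scores_frame(rows)
    df.to_csv(out / "leading_scores.csv", index=False, float_format=lio.FLOAT_FORMAT)
    return {"n_stimuli": len(df)}


def _surrogate_stage(cfg: PipelineConfig, out: Path) -> dict:
    meta = pd.read_csv(out / "dyads.csv")
    dyads = lio.read_motion_csv(out / "motion_energy.csv", fps=cfg.fps, meta=meta)
    ensembles = build_pseudo_dyads(dyads, n_iter=cfg.n_surrogate_iter, seed=cfg.seed + 4)
    report = pseudosynchrony_tests(ensembles)
    pd.DataFrame(
        {"dyad_id": [e.dyad_id for e in ensembles], "effect": [e.effect for e in ensembles]}
    ).to_csv(out / "surrogate_effects.csv", index=False, float_format=lio.FLOAT_FORMAT)
    summary = {k: v for k, v in report.items() if k != "effects"}
    with open(out / "surrogate_report.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return {"surrogate_bf10": report["bf10"]}


def _score_stage(cfg: PipelineConfig, out: Path) -> dict:
    predictors = pd.read_csv(out / "leading_scores.csv")
    predictors = predictors.assign(
        diagnosis=(predictors["diagnosis"] == "autistic").astype(int),
        source=(predictors["source"] == "B").astype(int),
    )
    trials = simulate_ratings(
        RatingSimConfig(n_participants=cfg.n_participants, n_stimuli=len(predictors), seed=cfg.seed + 5),
        predictors,
    )
    # recompute the composite from the six observed ratings
    trials["score"] = [
        composite_impression(
            RatingRecord(r.participant_id, r.stimulus_id, r.intelligent, r.awkward,
                         r.likeable, r.trustworthy, r.conversation, r.friends)
        )
        for r in trials.itertuples(index=False)
    ]
    fit = unidimensionality_fit(trials[list(RATING_COLUMNS)])
    participants = lio.read_participants_csv(out / "participants.csv")
    included, excluded = filter_participants(participants)
    trials.to_csv(out / "scored_trials.csv", index=False, float_format=lio.FLOAT_FORMAT)
    pd.DataFrame(
        [{"participant_id": r.participant_id, "reason": reason} for r, reason in excluded]
    ).to_csv(out / "exclusions.csv", index=False)
    return {
        "n_trials": len(trials),
        "unidimensionality_fit": fit,
        "n_included": len(included),
        "n_excluded": len(excluded),
    }


def _fit_stage(cfg: PipelineConfig, out: Path) -> dict:
    trials = pd.read_csv(out / "scored_trials.csv")
    design = build_design(trials, formula_variant=cfg.formula_variant)
    fit = fit_bayes_lmm(
        design,
        chains=cfg.chains,
        iterations=cfg.iterations,
        warmup_fraction=cfg.warmup_fraction,
        seed=cfg.seed + 6,
    )
    hyps = evaluate_hypotheses(fit, threshold=cfg.credibility_threshold)
    table = pd.DataFrame(
        [
            {
                "coefficient": name,
                "estimate": h.estimate,
                "ci_low": h.ci_low,
                "ci_high": h.ci_high,
                "posterior_probability": h.posterior_probability,
                "evidence_ratio": h.evidence_ratio,
                "direction": h.direction,
                "credible": h.credible,
            }
            for name, h in hyps.items()
        ]
    )
    table.to_csv(out / "hypotheses.csv", index=False, float_format=lio.FLOAT_FORMAT)
    if cfg.export_draws:
        fit.to_frame().to_csv(out / "posterior_draws.csv", index=False, float_format="%.6g")
    return {"n_coefficients": len(table), "max_rhat": float(np.nanmax(list(fit.rhat.values())))}


def _gaze_stage(cfg: PipelineConfig, out: Path) -> dict:
    trials = lio.read_gaze_csv(out / "gaze.csv")
    retained, excluded = preprocess_gaze(
        trials,
        min_track_fraction=cfg.min_track_fraction,
        min_samples=cfg.min_gaze_samples,
        min_trial_fraction=cfg.min_trial_fraction,
    )
    rows = []
    for t in retained:
        m = gaze_metrics(t)
        rows.append(
            {
                "participant_id": t.participant_id,
                "trial_id": t.trial_id,
                "diagnosis": t.diagnosis,
                "fixation_proportion_target": m.fixation_proportion_target,
                "switches_per_100": m.switches_per_100,
            }
        )
    metrics = pd.DataFrame(rows)
    metrics.to_csv(out / "gaze_metrics.csv", index=False, float_format=lio.FLOAT_FORMAT)
    report = compare_gaze(metrics) if len(metrics) else {}
    report["n_excluded_participants"] = len(excluded)
    with open(out / "gaze_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return {"n_gaze_retained": len(retained), "n_gaze_excluded_participants": len(excluded)}


_STAGE_FUNCS = {
    "simulate": _simulate_stage,
    "sync": _sync_stage,
    "surrogate": _surrogate_stage,
    "score": _score_stage,
    "fit": _fit_stage,
    "gaze": _gaze_stage,
}

_STAGE_INPUTS = {
    "sync": ("motion_energy.csv", "dyads.csv"),
    "surrogate": ("motion_energy.csv", "dyads.csv"),
    "score": ("leading_scores.csv", "participants.csv"),
    "fit": ("scored_trials.csv",),
    "gaze": ("gaze.csv",),
}


def run_pipeline(
    config: PipelineConfig,
    mode: str = "series",
    stages: tuple[str, ...] | None = None,
) -> dict:
    """Execute the requested stages in order and write the run manifest.

    ``mode="series"`` starts from motion-energy series (CSV or simulated);
    ``mode="video"`` would additionally decode video into series via the
    videomotion module before ``sync``.  Returns the manifest dict.
    """
    if stages is None:
        stages = ALL_STAGES
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    stages = tuple(s for s in ALL_STAGES if s in stages)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    logger.addHandler(handler)
    manifest: dict = {
        "leadsync_version": leadsync.__version__,
        "numpy_version": np.__version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "mode": mode,
        "stages": list(stages),
        "counts": {},
    }
    try:
        for stage in stages:
            for needed in _STAGE_INPUTS.get(stage, ()):
                if not (out / needed).exists():
                    raise FileNotFoundError(
                        f"stage {stage!r} needs missing artifact {needed!r}; "
                        "run the producing stage first"
                    )
            logger.info("running stage %s", stage)
            manifest["counts"].update(_STAGE_FUNCS[stage](config, out))
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return manifest
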