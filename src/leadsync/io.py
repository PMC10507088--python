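"""CSV readers and writers for the pipeline's tabular formats.

Dialect: UTF-8, comma-separated, "." decimal, mandatory header row.  Frame
indices are 0-based; floats are printed at fixed precision so reruns with
identical seeds produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from leadsync.gaze import GazeTrial
from leadsync.impression import ParticipantRecord
from leadsync.synchrony import DyadRecording, LeadingScores
from leadsync.videomotion import MotionEnergySeries

FLOAT_FORMAT = "%.10g"


def write_motion_csv(path: str | Path, dyads: Sequence[DyadRecording]) -> None:
    """Wide-format motion energy: frame_index plus one column per person-ROI."""
    cols = {"frame_index": np.arange(len(dyads[0].green))}
    fps = dyads[0].fps
    for d in dyads:
        if len(d.green) != len(next(iter(cols.values()))):
            raise ValueError("all dyads must share length for wide output")
        cols[f"{d.dyad_id}_green"] = d.green.values
        cols[f"{d.dyad_id}_white"] = d.white.values
    df = pd.DataFrame(cols)
    df.attrs["fps"] = fps
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_motion_csv(
    path: str | Path, fps: float, meta: pd.DataFrame | None = None
) -> list[DyadRecording]:
    """Read wide-format motion CSV back into dyad recordings.

    ``meta`` optionally maps dyad_id to diagnosis and source columns;
    without it, diagnosis defaults to non-autistic and source to A.
    """
    df = pd.read_csv(path)
    ids = sorted({c[:-6] for c in df.columns if c.endswith("_green")})
    lookup = {}
    if meta is not None:
        lookup = meta.set_index("dyad_id")[["diagnosis", "source"]].to_dict("index")
    out = []
    for dyad_id in ids:
        info = lookup.get(dyad_id, {"diagnosis": "non-autistic", "source": "A"})
        out.append(
            DyadRecording(
                dyad_id=dyad_id,
                green=MotionEnergySeries(df[f"{dyad_id}_green"].to_numpy(float), fps, "head-green"),
                white=MotionEnergySeries(df[f"{dyad_id}_white"].to_numpy(float), fps, "head-white"),
                diagnosis_of_target=info["diagnosis"],
                source=info["source"],
            )
        )
    return out


def leading_scores_frame(
    rows: Sequence[tuple[DyadRecording, int, LeadingScores]]
) -> pd.DataFrame:
    """Tabulate (dyad, excerpt index, scores) triples as the per-stimulus table."""
    return pd.DataFrame(
        {
            "dyad_id": [d.dyad_id for d, _, _ in rows],
            "excerpt": [e for _, e, _ in rows],
            "stimulus_id": [f"{d.dyad_id}-e{e}" for d, e, _ in rows],
            "diagnosis": [d.diagnosis_of_target for d, _, _ in rows],
            "source": [d.source for d, _, _ in rows],
            "green_leading": [s.green_leading for _, _, s in rows],
            "white_leading": [s.white_leading for _, _, s in rows],
            "zero_lag": [s.zero_lag for _, _, s in rows],
            "green_leading_log": [s.green_leading_log for _, _, s in rows],
            "white_leading_log": [s.white_leading_log for _, _, s in rows],
            "motion_green": [s.motion_green for _, _, s in rows],
            "motion_white": [s.motion_white for _, _, s in rows],
        }
    )


def write_participants_csv(path: str | Path, records: Sequence[ParticipantRecord]) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def read_participants_csv(path: str | Path) -> list[ParticipantRecord]:
    df = pd.read_csv(path)
    return [
        ParticipantRecord(
            participant_id=str(r.participant_id),
            age=float(r.age),
            gender=str(r.gender),
            aq10=int(r.aq10),
            wst=int(r.wst),
            conscientious=bool(r.conscientious),
        )
        for r in df.itertuples(index=False)
    ]


def write_gaze_csv(path: str | Path, trials: Sequence[GazeTrial]) -> None:
    """Long-format gaze samples: participant, trial, t_ms, side, tracked."""
    frames = [
        pd.DataFrame(
            {
                "participant_id": t.participant_id,
                "trial_id": t.trial_id,
                "diagnosis": t.diagnosis,
                "t_ms": t.t_ms,
                "side": t.sides,
                "tracked": t.tracked.astype(int),
            }
        )
        for t in trials
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_gaze_csv(path: str | Path) -> list[GazeTrial]:
    df = pd.read_csv(path)
    out = []
    for (pid, tid), grp in df.groupby(["participant_id", "trial_id"], sort=True):
        out.append(
            GazeTrial(
                participant_id=str(pid),
                trial_id=str(tid),
                t_ms=grp["t_ms"].to_numpy(float),
                sides=grp["side"].to_numpy(object),
                tracked=grp["tracked"].to_numpy(bool),
                diagnosis=str(grp["diagnosis"].iloc[0]) if "diagnosis" in grp else "",
            )
        )
    return out
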