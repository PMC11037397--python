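"""Plain-text serialization of trials and cohorts.

One trial is stored as a tidy CSV (columns ``t, point, y_ap, z, pitch``;
body points leave ``pitch`` empty, the headset row leaves ``z`` empty) plus
a JSON sidecar holding the trial spec, ground truth and annotations. A
cohort directory adds ``manifest.csv`` (one row per trial) and
``profiles.csv``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import ParticipantProfile, TrialSpec
from .simulate import BodyTrack, Cohort, HeadsetTrack, TrialRecord

__all__ = ["save_trial", "load_trial", "save_cohort", "load_cohort", "trial_id"]


def trial_id(spec: TrialSpec) -> str:
    return f"{spec.participant_id}_t{spec.trial_index:03d}"


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_trial(record: TrialRecord, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tid = trial_id(record.spec)
    frames = []
    for name, track in record.tracks.items():
        frames.append(
            pd.DataFrame(
                {"t": track.t, "point": name, "y_ap": track.y_ap, "z": track.z, "pitch": np.nan}
            )
        )
    h = record.headset
    frames.append(
        pd.DataFrame({"t": h.t, "point": "headset", "y_ap": h.y_ap, "z": np.nan, "pitch": h.pitch})
    )
    pd.concat(frames, ignore_index=True).to_csv(outdir / f"{tid}.csv", index=False)
    sidecar = {
        "spec": dataclasses.asdict(record.spec),
        "truth": _jsonable(record.truth),
        "annotations": _jsonable(record.annotations),
    }
    (outdir / f"{tid}.json").write_text(json.dumps(sidecar, indent=1))
    return outdir / f"{tid}.csv"


def load_trial(outdir: str | Path, tid: str) -> TrialRecord:
    outdir = Path(outdir)
    table = pd.read_csv(outdir / f"{tid}.csv")
    sidecar = json.loads((outdir / f"{tid}.json").read_text())
    spec = TrialSpec(**sidecar["spec"])
    tracks = {}
    for name, sub in table[table["point"] != "headset"].groupby("point"):
        tracks[name] = BodyTrack(
            point_name=name,
            t=sub["t"].to_numpy(),
            y_ap=sub["y_ap"].to_numpy(),
            z=sub["z"].to_numpy(),
        )
    hs = table[table["point"] == "headset"]
    headset = HeadsetTrack(t=hs["t"].to_numpy(), y_ap=hs["y_ap"].to_numpy(), pitch=hs["pitch"].to_numpy())
    truth = sidecar["truth"]
    if "fixation_pitch_deg" in truth:
        truth["fixation_pitch_deg"] = {float(k): v for k, v in truth["fixation_pitch_deg"].items()}
    return TrialRecord(spec=spec, tracks=tracks, headset=headset, truth=truth,
                       annotations=sidecar["annotations"])


def save_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort.records:
        save_trial(rec, outdir)
        s = rec.spec
        rows.append(
            dict(
                trial_id=trial_id(s), participant_id=s.participant_id, task=s.task,
                content=s.content, modulation=s.modulation, imposed_value=s.imposed_value,
                headset=s.headset, analysis_included=s.analysis_included,
                is_calibration=s.is_calibration,
            )
        )
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
    pd.DataFrame([dataclasses.asdict(p) for p in cohort.profiles]).to_csv(
        outdir / "profiles.csv", index=False
    )
    return outdir / "manifest.csv"


def load_cohort(outdir: str | Path) -> Cohort:
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.csv")
    profiles = [
        ParticipantProfile(**row)
        for row in pd.read_csv(outdir / "profiles.csv").to_dict("records")
    ]
    records = [load_trial(outdir, tid) for tid in manifest["trial_id"]]
    return Cohort(profiles=profiles, records=records)
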