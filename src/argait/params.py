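"""Spatiotemporal gait parameters and head-orientation outcomes.

Operational definitions (all distances along the walkway axis, outputs in
cm, cm/s or degrees):

* gait speed — distance travelled between the 3 m and 9 m marks divided by
  the time elapsed, from the spine-shoulder track, with crossing times
  linearly interpolated between the bracketing samples;
* step length — median of the differences between consecutive (bilaterally
  pooled, time-ordered) step locations whose both endpoints lie in [1, 9] m;
* crossing step length at gait initiation — first step location minus the
  median position of the leading limb during the pre-trial standing segment;
* crossing step length halfway — first step location past 5 m minus the
  last step location before 5 m;
* walking head pitch — median headset pitch over samples with the headset
  between 3 and 7 m, minus a baseline pitch;
* static head pitch — per fixated ground line, median pitch within the
  fixation window minus the median over the pooled straight-ahead segments.

A parameter that cannot be computed is returned as a null measurement with
an explicit reason, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import StanceEvent, detect_stances, merge_bilateral
from .simulate import TrialRecord

__all__ = [
    "Measurement",
    "GaitParams",
    "gait_speed",
    "step_length",
    "crossing_step_length",
    "head_pitch_walking",
    "head_pitch_static",
    "extract_trial",
]

SPEED_WINDOW_M = (3.0, 9.0)
STEP_WINDOW_M = (1.0, 9.0)
PITCH_WINDOW_M = (3.0, 7.0)
HALFWAY_M = 5.0


@dataclass(frozen=True)
class Measurement:
    """A nullable outcome: either a finite value or a reason it is missing."""

    value: float | None
    reason: str | None = None

    @property
    def is_missing(self) -> bool:
        return self.value is None

    def __float__(self) -> float:
        return float("nan") if self.value is None else float(self.value)


@dataclass
class GaitParams:
    trial_id: str
    gait_speed: Measurement | None = None  # cm/s
    step_length: Measurement | None = None  # cm
    crossing_init: Measurement | None = None  # cm
    crossing_halfway: Measurement | None = None  # cm
    head_pitch_walking: Measurement | None = None  # deg
    static_pitch_by_line: list = field(default_factory=list)  # (distance cm, Measurement)


def _first_crossing_time(t: np.ndarray, y: np.ndarray, level: float) -> float | None:
    """Time of the first upward crossing of ``level``, linearly interpolated."""
    above = y >= level
    if above[0]:
        return float(t[0])
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return None
    i = idx[0]
    y0, y1 = y[i - 1], y[i]
    if y1 == y0:
        return float(t[i])
    frac = (level - y0) / (y1 - y0)
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def gait_speed(record: TrialRecord) -> Measurement:
    """Gait speed in cm/s over the 3-9 m window of the spine-shoulder track."""
    spine = record.spine
    lo, hi = SPEED_WINDOW_M
    t3 = _first_crossing_time(spine.t, spine.y_ap, lo)
    t9 = _first_crossing_time(spine.t, spine.y_ap, hi)
    if t3 is None or t9 is None or t9 <= t3:
        return Measurement(None, "window not traversed")
    return Measurement(100.0 * (hi - lo) / (t9 - t3))


def step_length(record: TrialRecord, events: list[StanceEvent]) -> Measurement:
    """Median consecutive step-location difference within 1-9 m, in cm."""
    locs = np.array([e.step_location for e in sorted(events, key=lambda e: e.t_start)])
    lo, hi = STEP_WINDOW_M
    diffs = np.diff(locs)
    inside = (locs[:-1] >= lo) & (locs[:-1] <= hi) & (locs[1:] >= lo) & (locs[1:] <= hi)
    qualifying = diffs[inside]
    if qualifying.size < 2:
        return Measurement(None, "fewer than 2 step-location differences in window")
    return Measurement(100.0 * float(np.median(qualifying)))


def _walking_steps(record: TrialRecord, events: list[StanceEvent]) -> list[StanceEvent]:
    """Stances that are actual steps: drop those overlapping quiet standing."""
    stand_end = record.annotations.get("standing_end_s", 0.0)
    return [e for e in sorted(events, key=lambda e: e.t_start) if e.t_start >= stand_end]


def crossing_step_length(
    record: TrialRecord, events: list[StanceEvent], location: str
) -> Measurement:
    """Crossing step length (cm) at gait initiation or at the 5 m obstacle.

    ``location='initiation'``: first step location minus the median AP
    position of the leading limb over the annotated standing segment.
    ``location='halfway'``: first step location past 5 m minus the last one
    before 5 m, both feet pooled.
    """
    steps = _walking_steps(record, events)
    if location == "initiation":
        stand_end = record.annotations.get("standing_end_s")
        lead = record.annotations.get("leading_limb")
        if stand_end is None or lead is None:
            return Measurement(None, "no standing-segment annotation")
        track = record.tracks[f"{lead}_foot"]
        standing = track.y_ap[track.t <= stand_end]
        if standing.size == 0:
            return Measurement(None, "empty standing segment")
        if not steps:
            return Measurement(None, "no step detected after standing")
        return Measurement(100.0 * (steps[0].step_location - float(np.median(standing))))
    if location == "halfway":
        locs = np.array([e.step_location for e in steps])
        before = locs[locs < HALFWAY_M]
        after = locs[locs > HALFWAY_M]
        if after.size == 0:
            return Measurement(None, "no post-obstacle step")
        if before.size == 0:
            return Measurement(None, "no pre-obstacle step")
        return Measurement(100.0 * (float(after[0]) - float(before[-1])))
    raise ValueError("location must be 'initiation' or 'halfway'")


def head_pitch_walking(record: TrialRecord, baseline_pitch: float = 0.0) -> Measurement:
    """Median headset pitch (deg) while the headset is between 3 and 7 m,
    minus ``baseline_pitch``."""
    h = record.headset
    lo, hi = PITCH_WINDOW_M
    inside = (h.y_ap >= lo) & (h.y_ap <= hi)
    if not inside.any() or h.y_ap.max() < hi:
        return Measurement(None, "3-7 m span not covered")
    return Measurement(float(np.median(h.pitch[inside])) - baseline_pitch)


def head_pitch_static(record: TrialRecord) -> list[tuple[float, Measurement]]:
    """Baseline-corrected median pitch per fixated line of a static trial.

    The baseline is the median pitch over the pooled straight-ahead segments
    at the start and end of the trial.
    """
    windows = record.annotations.get("fixation_windows")
    straight = record.annotations.get("straight_segments")
    if not windows or not straight:
        raise ValueError("record lacks static-trial annotations")
    h = record.headset
    mask = np.zeros(h.t.shape, dtype=bool)
    for ts, te in straight:
        mask |= (h.t >= ts) & (h.t < te)
    baseline = float(np.median(h.pitch[mask]))
    out = []
    for win in windows:
        sel = (h.t >= win["t_start"]) & (h.t < win["t_end"])
        if not sel.any():
            out.append((win["distance_cm"], Measurement(None, "fixation window missing")))
        else:
            out.append(
                (win["distance_cm"], Measurement(float(np.median(h.pitch[sel])) - baseline))
            )
    return out


def extract_trial(
    record: TrialRecord,
    v_thresh: float = 0.2,
    min_duration: float = 0.15,
    merge_gap: float = 0.05,
    baseline_pitch: float = 0.0,
) -> GaitParams:
    """Run detection + every parameter relevant to the trial's task."""
    spec = record.spec
    trial_id = f"{spec.participant_id}_t{spec.trial_index}"
    params = GaitParams(trial_id=trial_id)

    if spec.task == "static":
        params.static_pitch_by_line = head_pitch_static(record)
        return params

    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        left = detect_stances(record.left_foot, v_thresh, min_duration, merge_gap)
        right = detect_stances(record.right_foot, v_thresh, min_duration, merge_gap)
        merged = merge_bilateral(left, right)

    params.gait_speed = gait_speed(record)
    params.step_length = step_length(record, _walking_steps(record, merged))
    if spec.task in ("crossing_length", "crossing_height"):
        params.crossing_init = crossing_step_length(record, merged, "initiation")
        params.crossing_halfway = crossing_step_length(record, merged, "halfway")
    params.head_pitch_walking = head_pitch_walking(record, baseline_pitch)
    return params
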