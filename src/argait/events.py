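"""Stance detection and step-location extraction from foot tracks.

The downstream gait parameters need only where each foot was planted along
the walkway (anterior-posterior step locations) and roughly when. A simple
velocity-threshold detector suffices for that: intervals where the AP foot
velocity stays below a threshold are stance phases, and the step location is
the median AP position within the stance (robust to marker jitter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import BodyTrack

__all__ = [
    "StanceEvent",
    "AlternationWarning",
    "detect_stances",
    "merge_bilateral",
    "events_to_frame",
]


class AlternationWarning(UserWarning):
    """Raised when merged stances do not strictly alternate left/right."""


@dataclass(frozen=True)
class StanceEvent:
    foot: str  # "left" | "right"
    t_start: float  # s
    t_end: float  # s
    step_location: float  # m, anterior-posterior

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) index pairs, stop exclusive."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_stances(
    track: BodyTrack,
    v_thresh: float = 0.2,
    min_duration: float = 0.15,
    merge_gap: float = 0.05,
    smooth_window: int = 3,
) -> list[StanceEvent]:
    """Detect stance phases of one foot by thresholding its AP velocity.

    AP velocity is computed by central differences after a short
    moving-average smooth (``smooth_window`` samples) that keeps marker
    jitter from punching through the threshold mid-stance; maximal intervals
    with ``|velocity| < v_thresh`` that last at least ``min_duration``
    become stances, after merging intervals separated by less than
    ``merge_gap``. The step location is the median of the *raw* positions in
    the stance. Returns an empty list (not an error) when nothing qualifies;
    the caller marks the trial as missing.
    """
    if v_thresh <= 0:
        raise ValueError("v_thresh must be positive")
    t, y = np.asarray(track.t, float), np.asarray(track.y_ap, float)
    if len(t) < 3:
        return []
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.concatenate([np.full(pad, y[0]), y, np.full(pad, y[-1])])
        y_smooth = np.convolve(padded, kernel, mode="valid")[: len(y)]
    else:
        y_smooth = y
    vel = np.gradient(y_smooth, t)
    runs = _runs(np.abs(vel) < v_thresh)
    if not runs:
        return []

    dt = float(np.median(np.diff(t)))
    merged = [list(runs[0])]
    for start, stop in runs[1:]:
        if (start - merged[-1][1]) * dt < merge_gap:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])

    foot = "left" if "left" in track.point_name else "right"
    events = []
    for start, stop in merged:
        duration = t[stop - 1] - t[start]
        if duration < min_duration:
            continue
        events.append(
            StanceEvent(
                foot=foot,
                t_start=float(t[start]),
                t_end=float(t[stop - 1]),
                step_location=float(np.median(y[start:stop])),
            )
        )
    return events


def merge_bilateral(
    left: list[StanceEvent], right: list[StanceEvent]
) -> list[StanceEvent]:
    """Merge per-foot stance lists into one time-ordered sequence.

    Warns (``AlternationWarning``) instead of failing when the merged
    sequence does not strictly alternate feet, including when one side is
    empty — the analysis can often still proceed on the pooled locations.
    """
    merged = sorted(list(left) + list(right), key=lambda e: e.t_start)
    if not left or not right:
        warnings.warn("one foot contributed no stances", AlternationWarning, stacklevel=2)
        return merged
    for prev, cur in zip(merged, merged[1:]):
        if prev.foot == cur.foot:
            warnings.warn(
                f"consecutive stances on the same foot ({cur.foot}) "
                f"at t={prev.t_start:.2f}s and t={cur.t_start:.2f}s",
                AlternationWarning,
                stacklevel=2,
            )
            break
    return merged


def events_to_frame(events: list[StanceEvent], trial_id: str = "") -> pd.DataFrame:
    """CSV-ready table of stance events."""
    return pd.DataFrame(
        {
            "trial_id": trial_id,
            "foot": [e.foot for e in events],
            "t_start": [e.t_start for e in events],
            "t_end": [e.t_end for e in events],
            "step_location": [e.step_location for e in events],
        }
    )
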