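"""Experimental design of the cued-walking protocol.

A participant performs a fixed sequence of tasks on a 10 m walkway: a static
head-orientation task (fixating ground lines at known distances), then four
cued walking tasks that impose changes in gait speed, step length, obstacle
crossing step length and hurdle crossing height. Within each task the
condition order (cue content x modulation level) is randomized per
participant; the task order itself is fixed.

Modulations are anchored to the participant's preferred (baseline) gait:
speed cues move at baseline -20 / +0 / +20 cm/s, stepping targets are spaced
at baseline step length -15 / +0 / +15 cm, 2D obstacles are 15/30/45 cm deep
and 3D hurdles 5/10/15 cm high. Enumerating the cued conditions yields
exactly 30 walking trials per participant plus two static trials; baseline
walks (two without the headset, one with it) are emitted as calibration
trials outside that count. Hurdle (crossing-height) trials are generated but
flagged as excluded from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "TrialSpec",
    "ParticipantProfile",
    "enumerate_design",
    "design_to_frame",
    "frame_to_design",
    "TASKS",
    "CUED_TASKS",
    "TASK_CONTENTS",
    "MODULATIONS",
    "SPEED_OFFSETS_CMPS",
    "STEP_OFFSETS_CM",
    "OBSTACLE_DEPTHS_CM",
    "HURDLE_HEIGHTS_CM",
    "SPEED_MODULATION_CMPS",
    "STEP_MODULATION_CM",
    "STATIC_LINE_DISTANCES_CM",
]

#: fixed task order of the protocol
TASKS = ("static", "gait_speed", "step_length", "crossing_length", "crossing_height")

#: the four cued walking tasks (the 30-trial count refers to these)
CUED_TASKS = ("gait_speed", "step_length", "crossing_length", "crossing_height")

#: admissible cue contents per task
TASK_CONTENTS = {
    "static": ("real_world", "ar"),
    "gait_speed": ("real_world", "ar", "ar_bird"),
    "step_length": ("real_world", "ar", "ar_sound"),
    "crossing_length": ("real_world", "ar"),
    "crossing_height": ("real_world", "ar"),
}

MODULATIONS = ("low", "mid", "high")

#: semantic aliases for the generic low/mid/high levels, per task
MODULATION_ALIASES = {
    "gait_speed": {"low": "slow", "mid": "preferred", "high": "fast"},
    "step_length": {"low": "short", "mid": "preferred", "high": "long"},
    "crossing_length": {"low": "small", "mid": "medium", "high": "large"},
    "crossing_height": {"low": "low", "mid": "medium", "high": "high"},
}

SPEED_OFFSETS_CMPS = {"low": -20.0, "mid": 0.0, "high": 20.0}
STEP_OFFSETS_CM = {"low": -15.0, "mid": 0.0, "high": 15.0}
OBSTACLE_DEPTHS_CM = {"low": 15.0, "mid": 30.0, "high": 45.0}
HURDLE_HEIGHTS_CM = {"low": 5.0, "mid": 10.0, "high": 15.0}

#: magnitude of the imposed modulation (distance between adjacent levels)
SPEED_MODULATION_CMPS = 20.0
STEP_MODULATION_CM = 15.0

#: ground-line distances of the static head-orientation task, cm
STATIC_LINE_DISTANCES_CM = (10.0, 30.0, 60.0, 100.0, 150.0, 210.0, 280.0)

HEADSETS = ("HL2", "ML2")


@dataclass(frozen=True)
class ParticipantProfile:
    """Baseline characteristics anchoring a participant's cue modulations."""

    participant_id: str
    baseline_speed: float  # preferred gait speed, cm/s
    baseline_step_length: float  # preferred step length, cm
    eye_height: float = 1.65  # m
    headset: str = "HL2"
    leading_limb: str = "right"

    def __post_init__(self) -> None:
        if self.baseline_speed <= 0:
            raise ValueError("baseline_speed must be positive")
        if self.baseline_step_length <= 0:
            raise ValueError("baseline_step_length must be positive")
        if not 1.0 <= self.eye_height <= 2.0:
            raise ValueError("eye_height must lie in [1.0, 2.0] m")
        if self.headset not in HEADSETS:
            raise ValueError(f"unknown headset {self.headset!r}")
        if self.leading_limb not in ("left", "right"):
            raise ValueError("leading_limb must be 'left' or 'right'")


@dataclass(frozen=True)
class TrialSpec:
    """Identity of one trial: task, cue content, modulation, imposed value.

    ``imposed_value`` carries task-specific units: cm/s for gait-speed
    trials, cm for step-length / obstacle-depth / hurdle-height trials, and
    ``None`` for static and calibration trials.
    """

    participant_id: str
    task: str
    content: str
    modulation: str | None
    imposed_value: float | None
    headset: str
    analysis_included: bool = True
    is_calibration: bool = False
    trial_index: int = 0

    def __post_init__(self) -> None:
        if self.is_calibration:
            return
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.content not in TASK_CONTENTS[self.task]:
            raise ValueError(
                f"content {self.content!r} not admissible for task {self.task!r}"
            )
        if self.task != "static" and self.modulation not in MODULATIONS:
            raise ValueError(f"unknown modulation {self.modulation!r}")

    @property
    def modulation_alias(self) -> str | None:
        if self.task in MODULATION_ALIASES and self.modulation is not None:
            return MODULATION_ALIASES[self.task][self.modulation]
        return None


def imposed_value(task: str, modulation: str, profile: ParticipantProfile) -> float:
    """Imposed cue value for a task x modulation cell, from the baselines."""
    if task == "gait_speed":
        return profile.baseline_speed + SPEED_OFFSETS_CMPS[modulation]
    if task == "step_length":
        return profile.baseline_step_length + STEP_OFFSETS_CM[modulation]
    if task == "crossing_length":
        return OBSTACLE_DEPTHS_CM[modulation]
    if task == "crossing_height":
        return HURDLE_HEIGHTS_CM[modulation]
    raise ValueError(f"task {task!r} has no imposed value")


def enumerate_design(
    profile: ParticipantProfile,
    seed: int = 0,
    include_calibration: bool = True,
) -> list[TrialSpec]:
    """Enumerate every trial of one participant's session.

    Tasks appear in the protocol's fixed order; within a task the
    content x modulation conditions are shuffled with a seeded generator so
    the ordering is reproducible. Returns calibration baseline walks (if
    requested), two static trials and the 30 cued walking trials.
    Crossing-height trials carry ``analysis_included=False``.
    """
    rng = np.random.default_rng(seed)
    specs: list[TrialSpec] = []
    idx = 0

    if include_calibration:
        # two baseline walks without headset, one with, before the cued tasks
        for label in ("baseline_no_headset_1", "baseline_no_headset_2", "baseline_headset"):
            specs.append(
                TrialSpec(
                    participant_id=profile.participant_id,
                    task=label,
                    content="none",
                    modulation=None,
                    imposed_value=None,
                    headset=profile.headset,
                    analysis_included=False,
                    is_calibration=True,
                    trial_index=idx,
                )
            )
            idx += 1

    for task in TASKS:
        if task == "static":
            conditions = [(c, None) for c in TASK_CONTENTS[task]]
        else:
            conditions = [
                (c, m) for c in TASK_CONTENTS[task] for m in MODULATIONS
            ]
        order = rng.permutation(len(conditions))
        for j in order:
            content, modulation = conditions[j]
            specs.append(
                TrialSpec(
                    participant_id=profile.participant_id,
                    task=task,
                    content=content,
                    modulation=modulation,
                    imposed_value=(
                        None if task == "static" else imposed_value(task, modulation, profile)
                    ),
                    headset=profile.headset,
                    analysis_included=task != "crossing_height",
                    trial_index=idx,
                )
            )
            idx += 1
    return specs


def design_to_frame(specs: list[TrialSpec]) -> pd.DataFrame:
    """Flat-table (CSV-ready) view of a design."""
    rows = [asdict(s) for s in specs]
    frame = pd.DataFrame(rows)
    cols = [
        "participant_id", "trial_index", "task", "content", "modulation",
        "imposed_value", "headset", "analysis_included", "is_calibration",
    ]
    return frame[cols]


def frame_to_design(frame: pd.DataFrame) -> list[TrialSpec]:
    specs = []
    for row in frame.itertuples(index=False):
        modulation = row.modulation if isinstance(row.modulation, str) else None
        value = row.imposed_value
        if value is not None and not np.isfinite(value):
            value = None
        specs.append(
            TrialSpec(
                participant_id=row.participant_id,
                task=row.task,
                content=row.content,
                modulation=modulation,
                imposed_value=value,
                headset=row.headset,
                analysis_included=bool(row.analysis_included),
                is_calibration=bool(row.is_calibration),
                trial_index=int(row.trial_index),
            )
        )
    return specs
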