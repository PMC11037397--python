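"""Synthetic kinematics generator for cued walking on a 10 m walkway.

Each simulated trial produces the tracks the downstream analysis consumes:
anterior-posterior (AP) and vertical positions of the spine-shoulder point
and both feet on a uniform time grid, plus a headset track (AP position and
pitch, degrees, positive downward). Ground-truth latents (executed speed,
per-step lengths, step locations, cue pitch) are recorded alongside so that
event detection and parameter extraction can be validated by recovery.

The walking model is deliberately minimal: a step plan (footfall locations
and completion times) is drawn from the imposed cue value plus optional
systematic adherence bias and Gaussian execution noise; feet are stationary
during stance and advance along a smoothstep profile during a fixed-duration
swing; the spine-shoulder point moves through the mid-feet positions at the
executed speed. Within-step kinematics beyond this carry no information used
by the analysis.

Head pitch follows gaze-to-ground geometry: a walker fixating the floor a
preview distance ``p`` ahead with eyes at height ``h`` pitches the head down
by ``atan(h / p)``; a cue at eye height (the flying-bird speed cue) requires
no downward pitch at all. The static task fixates ground lines at known
distances, so its noise-free pitch per line is exactly ``atan(h / d)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .design import (
    CUED_TASKS,
    ParticipantProfile,
    STATIC_LINE_DISTANCES_CM,
    TrialSpec,
    enumerate_design,
)

__all__ = [
    "BodyTrack",
    "HeadsetTrack",
    "TrialRecord",
    "NoiseConfig",
    "CohortConfig",
    "Cohort",
    "simulate_walking_trial",
    "simulate_static_trial",
    "simulate_cohort",
]

WALKWAY_LENGTH_M = 10.0
#: feet start just behind the start line; leading limb slightly ahead
STAND_LEAD_Y = 0.0
STAND_TRAIL_Y = -0.12


@dataclass
class NoiseConfig:
    """Noise, adherence and kinematic nuisance parameters of the generator.

    All SDs are Gaussian standard deviations; ``adherence_bias`` is a
    systematic offset added to the modulated parameter (cm for step length,
    cm/s for speed). ``preview_distance`` is how far ahead of the feet a
    walker fixates floor cues, which sets the baseline downward head pitch.
    """

    fs: float = 30.0  # sampling rate, Hz
    marker_noise_sd: float = 0.003  # per-sample position jitter, m
    step_exec_sd: float = 2.0  # per-step execution noise, cm
    speed_exec_sd: float = 6.0  # per-trial speed execution noise, cm/s
    adherence_bias: float = 0.0  # systematic over/undershoot, cm or cm/s
    pitch_noise_sd: float = 2.0  # headset pitch jitter, deg
    preview_distance: float = 2.4  # gaze point ahead of the feet, m
    swing_duration: float = 0.4  # s
    stand_duration: float = 1.5  # quiet standing before gait initiation, s
    crossing_margin_before: float = 0.15  # foot-to-obstacle clearance, m
    crossing_margin_after: float = 0.15
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("marker_noise_sd", "step_exec_sd", "speed_exec_sd", "pitch_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.preview_distance <= 0:
            raise ValueError("preview_distance must be positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    def noise_free(self) -> "NoiseConfig":
        """Copy with every stochastic term switched off."""
        return dataclasses.replace(
            self,
            marker_noise_sd=0.0,
            step_exec_sd=0.0,
            speed_exec_sd=0.0,
            pitch_noise_sd=0.0,
            adherence_bias=0.0,
        )


@dataclass
class BodyTrack:
    point_name: str  # spine_shoulder | left_foot | right_foot
    t: np.ndarray  # s, uniform grid
    y_ap: np.ndarray  # anterior-posterior position, m
    z: np.ndarray  # vertical position, m


@dataclass
class HeadsetTrack:
    t: np.ndarray
    y_ap: np.ndarray
    pitch: np.ndarray  # deg, positive downward


@dataclass
class TrialRecord:
    """One simulated trial: spec, tracks, ground truth and annotations."""

    spec: TrialSpec
    tracks: dict[str, BodyTrack]
    headset: HeadsetTrack
    truth: dict
    annotations: dict

    @property
    def spine(self) -> BodyTrack:
        return self.tracks["spine_shoulder"]

    @property
    def left_foot(self) -> BodyTrack:
        return self.tracks["left_foot"]

    @property
    def right_foot(self) -> BodyTrack:
        return self.tracks["right_foot"]


@dataclass
class CohortConfig:
    """Study-level configuration: cohort size, between-subject variability
    and condition-wise adherence biases.

    Defaults mirror the cued-walking study conditions: 21 participants,
    preferred speed 127 +/- 16 cm/s, preferred step length 68 +/- 10 cm,
    two headsets split as evenly as possible.
    """

    n_participants: int = 21
    mean_baseline_speed: float = 127.0  # cm/s
    between_sd_speed: float = 16.0  # cm/s
    mean_baseline_step: float = 68.0  # cm
    between_sd_step: float = 10.0  # cm
    mean_eye_height: float = 1.65  # m
    between_sd_eye_height: float = 0.05  # m
    #: (task, content, modulation) -> systematic bias in the task's units;
    #: missing keys default to 0 (unbiased execution)
    adherence_bias: dict = field(default_factory=dict)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    include_static: bool = True
    include_calibration: bool = True
    tasks: tuple = CUED_TASKS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")


@dataclass
class Cohort:
    profiles: list[ParticipantProfile]
    records: list[TrialRecord]


def _smoothstep(u: np.ndarray) -> np.ndarray:
    return u * u * (3.0 - 2.0 * u)


def _rng_for(noise: NoiseConfig, rng: np.random.Generator | None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(noise.seed)


def _plan_steps(
    spec: TrialSpec,
    profile: ParticipantProfile,
    noise: NoiseConfig,
    rng: np.random.Generator,
) -> tuple[list[float], float, dict]:
    """Draw the step plan: footfall locations (m) and the executed speed (m/s).

    Returns (locations, speed, extras) where extras holds crossing-step
    truths when applicable.
    """
    v_pref = profile.baseline_speed / 100.0
    step_pref = profile.baseline_step_length / 100.0
    extras: dict = {}

    def draw_step_m() -> float:
        # preferred-length steps with execution noise (never below 10 cm)
        return max(0.10, step_pref + rng.normal(0.0, noise.step_exec_sd) / 100.0)

    if spec.task == "gait_speed":
        v = (spec.imposed_value + noise.adherence_bias + rng.normal(0.0, noise.speed_exec_sd)) / 100.0
        if v <= 0.2:
            raise ValueError("executed speed drawn non-positive; reduce speed_exec_sd/bias")
    elif spec.task == "step_length":
        target_cm = spec.imposed_value + noise.adherence_bias
        if target_cm - 4.0 * noise.step_exec_sd <= 0:
            raise ValueError(
                "step-length target minus 4 SD is non-positive; the generator "
                "would draw negative steps"
            )
        # cadence-preserving execution: step duration stays at the preferred
        # value, so speed scales with the imposed step length (stepping
        # targets modulate speed proportionally, not cadence)
        v = max(0.3, v_pref * (target_cm / 100.0) / step_pref)

        def draw_step_m() -> float:
            return (target_cm + rng.normal(0.0, noise.step_exec_sd)) / 100.0

    else:  # crossing tasks and calibration baselines
        v = v_pref

    locs: list[float] = []
    crossing = spec.task in ("crossing_length", "crossing_height")
    if crossing:
        # obstacle depth along the walkway; hurdles are thin (2 cm) but tall
        depth_m = spec.imposed_value / 100.0 if spec.task == "crossing_length" else 0.02
        extras["obstacle_depth_m"] = depth_m
        first = STAND_LEAD_Y + noise.crossing_margin_before + depth_m + noise.crossing_margin_after
        first += rng.normal(0.0, noise.step_exec_sd / 100.0)
        locs.append(first)
        extras["crossing_init_m"] = first - STAND_LEAD_Y
    else:
        locs.append(STAND_LEAD_Y + draw_step_m())

    while locs[-1] < 9.7:
        prev = locs[-1]
        nxt = min(prev + draw_step_m(), 10.3)  # never step off the walkway
        if crossing and prev < 5.0 and nxt > 5.0 - noise.crossing_margin_before:
            # replace the step that would land on/just before the obstacle at
            # 5 m with a crossing step clearing its far edge
            nxt = 5.0 + extras["obstacle_depth_m"] + noise.crossing_margin_after
            nxt += rng.normal(0.0, noise.step_exec_sd / 100.0)
            extras["crossing_halfway_m"] = nxt - prev
        locs.append(nxt)
    return locs, v, extras


def simulate_walking_trial(
    spec: TrialSpec,
    profile: ParticipantProfile,
    noise: NoiseConfig | None = None,
    rng: np.random.Generator | None = None,
) -> TrialRecord:
    """Simulate one walking trial (any task except ``static``).

    The trial begins with ``stand_duration`` seconds of quiet standing, then
    gait initiation and steady walking past 9 m. Step completion times follow
    the executed speed (each step of length L takes L/v seconds, i.e. the
    instantaneous progression speed is constant); feet move only during the
    swing window preceding each footfall. The spine-shoulder track linearly
    interpolates the mid-feet position at each step completion, which makes
    its steady-state velocity exactly the executed speed.
    """
    if spec.task == "static":
        raise ValueError("use simulate_static_trial for static trials")
    noise = noise or NoiseConfig()
    rng = _rng_for(noise, rng)

    locs, v, extras = _plan_steps(spec, profile, noise, rng)
    n_steps = len(locs)
    lengths = np.diff([STAND_LEAD_Y] + locs)  # m, first step measured from lead foot
    durations = lengths / v
    t0 = noise.stand_duration
    step_times = t0 + np.cumsum(durations)
    t_end = step_times[-1] + 1.0

    fs, dt = noise.fs, 1.0 / noise.fs
    n = int(np.ceil(t_end * fs)) + 1
    t = np.arange(n) * dt

    lead = profile.leading_limb
    trail = "left" if lead == "right" else "right"
    start_pos = {lead: STAND_LEAD_Y, trail: STAND_TRAIL_Y}
    # footfall k (0-based) belongs to the leading limb when k is even
    foot_of_step = [lead if k % 2 == 0 else trail for k in range(n_steps)]

    w = min(noise.swing_duration, 0.8 * float(durations.min()))
    foot_y: dict[str, np.ndarray] = {}
    foot_z: dict[str, np.ndarray] = {}
    for foot in (lead, trail):
        y = np.full(n, start_pos[foot])
        z = np.full(n, 0.05)
        prev_pos = start_pos[foot]
        for k in range(n_steps):
            if foot_of_step[k] != foot:
                continue
            tk = step_times[k]
            in_swing = (t >= tk - w) & (t < tk)
            u = (t[in_swing] - (tk - w)) / w
            y[in_swing] = prev_pos + _smoothstep(u) * (locs[k] - prev_pos)
            z[in_swing] = 0.05 + 4.0 * u * (1.0 - u) * 0.08
            y[t >= tk] = locs[k]
            prev_pos = locs[k]
        foot_y[foot] = y
        foot_z[foot] = z

    # spine-shoulder: piecewise-linear through mid-feet positions at each
    # step completion; constant-velocity tail past the last step
    mid0 = 0.5 * (STAND_LEAD_Y + STAND_TRAIL_Y)
    knot_t = np.concatenate([[0.0, t0], step_times, [step_times[-1] + 5.0]])
    prev_locs = np.concatenate([[STAND_LEAD_Y], locs[:-1]])
    knot_y = np.concatenate([[mid0, mid0], 0.5 * (np.asarray(locs) + prev_locs), [0.0]])
    knot_y[1] = mid0
    knot_y[-1] = knot_y[-2] + 5.0 * v
    # the walker halts at the end of the walkway
    spine_y = np.minimum(np.interp(t, knot_t, knot_y), 10.3)

    sd = noise.marker_noise_sd
    tracks = {}
    for foot in ("left", "right"):
        tracks[f"{foot}_foot"] = BodyTrack(
            point_name=f"{foot}_foot",
            t=t,
            y_ap=foot_y[foot] + rng.normal(0.0, sd, n),
            z=foot_z[foot] + rng.normal(0.0, sd, n),
        )
    tracks["spine_shoulder"] = BodyTrack(
        point_name="spine_shoulder",
        t=t,
        y_ap=spine_y + rng.normal(0.0, sd, n),
        z=np.full(n, profile.eye_height - 0.25) + rng.normal(0.0, sd, n),
    )

    if spec.content == "ar_bird" or spec.is_calibration:
        cue_pitch = 0.0  # cue at eye height (or no cue): no downward pitch
    else:
        cue_pitch = float(np.degrees(np.arctan(profile.eye_height / noise.preview_distance)))
    headset = HeadsetTrack(
        t=t,
        y_ap=spine_y + rng.normal(0.0, sd, n),
        pitch=cue_pitch + rng.normal(0.0, noise.pitch_noise_sd, n),
    )

    truth = {
        "executed_speed_cmps": v * 100.0,
        "step_lengths_cm": (lengths * 100.0).tolist(),
        "step_locations_m": list(map(float, locs)),
        "step_feet": foot_of_step,
        "cue_pitch_deg": cue_pitch,
    }
    if "crossing_init_m" in extras:
        truth["crossing_init_cm"] = extras["crossing_init_m"] * 100.0
    if "crossing_halfway_m" in extras:
        truth["crossing_halfway_cm"] = extras["crossing_halfway_m"] * 100.0
    annotations = {
        "standing_end_s": t0,
        "leading_limb": lead,
        "standing_positions": dict(start_pos),
    }
    return TrialRecord(spec=spec, tracks=tracks, headset=headset, truth=truth, annotations=annotations)


def simulate_static_trial(
    profile: ParticipantProfile,
    distances_cm: tuple = STATIC_LINE_DISTANCES_CM,
    noise: NoiseConfig | None = None,
    rng: np.random.Generator | None = None,
    content: str = "real_world",
    fixation_duration: float = 5.0,
    straight_duration: float = 3.0,
) -> TrialRecord:
    """Simulate the static head-orientation task.

    The participant stands still, looks straight ahead, then fixates a
    ground line at each requested distance for ``fixation_duration`` seconds
    (noise-free pitch ``atan(eye_height / distance)``), closing with another
    straight-ahead segment. Fixation windows and straight segments are
    annotated for the extraction stage.
    """
    if any(d <= 0 for d in distances_cm):
        raise ValueError("line distances must be positive")
    noise = noise or NoiseConfig()
    rng = _rng_for(noise, rng)
    fs, dt = noise.fs, 1.0 / noise.fs

    segments: list[tuple[str, float, float]] = []  # (label, t_start, t_end)
    cursor = 0.0
    segments.append(("straight", cursor, cursor + straight_duration))
    cursor += straight_duration
    fixation_windows = []
    true_pitch = {}
    for d in distances_cm:
        pitch = float(np.degrees(np.arctan(profile.eye_height / (d / 100.0))))
        fixation_windows.append({"distance_cm": d, "t_start": cursor, "t_end": cursor + fixation_duration})
        true_pitch[d] = pitch
        segments.append((f"line_{d:g}", cursor, cursor + fixation_duration))
        cursor += fixation_duration
    segments.append(("straight", cursor, cursor + straight_duration))
    cursor += straight_duration

    n = int(np.ceil(cursor * fs)) + 1
    t = np.arange(n) * dt
    pitch = np.zeros(n)
    for label, ts, te in segments:
        if label.startswith("line_"):
            d = float(label[5:])
            pitch[(t >= ts) & (t < te)] = true_pitch[d]
    pitch = pitch + rng.normal(0.0, noise.pitch_noise_sd, n)

    sd = noise.marker_noise_sd
    tracks = {}
    for foot, y0 in (("left", STAND_TRAIL_Y), ("right", STAND_LEAD_Y)):
        tracks[f"{foot}_foot"] = BodyTrack(
            point_name=f"{foot}_foot",
            t=t,
            y_ap=np.full(n, y0) + rng.normal(0.0, sd, n),
            z=np.full(n, 0.05) + rng.normal(0.0, sd, n),
        )
    tracks["spine_shoulder"] = BodyTrack(
        point_name="spine_shoulder",
        t=t,
        y_ap=np.zeros(n) + rng.normal(0.0, sd, n),
        z=np.full(n, profile.eye_height - 0.25) + rng.normal(0.0, sd, n),
    )
    headset = HeadsetTrack(t=t, y_ap=np.zeros(n) + rng.normal(0.0, sd, n), pitch=pitch)

    spec = TrialSpec(
        participant_id=profile.participant_id,
        task="static",
        content=content,
        modulation=None,
        imposed_value=None,
        headset=profile.headset,
    )
    straight = [(s[1], s[2]) for s in segments if s[0] == "straight"]
    return TrialRecord(
        spec=spec,
        tracks=tracks,
        headset=headset,
        truth={"fixation_pitch_deg": true_pitch, "baseline_pitch_deg": 0.0},
        annotations={"fixation_windows": fixation_windows, "straight_segments": straight},
    )


def draw_profiles(cfg: CohortConfig) -> list[ParticipantProfile]:
    """Draw participant baselines from the configured between-subject model."""
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0]))
    profiles = []
    for i in range(cfg.n_participants):
        speed = float(np.clip(rng.normal(cfg.mean_baseline_speed, cfg.between_sd_speed), 60.0, 250.0))
        step = float(np.clip(rng.normal(cfg.mean_baseline_step, cfg.between_sd_step), 35.0, 110.0))
        eye = float(np.clip(rng.normal(cfg.mean_eye_height, cfg.between_sd_eye_height), 1.0, 2.0))
        profiles.append(
            ParticipantProfile(
                participant_id=f"P{i + 1:02d}",
                baseline_speed=speed,
                baseline_step_length=step,
                eye_height=eye,
                headset="HL2" if i % 2 == 0 else "ML2",
                leading_limb="right" if rng.random() < 0.5 else "left",
            )
        )
    return profiles


def simulate_cohort(cfg: CohortConfig) -> Cohort:
    """Simulate every trial of every participant, reproducibly from one seed.

    Per-participant and per-trial random streams are derived from the master
    seed with ``SeedSequence`` spawn keys, so adding participants or trials
    never reshuffles the randomness of earlier ones.
    """
    profiles = draw_profiles(cfg)
    records: list[TrialRecord] = []
    for i, profile in enumerate(profiles):
        design_seed = int(np.random.SeedSequence([int(cfg.seed), 1, i]).generate_state(1)[0] % (2**31))
        specs = enumerate_design(profile, seed=design_seed, include_calibration=cfg.include_calibration)
        for spec in specs:
            if spec.task == "static" and not cfg.include_static:
                continue
            if (not spec.is_calibration and spec.task not in cfg.tasks and spec.task != "static"):
                continue
            rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 2, i, spec.trial_index]))
            bias = cfg.adherence_bias.get((spec.task, spec.content, spec.modulation), 0.0)
            noise = dataclasses.replace(cfg.noise, adherence_bias=bias)
            if spec.task == "static":
                rec = simulate_static_trial(profile, noise=noise, rng=rng, content=spec.content)
                rec = dataclasses.replace(rec, spec=spec)
            else:
                rec = simulate_walking_trial(spec, profile, noise=noise, rng=rng)
            records.append(rec)
    return Cohort(profiles=profiles, records=records)
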