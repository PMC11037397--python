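import numpy as np
import pytest

from argait import NoiseConfig, ParticipantProfile, enumerate_design


@pytest.fixture
def profile() -> ParticipantProfile:
    return ParticipantProfile(
        participant_id="P01",
        baseline_speed=127.0,
        baseline_step_length=68.0,
        eye_height=1.60,
        headset="HL2",
        leading_limb="right",
    )


@pytest.fixture
def noise_free() -> NoiseConfig:
    return NoiseConfig().noise_free()


def spec_for(profile, task, content, modulation, seed=0):
    """First enumerated spec matching the requested condition."""
    for s in enumerate_design(profile, seed=seed):
        if s.task == task and s.content == content and s.modulation == modulation:
            return s
    raise LookupError(f"no spec for {task}/{content}/{modulation}")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
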