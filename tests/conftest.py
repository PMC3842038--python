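import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from locogear import ArenaSpec, PipelineConfig, Trajectory
from locogear.synth import SynthConfig, generate_recording

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def arena():
    return ArenaSpec()


@pytest.fixture
def config():
    return PipelineConfig()


def make_recording(seed: int, duration_s: float = 1800.0, episode_rate: float = 6.0,
                   clean: bool = False, **kwargs):
    """A 30-min flat-profile recording (corrupted by default)."""
    if clean:
        kwargs.setdefault("artifact_rates",
                          {"out_of_arena": 0.0, "corner_jump": 0.0, "teleport": 0.0})
    cfg = SynthConfig(duration_s=duration_s, episode_rate=episode_rate,
                      circadian_profile=(1.0,), seed=seed, **kwargs)
    return cfg, *generate_recording(cfg)


def clean_trajectory(truth, sample_rate_hz: float = 12.8) -> Trajectory:
    """Trajectory carrying the uncorrupted ground-truth positions."""
    return Trajectory(sample_rate_hz, truth.clean_positions[:, 0],
                      truth.clean_positions[:, 1],
                      np.ones(len(truth.clean_positions), dtype=bool))


@pytest.fixture(scope="session")
def recording30():
    """One corrupted 30-min recording shared across read-only tests."""
    cfg = SynthConfig(duration_s=1800.0, episode_rate=6.0, circadian_profile=(1.0,), seed=11)
    traj, truth = generate_recording(cfg)
    return cfg, traj, truth
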