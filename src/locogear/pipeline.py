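"""End-to-end convenience runner: preprocessing through endpoints."""

from __future__ import annotations

from dataclasses import dataclass, field

import dataclasses

from .endpoints import EndpointSet, compute_endpoints, episode_curvature
from .gears import GearModel, assign_gears, fit_gear_mixture
from .io import ArenaSpec, PipelineConfig, Trajectory
from .preprocess import preprocess
from .segment import MotionEpisode, SpeedSeries, compute_speed, segment_episodes

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    trajectory: Trajectory
    speed: SpeedSeries
    episodes: list
    gear_model: GearModel | None
    endpoints: EndpointSet
    provenance: list = field(default_factory=list)


def run_pipeline(traj: Trajectory, arena: ArenaSpec | None = None,
                 config: PipelineConfig | None = None,
                 fit_mixture: bool = True, mixture_seed: int = 0) -> PipelineResult:
    """Run artifact rejection, segmentation, gear labelling and endpoints.

    The Gaussian-mixture characterization is fitted when at least 10
    episodes are available and ``fit_mixture`` is set; gear labels always
    come from the fixed threshold.
    """
    arena = arena or ArenaSpec()
    config = config or PipelineConfig()
    clean = preprocess(traj, arena, config)
    speed = compute_speed(clean, arena, config)
    episodes = segment_episodes(speed, clean, arena, config)
    episodes = assign_gears(episodes, config)
    pos_cm = clean.positions_cm(arena)
    episodes = [dataclasses.replace(
        e, curvature_pct=episode_curvature(clean, e, arena, config, positions_cm=pos_cm))
        for e in episodes]
    model = None
    if fit_mixture and len(episodes) >= 10:
        model = fit_gear_mixture([e.log_max_sd for e in episodes], seed=mixture_seed)
    eps = compute_endpoints(clean, episodes, arena, config)
    return PipelineResult(trajectory=clean, speed=speed, episodes=episodes,
                          gear_model=model, endpoints=eps,
                          provenance=list(clean.provenance))
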