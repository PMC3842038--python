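"""The six behavioral endpoints and the circadian activity profile.

Endpoints for one recording: (1) incidence of second-gear episodes (% of all
motion episodes), (2) total covered distance in meters over all motion
episodes, (3) mean maximal speed per gear, (4) mean dwell time per gear,
(5) mean spatial spread (within-episode covered path) per gear, (6) mean
track curvature per gear, reported as percent excess of path over chord in
0.5 s windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import ArenaSpec, PipelineConfig, Trajectory
from .segment import MotionEpisode

__all__ = [
    "EndpointSet",
    "incidence_second_gear",
    "total_distance",
    "mean_max_speed",
    "mean_dwell_time",
    "mean_spatial_spread",
    "episode_curvature",
    "activity_profile",
    "compute_endpoints",
]

GEARS = (1, 2)


@dataclass
class EndpointSet:
    """Per-recording endpoint values; per-gear fields are keyed by gear label.

    Missing values (e.g. no second-gear episodes) are NaN.
    """

    incidence2_pct: float
    distance_m: float
    mean_max_speed_cms: dict = field(default_factory=dict)
    mean_dwell_s: dict = field(default_factory=dict)
    mean_spread_cm: dict = field(default_factory=dict)
    mean_curvature_pct: dict = field(default_factory=dict)
    n_episodes: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "incidence2_pct": self.incidence2_pct,
            "distance_m": self.distance_m,
            "mean_max_speed_cms": dict(self.mean_max_speed_cms),
            "mean_dwell_s": dict(self.mean_dwell_s),
            "mean_spread_cm": dict(self.mean_spread_cm),
            "mean_curvature_pct": dict(self.mean_curvature_pct),
            "n_episodes": dict(self.n_episodes),
        }


def _gear_values(episodes, gear, attr):
    return [getattr(e, attr) for e in episodes if e.gear == gear]


def incidence_second_gear(episodes) -> float:
    """Percentage of second-gear episodes among all motion episodes."""
    if not episodes:
        return float("nan")
    n2 = sum(1 for e in episodes if e.gear == 2)
    return 100.0 * n2 / len(episodes)


def total_distance(episodes) -> float:
    """Cumulative covered distance over all motion episodes, in meters."""
    return sum(e.path_cm for e in episodes) / 100.0


def mean_max_speed(episodes, gear: int) -> float:
    vals = _gear_values(episodes, gear, "max_speed_cms")
    return float(np.mean(vals)) if vals else float("nan")


def mean_dwell_time(episodes, gear: int) -> float:
    vals = _gear_values(episodes, gear, "dwell_s")
    return float(np.mean(vals)) if vals else float("nan")


def mean_spatial_spread(episodes, gear: int) -> float:
    vals = _gear_values(episodes, gear, "path_cm")
    return float(np.mean(vals)) if vals else float("nan")


def curvature_window_intervals(config: PipelineConfig, sample_rate_hz: float) -> int:
    return max(1, int(round(config.curvature_window_s * sample_rate_hz)))


def episode_curvature(traj: Trajectory, episode: MotionEpisode, arena: ArenaSpec,
                      config: PipelineConfig, as_ratio: bool = False,
                      min_chord_cm: float = 0.1, positions_cm=None) -> float:
    """Mean path/chord curvature of an episode over 0.5 s windows.

    The episode is partitioned into consecutive non-overlapping windows of
    ``round(0.5 * rate)`` sample intervals (6 at 12.8 Hz); a trailing
    remainder is dropped.  Per window, ratio = summed path / endpoint chord;
    windows with chord < ``min_chord_cm`` are skipped to avoid unbounded
    ratios.  Returns mean (ratio - 1) * 100, or the raw mean ratio with
    ``as_ratio=True``; NaN if the episode is shorter than one window or no
    window has a usable chord.
    """
    w = curvature_window_intervals(config, traj.sample_rate_hz)
    a, b = episode.start, episode.end
    n_windows = (b - a) // w
    if n_windows < 1:
        return float("nan")
    xc, yc = positions_cm if positions_cm is not None else traj.positions_cm(arena)
    ratios = []
    for k in range(n_windows):
        s = a + k * w
        e = s + w
        dx = np.diff(xc[s:e + 1])
        dy = np.diff(yc[s:e + 1])
        path = float(np.hypot(dx, dy).sum())
        chord = math.hypot(xc[e] - xc[s], yc[e] - yc[s])
        if chord < min_chord_cm:
            continue
        ratios.append(path / chord)
    if not ratios:
        return float("nan")
    mean_ratio = float(np.mean(ratios))
    return mean_ratio if as_ratio else (mean_ratio - 1.0) * 100.0


def activity_profile(episodes, n_samples: int, sample_rate_hz: float,
                     bin_minutes: float = 10.0, phase_fraction: float = 0.2,
                     smooth_bins: int = 3):
    """Binned motion time and global activity phases.

    Returns ``(bin_start_s, motion_s, phases)`` where ``motion_s[k]`` is the
    seconds of motion-episode samples in bin ``k`` and ``phases`` is a list of
    ``(first_bin, last_bin)`` index pairs: maximal runs of bins whose smoothed
    (moving-average over ``smooth_bins`` bins) motion time exceeds
    ``phase_fraction`` of the peak bin.
    """
    bin_samples = max(1, int(round(bin_minutes * 60.0 * sample_rate_hz)))
    n_bins = int(math.ceil(n_samples / bin_samples))
    motion = np.zeros(n_samples, dtype=bool)
    for e in episodes:
        motion[e.start:e.end + 1] = True
    counts = np.bincount(np.arange(n_samples)[motion] // bin_samples, minlength=n_bins)
    motion_s = counts / sample_rate_hz
    bin_start_s = np.arange(n_bins) * bin_samples / sample_rate_hz
    if smooth_bins > 1 and n_bins >= smooth_bins:
        kernel = np.ones(smooth_bins) / smooth_bins
        smoothed = np.convolve(motion_s, kernel, mode="same")
    else:
        smoothed = motion_s.astype(float)
    phases = []
    peak = smoothed.max() if n_bins else 0.0
    if peak > 0:
        above = smoothed > phase_fraction * peak
        diff = np.diff(above.astype(np.int8))
        starts = list(np.flatnonzero(diff == 1) + 1)
        ends = list(np.flatnonzero(diff == -1))
        if above[0]:
            starts.insert(0, 0)
        if above[-1]:
            ends.append(n_bins - 1)
        phases = list(zip(starts, ends))
    return bin_start_s, motion_s, phases


def compute_endpoints(traj: Trajectory, episodes, arena: ArenaSpec,
                      config: PipelineConfig) -> EndpointSet:
    """Populate the full endpoint set for one recording.

    Episodes must already carry gear labels; curvature is computed here for
    episodes that do not have it yet.
    """
    if any(e.gear is None for e in episodes):
        raise ValueError("episodes must be gear-labelled before endpoint computation")
    pos_cm = traj.positions_cm(arena)
    labelled = []
    for e in episodes:
        if e.curvature_pct is None:
            c = episode_curvature(traj, e, arena, config, positions_cm=pos_cm)
            e = MotionEpisode(**{**e.__dict__, "curvature_pct": c})
        labelled.append(e)
    ep = EndpointSet(
        incidence2_pct=incidence_second_gear(labelled),
        distance_m=total_distance(labelled),
    )
    for g in GEARS:
        ep.n_episodes[g] = sum(1 for e in labelled if e.gear == g)
        ep.mean_max_speed_cms[g] = mean_max_speed(labelled, g)
        ep.mean_dwell_s[g] = mean_dwell_time(labelled, g)
        ep.mean_spread_cm[g] = mean_spatial_spread(labelled, g)
        curv = [e.curvature_pct for e in labelled
                if e.gear == g and e.curvature_pct is not None and not math.isnan(e.curvature_pct)]
        ep.mean_curvature_pct[g] = float(np.mean(curv)) if curv else float("nan")
    return ep
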