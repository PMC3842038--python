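"""Windowed speed computation and rest/motion episode segmentation.

Speed at sample ``i`` is the cm displacement between the positions ``h``
samples before and after, divided by the window duration ``2h / rate``, with
``h = round(speed_window_s * rate / 2)`` sample intervals (0.3 s at 12.8 Hz
gives h = 2, a 4-interval window of ~0.3125 s).  Speed is undefined wherever
any sample of the window is invalid.

Motion episodes are maximal runs of defined speed >= the 4 cm/s noise
threshold (inclusive); runs shorter than one full speed window carry no
well-defined windowed maximum and are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ArenaSpec, PipelineConfig, Trajectory

__all__ = [
    "SpeedSeries",
    "MotionEpisode",
    "speed_half_width",
    "compute_speed",
    "segment_episodes",
    "episodes_to_frame",
    "frame_to_episodes",
]


@dataclass
class SpeedSeries:
    """Per-sample windowed speed in cm/s; NaN where undefined."""

    speed: np.ndarray
    window_s: float
    half_width: int
    sample_rate_hz: float


@dataclass
class MotionEpisode:
    """One maximal supra-threshold run of motion.

    ``log_max_sd`` is log10 of the maximal windowed speed reached within the
    episode ("log max-SD"); ``gear`` (1 slow / 2 fast) and ``curvature_pct``
    are filled by the gear-assignment and endpoint stages.
    """

    start: int
    end: int  # inclusive
    dwell_s: float
    path_cm: float
    max_speed_cms: float
    log_max_sd: float
    gear: int | None = None
    curvature_pct: float | None = None


def speed_half_width(config: PipelineConfig, sample_rate_hz: float) -> int:
    """Half-width of the speed window in sample intervals (>= 1)."""
    return max(1, int(round(config.speed_window_s * sample_rate_hz / 2.0)))


def compute_speed(traj: Trajectory, arena: ArenaSpec, config: PipelineConfig) -> SpeedSeries:
    """Centered endpoint-displacement speed over a symmetric window."""
    n = len(traj)
    h = speed_half_width(config, traj.sample_rate_hz)
    if 2 * h >= n:
        raise ValueError(f"speed window ({2 * h} intervals) longer than recording ({n} samples)")
    xc, yc = traj.positions_cm(arena)
    speed = np.full(n, np.nan)
    # a sample is defined when all samples in [i-h, i+h] are valid
    ok = traj.valid.astype(np.int64)
    csum = np.concatenate(([0], np.cumsum(ok)))
    win = 2 * h + 1
    all_valid = (csum[win:] - csum[:-win]) == win  # for centers h .. n-h-1
    centers = np.arange(h, n - h)
    sel = centers[all_valid]
    dt = 2 * h / traj.sample_rate_hz
    dx = xc[sel + h] - xc[sel - h]
    dy = yc[sel + h] - yc[sel - h]
    speed[sel] = np.hypot(dx, dy) / dt
    return SpeedSeries(speed=speed, window_s=config.speed_window_s, half_width=h,
                       sample_rate_hz=traj.sample_rate_hz)


def _runs(mask: np.ndarray):
    """(start, end_inclusive) pairs of maximal True runs."""
    if mask.size == 0:
        return []
    m = mask.astype(np.int8)
    diff = np.diff(m)
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1))
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size - 1)
    return list(zip(starts, ends))


def segment_episodes(speed: SpeedSeries, traj: Trajectory, arena: ArenaSpec,
                     config: PipelineConfig) -> list[MotionEpisode]:
    """Split the recording into motion episodes at the noise threshold."""
    s = speed.speed
    above = np.zeros(s.shape, dtype=bool)
    defined = ~np.isnan(s)
    above[defined] = s[defined] >= config.vnoise_cms
    min_len = 2 * speed.half_width + 1  # one full speed window
    xc, yc = traj.positions_cm(arena)
    rate = traj.sample_rate_hz
    episodes: list[MotionEpisode] = []
    for a, b in _runs(above):
        if b - a + 1 < min_len:
            continue
        seg_dx = np.diff(xc[a:b + 1])
        seg_dy = np.diff(yc[a:b + 1])
        path = float(np.hypot(seg_dx, seg_dy).sum())
        vmax = float(np.nanmax(s[a:b + 1]))
        episodes.append(MotionEpisode(
            start=int(a), end=int(b),
            dwell_s=(b - a + 1) / rate,
            path_cm=path,
            max_speed_cms=vmax,
            log_max_sd=float(np.log10(vmax)),
        ))
    return episodes


_EPISODE_COLS = ["start", "end", "dwell_s", "path_cm", "max_speed_cms",
                 "log_max_sd", "gear", "curvature_pct"]


def episodes_to_frame(episodes: list[MotionEpisode]) -> pd.DataFrame:
    rows = [{c: getattr(e, c) for c in _EPISODE_COLS} for e in episodes]
    return pd.DataFrame(rows, columns=_EPISODE_COLS)


def frame_to_episodes(df: pd.DataFrame) -> list[MotionEpisode]:
    eps = []
    for row in df.itertuples(index=False):
        gear = None if pd.isna(row.gear) else int(row.gear)
        curv = None if pd.isna(row.curvature_pct) else float(row.curvature_pct)
        eps.append(MotionEpisode(
            start=int(row.start), end=int(row.end), dwell_s=float(row.dwell_s),
            path_cm=float(row.path_cm), max_speed_cms=float(row.max_speed_cms),
            log_max_sd=float(row.log_max_sd), gear=gear, curvature_pct=curv,
        ))
    return eps
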