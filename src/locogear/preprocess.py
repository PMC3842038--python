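"""Tracking-artifact rejection and single-gap interpolation.

Four steps, applied in the pipeline's canonical order:

1. spatial outlier rejection (positions outside the arena raster),
2. revisited-pixel removal (pixels with >= 2 distinct visits are blacklisted,
   which eliminates resting-spot jump artifacts),
3. low-pass speed filtering at 80 cm/s (teleport spikes),
4. linear interpolation of single missing samples.

Each step appends a provenance record ``{"step", "n_invalidated"}`` (the
interpolation step records ``"n_restored"``) so sample accounting is exact.
"""

from __future__ import annotations

import math

import numpy as np

from .io import ArenaSpec, PipelineConfig, Trajectory

__all__ = [
    "reject_spatial_outliers",
    "remove_revisited_pixels",
    "lowpass_speed_filter",
    "interpolate_single_gaps",
    "preprocess",
]


def _log(traj: Trajectory, step: str, **counts) -> None:
    traj.provenance.append({"step": step, **counts})


def reject_spatial_outliers(traj: Trajectory, arena: ArenaSpec) -> Trajectory:
    """Invalidate samples whose coordinates fall outside the pixel raster."""
    out = traj.copy()
    bad = out.valid & (
        (out.x < 0) | (out.x > arena.width_px) | (out.y < 0) | (out.y > arena.height_px)
    )
    out.valid[bad] = False
    out.interpolated[bad] = False
    _log(out, "spatial_outliers", n_invalidated=int(bad.sum()))
    return out


def remove_revisited_pixels(traj: Trajectory, config: PipelineConfig) -> Trajectory:
    """Blacklist pixels visited at least ``revisit_min_visits`` times.

    Positions are binned to integer pixels by floor.  A *visit* is a maximal
    run of consecutive valid samples binned to the same pixel (so slowly
    crossing a pixel once counts once, however many samples it takes).  All
    samples on blacklisted pixels are invalidated.  With
    ``revisit_mode="samples"`` raw sample occupancy is counted instead.
    """
    out = traj.copy()
    if not config.revisit_enabled:
        _log(out, "revisited_pixels", n_invalidated=0)
        return out
    idx = np.flatnonzero(out.valid)
    if idx.size == 0:
        _log(out, "revisited_pixels", n_invalidated=0)
        return out
    fx = np.floor(out.x[idx]).astype(np.int64)
    fy = np.floor(out.y[idx]).astype(np.int64)
    pid = fx * (1 << 21) + fy  # injective for any realistic raster

    if config.revisit_mode == "samples":
        pixels, counts = np.unique(pid, return_counts=True)
    else:
        starts = np.ones(idx.size, dtype=bool)
        starts[1:] = (np.diff(idx) != 1) | (pid[1:] != pid[:-1])
        pixels, counts = np.unique(pid[starts], return_counts=True)

    blacklist = pixels[counts >= config.revisit_min_visits]
    bad_local = np.isin(pid, blacklist)
    bad = idx[bad_local]
    out.valid[bad] = False
    out.interpolated[bad] = False
    _log(out, "revisited_pixels", n_invalidated=int(bad.size))
    return out


def lowpass_speed_filter(traj: Trajectory, arena: ArenaSpec, config: PipelineConfig) -> Trajectory:
    """Invalidate samples implying instantaneous speed above ``vmax_cms``.

    Single forward pass maintaining a reference ("last consistent") sample:
    each candidate is compared against the reference with the instantaneous
    speed cm-distance / inter-sample interval; an offending later sample is
    flagged and never becomes the reference, so a 1-3 sample teleport spike
    is removed without cascading deletion of the true path that follows.

    The reference set is every sample whose coordinates lie inside the arena
    raster and that has not itself been flagged — including samples the
    revisit rule already invalidated.  Those were removed for sitting on
    overused *locations*, not for carrying wrong coordinates, and skipping
    them would blind the filter to spikes that occur inside removed resting
    stretches.  Flagging only ever invalidates currently valid samples.
    """
    out = traj.copy()
    n = len(out)
    if n < 2:
        _log(out, "lowpass_speed", n_invalidated=0)
        return out
    in_arena = (
        (out.x >= 0) & (out.x <= arena.width_px) & (out.y >= 0) & (out.y <= arena.height_px)
        & ~np.isnan(out.x) & ~np.isnan(out.y)
    )
    cand = np.flatnonzero(in_arena)
    if cand.size < 2:
        _log(out, "lowpass_speed", n_invalidated=0)
        return out
    xc, yc = out.positions_cm(arena)
    rate = out.sample_rate_hz
    vmax = config.vmax_cms
    last = cand[0]
    xl = float(xc[last])
    yl = float(yc[last])
    dropped = []
    for i in cand[1:]:
        dt = (i - last) / rate
        d = math.hypot(xc[i] - xl, yc[i] - yl)
        if d / dt > vmax:
            if out.valid[i]:
                dropped.append(i)
        else:
            last = i
            xl = float(xc[i])
            yl = float(yc[i])
    dropped = np.asarray(dropped, dtype=np.int64)
    out.valid[dropped] = False
    out.interpolated[dropped] = False
    _log(out, "lowpass_speed", n_invalidated=int(dropped.size))
    return out


def interpolate_single_gaps(traj: Trajectory, config: PipelineConfig) -> Trajectory:
    """Fill invalid runs of up to ``max_interp_gap`` samples (default 1).

    A run qualifies only if flanked by valid samples on both sides; filled
    coordinates are linear interpolations per axis and the samples are marked
    valid and ``interpolated``.  Longer runs are left untouched.
    """
    out = traj.copy()
    v = out.valid
    n = len(v)
    if n == 0 or config.max_interp_gap == 0:
        _log(out, "interpolate_single_gaps", n_restored=0)
        return out
    inv = ~v
    # run-length encode invalid stretches
    edges = np.flatnonzero(np.diff(inv.astype(np.int8)))
    starts = edges[inv[edges + 1]] + 1 if edges.size else np.array([], dtype=int)
    if inv[0]:
        starts = np.concatenate(([0], starts))
    restored = 0
    for s in starts:
        e = s
        while e + 1 < n and inv[e + 1]:
            e += 1
        length = e - s + 1
        if length > config.max_interp_gap:
            continue
        if s == 0 or e == n - 1:
            continue  # not flanked on both sides
        x0, y0 = out.x[s - 1], out.y[s - 1]
        x1, y1 = out.x[e + 1], out.y[e + 1]
        for k, i in enumerate(range(s, e + 1), start=1):
            t = k / (length + 1)
            out.x[i] = x0 + t * (x1 - x0)
            out.y[i] = y0 + t * (y1 - y0)
            out.valid[i] = True
            out.interpolated[i] = True
        restored += int(length)
    _log(out, "interpolate_single_gaps", n_restored=restored)
    return out


def preprocess(traj: Trajectory, arena: ArenaSpec, config: PipelineConfig) -> Trajectory:
    """Full artifact-rejection chain in the canonical order."""
    t = reject_spatial_outliers(traj, arena)
    t = remove_revisited_pixels(t, config)
    t = lowpass_speed_filter(t, arena, config)
    t = interpolate_single_gaps(t, config)
    return t
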