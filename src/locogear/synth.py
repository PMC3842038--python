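"""Ground-truth-labelled synthetic open-field recordings.

Emulates 12.8 Hz video-tracking of a rat in a 70 x 100 cm arena (320 x 435
px): rest bouts at fixed positions alternate with motion episodes whose
maximal speed is drawn from a two-gear lognormal structure (log10 centers
0.71 and 1.24 by default), with circadian modulation of the episode rate and
the three canonical tracking-artifact types injected on top (out-of-arena
outliers, jumps to resting-corner pixels, in-arena teleports).

Design notes:

* Within an episode the speed profile is a raised-cosine bump from a floor
  just above the 4 cm/s noise threshold up to the drawn maximum and back;
  the bump is rescaled so the *windowed* (0.3 s) maximal speed equals the
  drawn value, making gear centers analytically controllable.
* Headings follow a correlated random walk; walls reflect the path.
* The animal rests where an episode ends (plus sub-pixel jitter, so rest
  never crosses the noise threshold); ``rest_spots`` provide the initial
  position and the corner-jump artifact targets.  Literal walk-backs to a
  corner after every episode would create heavily retraced corridors that
  the revisited-pixel rule blacklists wholesale, which would erase genuine
  motion rather than resting-spot artifacts.
* Ground-truth episode ranges are obtained by applying the analysis
  definition of an episode (windowed speed >= 4 cm/s, minimum one full
  window) to the noiseless path, using an independent re-implementation of
  the windowed speed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import ArenaSpec, Trajectory

__all__ = [
    "SynthConfig",
    "EpisodeTruth",
    "GroundTruth",
    "generate_recording",
    "inject_artifacts",
    "generate_stereo_counts",
    "lesioned_config",
    "write_ground_truth",
    "read_ground_truth",
]

# analysis constants the generator emulates (noise threshold, speed window)
_VNOISE_CMS = 4.0
_SPEED_WINDOW_S = 0.3
_SPEED_FLOOR_CMS = 4.2  # episode speed floor, just above the noise threshold

ARTIFACT_TYPES = ("out_of_arena", "corner_jump", "teleport")

# two active phases separated by a quiescent phase over the 24 h cycle
DEFAULT_CIRCADIAN = tuple([1.6] * 8 + [0.25] * 8 + [1.4] * 8)


def _default_rest_spots():
    return ((12.0, 12.0), (308.0, 12.0), (12.0, 423.0), (308.0, 423.0))


def _default_artifact_rates():
    return {"out_of_arena": 0.003, "corner_jump": 0.003, "teleport": 0.003}


@dataclass
class SynthConfig:
    """Generator parameters; defaults emulate the study's recording setup."""

    duration_s: float = 23 * 3600.0
    sample_rate_hz: float = 12.8
    arena: ArenaSpec = field(default_factory=ArenaSpec)
    episode_rate: float = 1.2  # episodes per minute, baseline
    circadian_profile: tuple = DEFAULT_CIRCADIAN
    p_second_gear: float = 0.5
    gear_log_centers: tuple = (0.71, 1.24)
    gear_log_sds: tuple = (0.05, 0.10)
    dwell_mean_s: tuple = (1.0, 1.3)
    dwell_log_sigma: float = 0.3
    heading_persistence: float = 0.94
    rest_spots: tuple = field(default_factory=_default_rest_spots)
    artifact_rates: dict = field(default_factory=_default_artifact_rates)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("SynthConfig.duration_s must be > 0")
        if self.sample_rate_hz <= 0:
            raise ValueError("SynthConfig.sample_rate_hz must be > 0")
        if not 0 <= self.p_second_gear <= 1:
            raise ValueError("SynthConfig.p_second_gear must be in [0, 1]")
        if self.episode_rate <= 0:
            raise ValueError("SynthConfig.episode_rate must be > 0")
        if len(self.circadian_profile) < 1 or any(m < 0 for m in self.circadian_profile):
            raise ValueError("SynthConfig.circadian_profile multipliers must be >= 0")
        if max(self.circadian_profile) == 0:
            raise ValueError("SynthConfig.circadian_profile must have a positive phase")
        if not self.gear_log_centers[0] < self.gear_log_centers[1]:
            raise ValueError("SynthConfig.gear_log_centers must be ascending")
        if any(s <= 0 for s in self.gear_log_sds):
            raise ValueError("SynthConfig.gear_log_sds must be > 0")
        if any(d <= 0 for d in self.dwell_mean_s):
            raise ValueError("SynthConfig.dwell_mean_s must be > 0")
        if self.dwell_log_sigma <= 0:
            raise ValueError("SynthConfig.dwell_log_sigma must be > 0")
        if not 0 <= self.heading_persistence < 1:
            raise ValueError("SynthConfig.heading_persistence must be in [0, 1)")
        if not self.rest_spots:
            raise ValueError("SynthConfig.rest_spots must be nonempty")
        unknown = set(self.artifact_rates) - set(ARTIFACT_TYPES)
        if unknown:
            raise ValueError(f"SynthConfig.artifact_rates has unknown types: {sorted(unknown)}")
        if any(r < 0 for r in self.artifact_rates.values()):
            raise ValueError("SynthConfig.artifact_rates must be >= 0")


def lesioned_config(base: SynthConfig | None = None, **overrides) -> SynthConfig:
    """A post-lesion phenotype: fewer and slower fast episodes, longer dwell,
    larger spread and more tortuous paths."""
    base = base or SynthConfig()
    params = dict(
        p_second_gear=0.35,
        gear_log_centers=(0.71, 1.175),
        dwell_mean_s=(1.5, 1.95),
        heading_persistence=max(0.0, base.heading_persistence - 0.08),
    )
    cfg = asdict_shallow(base)
    cfg.update(params)
    cfg.update(overrides)
    return SynthConfig(**cfg)


def asdict_shallow(config: SynthConfig) -> dict:
    return {
        "duration_s": config.duration_s,
        "sample_rate_hz": config.sample_rate_hz,
        "arena": config.arena,
        "episode_rate": config.episode_rate,
        "circadian_profile": config.circadian_profile,
        "p_second_gear": config.p_second_gear,
        "gear_log_centers": config.gear_log_centers,
        "gear_log_sds": config.gear_log_sds,
        "dwell_mean_s": config.dwell_mean_s,
        "dwell_log_sigma": config.dwell_log_sigma,
        "heading_persistence": config.heading_persistence,
        "rest_spots": config.rest_spots,
        "artifact_rates": dict(config.artifact_rates),
        "seed": config.seed,
    }


@dataclass
class EpisodeTruth:
    start: int
    end: int  # inclusive
    gear: int
    max_speed_cms: float


@dataclass
class GroundTruth:
    episodes: list
    artifact_samples: list  # (index, type) pairs
    clean_positions: np.ndarray  # (n, 2) pixel coordinates


def _fold(a: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect coordinates into [lo, hi] (billiard reflection at the walls)."""
    period = 2.0 * (hi - lo)
    b = np.mod(a - lo, period)
    return lo + np.minimum(b, period - b)


def _windowed_speed_1d(xcm: np.ndarray, ycm: np.ndarray, h: int, rate: float) -> np.ndarray:
    n = xcm.size
    w = np.full(n, np.nan)
    if n > 2 * h:
        dt = 2 * h / rate
        d = np.hypot(xcm[2 * h:] - xcm[:-2 * h], ycm[2 * h:] - ycm[:-2 * h])
        w[h:n - h] = d / dt
    return w


def _speed_half_width(rate: float) -> int:
    return max(1, int(round(_SPEED_WINDOW_S * rate / 2.0)))


def _episode_step_speeds(vmax: float, m: int, h: int, rate: float) -> np.ndarray:
    """Raised-cosine step-speed profile, rescaled so the windowed maximum of a
    straight-line realization equals ``vmax``."""
    f = min(_SPEED_FLOOR_CMS, 0.8 * vmax)
    k = np.arange(m - 1)
    bump = 0.5 * (1.0 - np.cos(2.0 * np.pi * (k + 0.5) / (m - 1)))
    v = f + (vmax - f) * bump
    # windowed max of the straight path (window fully inside the episode)
    if m - 1 >= 2 * h:
        kernel = np.ones(2 * h) / (2 * h)
        wcenter = np.convolve(v, kernel, mode="valid").max()
        if wcenter > f:
            alpha = (vmax - f) / (wcenter - f)
            v = f + alpha * (v - f)
    return v


def generate_recording(config: SynthConfig):
    """Generate one corrupted recording plus its ground truth.

    Returns ``(Trajectory, GroundTruth)``; the trajectory carries the
    artifact-injected positions (all samples marked valid, as delivered by a
    tracker), the ground truth carries episode ranges with gear labels and
    intended maximal speeds, the artifact log and the clean positions.
    """
    rate = config.sample_rate_hz
    arena = config.arena
    n = int(round(config.duration_s * rate))
    dt = 1.0 / rate
    h = _speed_half_width(rate)
    ss = np.random.SeedSequence(config.seed)
    sched_rng, motion_rng, rest_rng, art_rng = [np.random.default_rng(c) for c in ss.spawn(4)]

    profile = np.asarray(config.circadian_profile, dtype=float)
    lam_max = config.episode_rate / 60.0 * profile.max()

    def lam(t: float) -> float:
        idx = int((t % 86400.0) / 86400.0 * profile.size)
        return config.episode_rate / 60.0 * profile[min(idx, profile.size - 1)]

    x = np.empty(n)
    y = np.empty(n)
    sx, sy = config.rest_spots[0]
    cur_px = np.array([math.floor(sx) + 0.5, math.floor(sy) + 0.5])
    heading = float(sched_rng.uniform(-math.pi, math.pi))
    sigma_theta = (1.0 - config.heading_persistence) * math.pi

    bumps = []  # (start, end_exclusive, gear, vmax)
    i = 0
    t = 0.0
    while i < n:
        # next episode time via thinning of an inhomogeneous Poisson process
        te = t
        while True:
            te += sched_rng.exponential(1.0 / lam_max)
            if te >= config.duration_s:
                te = math.inf
                break
            if sched_rng.uniform() < lam(te) / (config.episode_rate / 60.0 * profile.max()):
                break
        gap_end = n if math.isinf(te) else min(n, int(round(te * rate)))
        # at least one full speed window of rest keeps adjacent episodes
        # unambiguous in the ground truth
        gap_end = max(gap_end, min(n, i + 2 * h + 1))
        # rest bout: sub-pixel jitter around the current pixel center
        m_rest = gap_end - i
        cx = math.floor(cur_px[0]) + 0.5
        cy = math.floor(cur_px[1]) + 0.5
        x[i:gap_end] = cx + rest_rng.uniform(-0.3, 0.3, m_rest)
        y[i:gap_end] = cy + rest_rng.uniform(-0.3, 0.3, m_rest)
        cur_px = np.array([cx, cy])
        i = gap_end
        t = i * dt
        if i >= n:
            break

        # motion episode
        gear = 2 if motion_rng.uniform() < config.p_second_gear else 1
        g = gear - 1
        vmax = float(10.0 ** motion_rng.normal(config.gear_log_centers[g], config.gear_log_sds[g]))
        mean_d = config.dwell_mean_s[g]
        sig = config.dwell_log_sigma
        d_s = float(np.exp(motion_rng.normal(math.log(mean_d) - sig**2 / 2.0, sig)))
        d_s = min(max(d_s, 0.7), 8.0 * mean_d)
        m = max(8, int(round(d_s * rate)) + 1)
        m = min(m, n - i + 1)
        if m < 3:
            break
        v = _episode_step_speeds(vmax, m, h, rate)
        dtheta = motion_rng.normal(0.0, sigma_theta, m - 1)
        theta = heading + motion_rng.normal(0.0, 0.6) + np.cumsum(dtheta)
        step = v * dt
        cur_cm = np.array([cur_px[0] * arena.cm_per_px_x, cur_px[1] * arena.cm_per_px_y])
        ex = cur_cm[0] + np.cumsum(step * np.cos(theta))
        ey = cur_cm[1] + np.cumsum(step * np.sin(theta))
        ex = _fold(ex, 0.2, arena.width_cm - 0.2)
        ey = _fold(ey, 0.2, arena.height_cm - 0.2)
        # sample i is the last rest sample; the episode occupies i .. i+m-2
        px = ex / arena.cm_per_px_x
        py = ey / arena.cm_per_px_y
        end = min(n, i + m - 1)
        x[i:end] = px[: end - i]
        y[i:end] = py[: end - i]
        bumps.append((i, end, gear, vmax))
        if end - i >= 2:
            heading = math.atan2(py[end - i - 1] - py[end - i - 2],
                                 px[end - i - 1] - px[end - i - 2])
        cur_px = np.array([px[end - i - 1], py[end - i - 1]])
        i = end
        t = i * dt

    clean = np.column_stack([x, y])

    # ground-truth episode ranges: the analysis definition applied to the
    # noiseless path (independent windowed-speed implementation)
    xcm = x * arena.cm_per_px_x
    ycm = y * arena.cm_per_px_y
    w = _windowed_speed_1d(xcm, ycm, h, rate)
    above = np.zeros(n, dtype=bool)
    defined = ~np.isnan(w)
    above[defined] = w[defined] >= _VNOISE_CMS
    min_len = 2 * h + 1
    diff = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1))
    if above.size and above[0]:
        starts.insert(0, 0)
    if above.size and above[-1]:
        ends.append(n - 1)
    bump_starts = np.array([b[0] for b in bumps], dtype=int)
    best_by_bump: dict[int, tuple[int, int]] = {}
    for a, b in zip(starts, ends):
        if b - a + 1 < min_len:
            continue
        mid = (a + b) // 2
        j = int(np.searchsorted(bump_starts, mid, side="right")) - 1
        if j < 0:
            continue
        prev = best_by_bump.get(j)
        if prev is None or (b - a) > (prev[1] - prev[0]):
            best_by_bump[j] = (a, b)
    episodes = [
        EpisodeTruth(start=int(a), end=int(b), gear=int(bumps[j][2]),
                     max_speed_cms=float(bumps[j][3]))
        for j, (a, b) in sorted(best_by_bump.items())
    ]

    corrupted, art_log = _inject_artifacts(clean, config, art_rng)
    traj = Trajectory(sample_rate_hz=rate, x=corrupted[:, 0], y=corrupted[:, 1],
                      valid=np.ones(n, dtype=bool))
    truth = GroundTruth(episodes=episodes, artifact_samples=art_log, clean_positions=clean)
    return traj, truth


def inject_artifacts(positions: np.ndarray, config: SynthConfig):
    """Corrupt a clean position series with the configured artifact types.

    ``positions`` is an (n, 2) pixel-coordinate array.  Returns a corrupted
    copy and a log of ``(index, type)`` pairs.  Bouts are 1-3 samples and the
    series returns to the true path afterwards.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    return _inject_artifacts(np.asarray(positions, dtype=float), config, rng)


def _bout_lengths(rng, n_bouts: int) -> np.ndarray:
    return rng.choice([1, 2, 3], size=n_bouts, p=[0.6, 0.25, 0.15])


def _inject_artifacts(positions: np.ndarray, config: SynthConfig, rng):
    n = positions.shape[0]
    arena = config.arena
    out = positions.copy()
    log: list[tuple[int, str]] = []
    mean_len = 1.0 * 0.6 + 2.0 * 0.25 + 3.0 * 0.15
    wanted = {k: int(round(config.artifact_rates.get(k, 0.0) * n / mean_len))
              for k in ARTIFACT_TYPES}
    total_samples = sum(wanted.values()) * 3
    if total_samples > n:
        raise ValueError("artifact rates imply more artifact samples than recording length")
    if sum(wanted.values()) == 0:
        return out, log

    # place bouts with >= 4 samples separation, away from the recording edges
    bouts = []
    for typ in ARTIFACT_TYPES:
        for ln in _bout_lengths(rng, wanted[typ]):
            bouts.append((typ, int(ln)))
    rng.shuffle(bouts)
    taken = np.zeros(n, dtype=bool)
    placed = []
    guard = 0
    bi = 0
    while bi < len(bouts) and guard < 50 * len(bouts):
        guard += 1
        typ, ln = bouts[bi]
        s = int(rng.integers(2, n - ln - 4))
        lo = max(0, s - 4)
        if taken[lo: s + ln + 4].any():
            continue
        taken[lo: s + ln + 4] = True
        placed.append((s, ln, typ))
        bi += 1
    if bi < len(bouts):
        raise ValueError("could not place all requested artifact bouts; lower the rates")

    cmx, cmy = arena.cm_per_px_x, arena.cm_per_px_y
    for s, ln, typ in sorted(placed):
        anchor = positions[s - 1]  # last true sample before the bout
        for k in range(ln):
            i = s + k
            if typ == "out_of_arena":
                side = rng.integers(0, 4)
                off = rng.uniform(3.0, 40.0)
                if side == 0:
                    out[i] = (-off, rng.uniform(0, arena.height_px))
                elif side == 1:
                    out[i] = (arena.width_px + off, rng.uniform(0, arena.height_px))
                elif side == 2:
                    out[i] = (rng.uniform(0, arena.width_px), -off)
                else:
                    out[i] = (rng.uniform(0, arena.width_px), arena.height_px + off)
            elif typ == "corner_jump":
                spots = np.asarray(config.rest_spots, dtype=float)
                d = np.hypot((spots[:, 0] - anchor[0]) * cmx, (spots[:, 1] - anchor[1]) * cmy)
                sx, sy = spots[int(np.argmax(d))]
                out[i] = (math.floor(sx) + 0.5 + rng.uniform(-0.3, 0.3),
                          math.floor(sy) + 0.5 + rng.uniform(-0.3, 0.3))
            else:  # teleport: in-arena, far from both predecessor and true path
                prev = out[i - 1]
                while True:
                    cand = np.array([rng.uniform(2, arena.width_px - 2),
                                     rng.uniform(2, arena.height_px - 2)])
                    d_prev = math.hypot((cand[0] - prev[0]) * cmx, (cand[1] - prev[1]) * cmy)
                    d_anchor = math.hypot((cand[0] - anchor[0]) * cmx, (cand[1] - anchor[1]) * cmy)
                    if d_prev >= 25.0 and d_anchor >= 25.0:
                        break
                out[i] = cand
            log.append((i, typ))
    log.sort()
    return out, log


def generate_stereo_counts(n_per_group: int, group_means: dict | None = None,
                           group_cv: float = 0.2, lesion_effect: dict | None = None,
                           seed: int = 0) -> pd.DataFrame:
    """Synthetic per-hemisphere cell-count tables for two groups.

    ``group_means`` are combined (two-hemisphere) control means per ROI;
    per-hemisphere counts are drawn lognormally around half the combined mean
    with coefficient of variation ``group_cv``; lesioned means are multiplied
    by (1 - reduction) per ROI.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if group_cv <= 0:
        raise ValueError("group_cv must be > 0")
    group_means = dict(group_means or {"SNc": 5098.0, "VTA": 6318.0})
    lesion_effect = dict(lesion_effect or {"SNc": 0.95, "VTA": 0.514})
    if any(m <= 0 for m in group_means.values()):
        raise ValueError("group means must be > 0")
    if any(not 0 <= r <= 1 for r in lesion_effect.values()):
        raise ValueError("lesion reductions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sigma2 = math.log(1.0 + group_cv**2)
    sigma = math.sqrt(sigma2)
    rows = []
    for group in ("control", "lesion"):
        for a in range(n_per_group):
            for roi, mean in group_means.items():
                hemi_mean = mean / 2.0
                if group == "lesion":
                    hemi_mean *= 1.0 - lesion_effect.get(roi, 0.0)
                for hemi in ("LH", "RH"):
                    if hemi_mean == 0:
                        est = 0.0
                    else:
                        mu = math.log(hemi_mean) - sigma2 / 2.0
                        est = float(rng.lognormal(mu, sigma))
                    rows.append({"animal": f"{group}{a:02d}", "group": group,
                                 "hemisphere": hemi, "roi": roi, "estimate": est})
    return pd.DataFrame(rows)


def write_ground_truth(truth: GroundTruth, path) -> None:
    data = {
        "episodes": [asdict(e) for e in truth.episodes],
        "artifact_samples": [[int(i), t] for i, t in truth.artifact_samples],
        "clean_positions": truth.clean_positions.tolist(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh)


def read_ground_truth(path) -> GroundTruth:
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    return GroundTruth(
        episodes=[EpisodeTruth(**e) for e in data["episodes"]],
        artifact_samples=[(int(i), str(t)) for i, t in data["artifact_samples"]],
        clean_positions=np.asarray(data["clean_positions"], dtype=float),
    )
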