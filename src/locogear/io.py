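"""Trajectory data model, arena geometry, unit conversion and file formats.

Coordinate convention: origin at the arena's top-left corner, x increases
rightward, y downward, 0-based continuous pixel coordinates (the frame-grabber
convention).  Pixel scaling is anisotropic: the default 70 x 100 cm arena is
digitized at 320 x 435 px, so a pixel is 0.21875 cm wide and ~0.22989 cm tall.
All speeds and distances are computed in cm after conversion.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ArenaSpec",
    "Trajectory",
    "PipelineConfig",
    "read_tracking",
    "write_tracking",
    "to_cm",
    "load_pipeline_config",
    "save_pipeline_config",
]


@dataclass(frozen=True)
class ArenaSpec:
    """Physical and digitized dimensions of the open-field arena."""

    width_cm: float = 70.0
    height_cm: float = 100.0
    width_px: float = 320.0
    height_px: float = 435.0
    origin: str = "top-left"

    def __post_init__(self) -> None:
        for name in ("width_cm", "height_cm", "width_px", "height_px"):
            if not getattr(self, name) > 0:
                raise ValueError(f"ArenaSpec.{name} must be > 0")

    @property
    def cm_per_px_x(self) -> float:
        return self.width_cm / self.width_px

    @property
    def cm_per_px_y(self) -> float:
        return self.height_cm / self.height_px

    def to_cm(self, x_px, y_px):
        """Convert pixel coordinates to cm (per-axis linear scaling)."""
        return (
            np.asarray(x_px, dtype=float) * self.cm_per_px_x,
            np.asarray(y_px, dtype=float) * self.cm_per_px_y,
        )


@dataclass
class Trajectory:
    """Time series of x-y positions (pixels) with a per-sample validity mask.

    ``interpolated`` marks samples whose coordinates were restored by
    single-gap interpolation; they are valid but not original measurements.
    ``provenance`` records each preprocessing step applied, in order.
    """

    sample_rate_hz: float
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    interpolated: np.ndarray | None = None
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.interpolated is None:
            self.interpolated = np.zeros(self.x.shape, dtype=bool)
        else:
            self.interpolated = np.asarray(self.interpolated, dtype=bool)
        if not (len(self.x) == len(self.y) == len(self.valid) == len(self.interpolated)):
            raise ValueError("x, y, valid, interpolated must have equal length")
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be > 0")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def n_samples(self) -> int:
        return len(self.x)

    @property
    def duration_s(self) -> float:
        return len(self.x) / self.sample_rate_hz

    def copy(self) -> "Trajectory":
        return Trajectory(
            sample_rate_hz=self.sample_rate_hz,
            x=self.x.copy(),
            y=self.y.copy(),
            valid=self.valid.copy(),
            interpolated=self.interpolated.copy(),
            provenance=list(self.provenance),
        )

    def positions_cm(self, arena: ArenaSpec):
        return arena.to_cm(self.x, self.y)


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis parameters.

    Defaults follow the published pipeline: an 80 cm/s low-pass speed
    threshold, a 4 cm/s rest/motion noise threshold, a 0.3 s speed window,
    0.5 s curvature windows, a 10 cm/s (log10 = 1) gear split and
    interpolation of single missing samples.
    """

    vmax_cms: float = 80.0
    vnoise_cms: float = 4.0
    speed_window_s: float = 0.3
    curvature_window_s: float = 0.5
    gear_threshold_cms: float = 10.0
    max_interp_gap: int = 1
    revisit_enabled: bool = True
    revisit_min_visits: int = 2
    revisit_mode: str = "visits"  # "visits" (distinct visits) or "samples"

    def __post_init__(self) -> None:
        if not (0 < self.vnoise_cms < self.gear_threshold_cms < self.vmax_cms):
            raise ValueError(
                "require 0 < vnoise_cms < gear_threshold_cms < vmax_cms"
            )
        if self.speed_window_s <= 0 or self.curvature_window_s <= 0:
            raise ValueError("window lengths must be > 0")
        if self.max_interp_gap < 0:
            raise ValueError("max_interp_gap must be >= 0")
        if self.revisit_min_visits < 1:
            raise ValueError("revisit_min_visits must be >= 1")
        if self.revisit_mode not in ("visits", "samples"):
            raise ValueError("revisit_mode must be 'visits' or 'samples'")


def read_tracking(path, arena: ArenaSpec | None = None, sample_rate_hz: float = 12.8) -> Trajectory:
    """Read a tracking CSV (``sample,x_px,y_px``; empty fields = missing).

    Missing positions become invalid samples.  Rows must be in strictly
    increasing sample order; duplicate or non-monotone sample indices and
    unparseable rows raise ``ValueError`` with the offending line number.
    """
    path = Path(path)
    samples: list[int] = []
    xs: list[float] = []
    ys: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        cols = [c.strip() for c in header.split(",")]
        if cols[:3] != ["sample", "x_px", "y_px"]:
            raise ValueError(f"{path}: expected header 'sample,x_px,y_px', got {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            try:
                s = int(parts[0])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: unparseable sample index {parts[0]!r}") from None
            sx, sy = parts[1].strip(), parts[2].strip()
            if (sx == "") != (sy == ""):
                raise ValueError(f"{path}:{lineno}: x and y must both be present or both empty")
            if sx == "":
                xv = np.nan
                yv = np.nan
            else:
                try:
                    xv = float(sx)
                    yv = float(sy)
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: unparseable coordinates {line!r}") from None
            if samples and s <= samples[-1]:
                raise ValueError(
                    f"{path}:{lineno}: non-monotone or duplicate sample index {s}"
                )
            samples.append(s)
            xs.append(xv)
            ys.append(yv)
    x = np.array(xs, dtype=float)
    y = np.array(ys, dtype=float)
    valid = ~(np.isnan(x) | np.isnan(y))
    return Trajectory(sample_rate_hz=sample_rate_hz, x=x, y=y, valid=valid)


def write_tracking(traj: Trajectory, path) -> None:
    """Write a trajectory as tracking CSV; invalid samples get empty fields.

    Coordinates are written with ``repr`` precision so a read round-trip is
    bit-exact.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample,x_px,y_px\n")
        for i in range(len(traj)):
            if traj.valid[i]:
                fh.write(f"{i},{float(traj.x[i])!r},{float(traj.y[i])!r}\n")
            else:
                fh.write(f"{i},,\n")


def to_cm(traj: Trajectory, arena: ArenaSpec):
    """Positions of a trajectory in cm: ``x_cm = x_px * width_cm/width_px`` etc."""
    return traj.positions_cm(arena)


def load_pipeline_config(path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return PipelineConfig(**data)


def save_pipeline_config(config: PipelineConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)
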