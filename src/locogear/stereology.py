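"""Design-based stereology arithmetic: optical-fractionator identities,
group reduction percentages and the laterality index of cell depletion.

The laterality index LI = f * (E_LH - E_RH) / (E_LH + E_RH) measures the
left-right asymmetry of combined SNc+VTA cell-population estimates; with the
default scaling f = 1 it is bounded in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "FractionatorParams",
    "StereoEstimate",
    "laterality_index",
    "percent_reduction",
    "fractionator_identities",
    "estimated_population",
    "stereo_estimates",
]

ROIS = ("SNc", "VTA")


@dataclass(frozen=True)
class FractionatorParams:
    """Optical-fractionator sampling geometry (micrometres)."""

    frame_x_um: float = 50.0
    frame_y_um: float = 50.0
    dissector_height_um: float = 20.0
    grid_x_um: float = 150.0
    grid_y_um: float = 150.0
    section_thickness_um: float = 40.0
    n_sections: int = 10
    section_sampling_interval: float = 1.2

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not v > 0:
                raise ValueError(f"FractionatorParams.{name} must be > 0")


@dataclass
class StereoEstimate:
    """Per-animal cell-population estimates with laterality index."""

    animal: str
    group: str
    counts: dict  # (hemisphere, roi) -> estimate
    e_lh: float
    e_rh: float
    li: float
    f: float = 1.0


def laterality_index(e_lh: float, e_rh: float, f: float = 1.0) -> float:
    """f * (E_LH - E_RH) / (E_LH + E_RH); NaN when both hemispheres are zero."""
    if e_lh < 0 or e_rh < 0:
        raise ValueError("hemisphere estimates must be non-negative")
    total = e_lh + e_rh
    if total == 0:
        return float("nan")
    return f * (e_lh - e_rh) / total


def percent_reduction(mean_lesion: float, mean_control: float) -> float:
    """Percent reduction of the lesioned group mean relative to control."""
    if not mean_control > 0:
        raise ValueError("control mean must be > 0")
    return 100.0 * (1.0 - mean_lesion / mean_control)


def fractionator_identities(params: FractionatorParams) -> dict:
    """Derived sampling quantities: dissector volume, grid area, section span."""
    return {
        "dissector_volume_um3": params.frame_x_um * params.frame_y_um * params.dissector_height_um,
        "grid_area_um2": params.grid_x_um * params.grid_y_um,
        "craniocaudal_span_um": params.n_sections * params.section_sampling_interval
        * params.section_thickness_um,
    }


def estimated_population(q_counted: float, ssf: float, asf: float, tsf: float) -> float:
    """Fractionator estimate N = Q / (ssf * asf * tsf) from raw dissector tallies.

    ``ssf``/``asf``/``tsf`` are the section, area and thickness sampling
    fractions (each in (0, 1]).
    """
    for name, v in (("ssf", ssf), ("asf", asf), ("tsf", tsf)):
        if not 0 < v <= 1:
            raise ValueError(f"{name} must be in (0, 1]")
    if q_counted < 0:
        raise ValueError("counted objects must be non-negative")
    return q_counted / (ssf * asf * tsf)


def stereo_estimates(counts: pd.DataFrame, f: float = 1.0) -> list[StereoEstimate]:
    """Combine a long count table into per-animal estimates with LI.

    ``counts`` columns: ``animal, group, hemisphere (LH/RH), roi (SNc/VTA),
    estimate``.  E_LH / E_RH are the SNc+VTA sums per hemisphere.
    """
    required = {"animal", "group", "hemisphere", "roi", "estimate"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    out = []
    for (animal, group), sub in counts.groupby(["animal", "group"], sort=True):
        cmap = {(h, r): float(v) for h, r, v in zip(sub.hemisphere, sub.roi, sub.estimate)}
        e_lh = sum(cmap.get(("LH", r), 0.0) for r in ROIS)
        e_rh = sum(cmap.get(("RH", r), 0.0) for r in ROIS)
        out.append(StereoEstimate(
            animal=str(animal), group=str(group), counts=cmap,
            e_lh=e_lh, e_rh=e_rh, li=laterality_index(e_lh, e_rh, f), f=f,
        ))
    return out
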