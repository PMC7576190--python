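"""Regional morphometric outputs of one angiogram layer.

Seven numbers summarize the microvasculature of a region (a hemifield or
the full crop) of one layer of one eye:

* branch number — count of skeleton branches assigned to the region;
* sum BL / sum EL — total branch and chord lengths (mm);
* mean BL / mean EL — arithmetic per-branch means (µm);
* VT — vessel tortuosity, Σ BL / Σ EL over the region's non-cyclic
  branches (dimensionless, ≥ 1, with 1 meaning perfectly straight);
* VD — vessel density, vessel pixels / total pixels of the region.

A branch belongs to the hemifield containing its path's midpoint pixel, so
branches crossing the boundary are never double counted. Group-level
statistics must average these per-eye values across eyes (mean of per-eye
ratios, never a pooled ratio).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .images import VesselMask
from .regions import OrientationConvention, superior_row_range
from .skeleton import Branch, SkeletonGraph

#: column order of the long-format metrics table
METRIC_COLUMNS = ("branch_number", "sum_bl_mm", "sum_el_mm",
                  "mean_bl_um", "mean_el_um", "vt", "vd")


@dataclass(frozen=True)
class MorphometricRecord:
    eye_id: str
    layer: str
    region: str  # affected | nonaffected | superior | inferior | full
    branch_number: int
    sum_bl_mm: float
    sum_el_mm: float
    mean_bl_um: float | None
    mean_el_um: float | None
    vt: float | None
    vd: float

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("mean_bl_um", "mean_el_um", "vt"):
            if d[k] is None:
                d[k] = math.nan  # explicit missing marker in tables
        return d


def _region_rows(height: int, half: str,
                 orientation: OrientationConvention) -> tuple[int, int]:
    if half == "full":
        return 0, height
    lo, hi = superior_row_range(height, orientation)
    if half == "superior":
        return lo, hi
    if half == "inferior":
        return (hi, height) if lo == 0 else (0, lo)
    raise ValueError(f"unknown half {half!r}")


def vessel_density(mask: VesselMask, half: str = "full",
                   orientation: OrientationConvention = OrientationConvention()) -> float:
    """Fraction of region pixels occupied by binarized vessels."""
    r0, r1 = _region_rows(mask.shape[0], half, orientation)
    region = mask.pixels[r0:r1]
    if region.size == 0:
        raise ValueError("region is empty")
    return float(region.sum()) / float(region.size)


def branches_in_half(graph: SkeletonGraph, half: str,
                     orientation: OrientationConvention = OrientationConvention(),
                     height: int | None = None) -> list[Branch]:
    """Branches whose path midpoint falls inside the hemifield."""
    if half == "full":
        return list(graph.branches)
    if height is None:
        height = 1 + max((p[0] for b in graph.branches for p in b.path), default=0)
    r0, r1 = _region_rows(height, half, orientation)
    return [b for b in graph.branches if r0 <= b.midpoint[0] < r1]


def vessel_tortuosity(branches) -> float:
    """Σ BL / Σ EL over non-cyclic branches (the arc-chord tortuosity)."""
    eligible = [b for b in branches if not b.is_cycle]
    sum_el = sum(b.el_um for b in eligible)
    if sum_el == 0:
        raise ValueError("tortuosity undefined: no chord length in region")
    sum_bl = sum(b.bl_um for b in eligible)
    return sum_bl / sum_el


def summarize_region(mask: VesselMask, graph: SkeletonGraph, *,
                     eye_id: str = "", layer: str | None = None,
                     half: str = "full", region_label: str | None = None,
                     orientation: OrientationConvention = OrientationConvention(),
                     ) -> MorphometricRecord:
    """All seven metrics for one region; undefined values become missing."""
    if graph.scale_um_per_px != mask.scale_um_per_px:
        raise ValueError("mask and graph pixel scales disagree")
    branches = branches_in_half(graph, half, orientation, height=mask.shape[0])
    n = len(branches)
    sum_bl_um = sum(b.bl_um for b in branches)
    sum_el_um = sum(b.el_um for b in branches)
    mean_bl = sum_bl_um / n if n else None
    mean_el = sum_el_um / n if n else None
    try:
        vt = vessel_tortuosity(branches)
    except ValueError:
        vt = None
    return MorphometricRecord(
        eye_id=eye_id,
        layer=layer if layer is not None else mask.layer_tag,
        region=region_label if region_label is not None else half,
        branch_number=n,
        sum_bl_mm=sum_bl_um / 1000.0,
        sum_el_mm=sum_el_um / 1000.0,
        mean_bl_um=mean_bl,
        mean_el_um=mean_el,
        vt=vt,
        vd=vessel_density(mask, half, orientation),
    )


def records_to_frame(records):
    """Long-format per-eye metrics table (one row per eye/layer/region)."""
    import pandas as pd

    rows = [r.to_dict() for r in records]
    cols = ["eye_id", "layer", "region", *METRIC_COLUMNS]
    return pd.DataFrame(rows, columns=cols)
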