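"""Spatial conventions: central macular crop, hemifield split, clinical labels.

The analysis region is the central 3×3 mm square of a 6×6 mm scan. Each crop
is split into a superior and an inferior half; in branch retinal vein
occlusion (BRVO) the half drained by the occluded vein is the "affected"
area and the other half the "nonaffected" area. Fellow (contralateral) eyes
mirror the occluded eye's assignment onto the same hemifield; control and
CRVO eyes keep plain superior/inferior labels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .images import AngioImage, VesselMask

HALVES = ("superior", "inferior", "full")
CLINICAL_LABELS = ("affected", "nonaffected", "none")


@dataclass(frozen=True)
class OrientationConvention:
    """Where the superior retina sits on the pixel grid (uniform per cohort)."""

    superior_at: str = "top"

    def __post_init__(self) -> None:
        if self.superior_at not in ("top", "bottom"):
            raise ValueError("superior_at must be 'top' or 'bottom'")


@dataclass(frozen=True)
class RegionSpec:
    """One analysis region: crop size + hemifield + clinical label."""

    crop_mm: float = 3.0
    half: str = "full"
    clinical_label: str = "none"

    def __post_init__(self) -> None:
        if self.half not in HALVES:
            raise ValueError(f"half must be one of {HALVES}")
        if self.clinical_label not in CLINICAL_LABELS:
            raise ValueError(f"clinical_label must be one of {CLINICAL_LABELS}")


def crop_center(grid: AngioImage | VesselMask, crop_mm: float):
    """Central square crop of ``crop_mm`` side length.

    The side length in pixels is round(crop_mm·1000 / scale). For odd
    remainders the extra row/column is dropped from the bottom/right.
    """
    h, w = grid.shape
    scale = grid.scale_um_per_px
    side_px = int(round(crop_mm * 1000.0 / scale))
    if side_px <= 0:
        raise ValueError("crop size must be positive")
    if side_px > h or side_px > w:
        raise ValueError(
            f"crop of {crop_mm} mm ({side_px} px) exceeds image extent {h}x{w} px")
    r0 = (h - side_px) // 2
    c0 = (w - side_px) // 2
    out = grid.pixels[r0:r0 + side_px, c0:c0 + side_px]
    return grid.with_pixels(out)


def split_halves(grid: AngioImage | VesselMask,
                 orientation: OrientationConvention = OrientationConvention()):
    """Split into (superior, inferior) halves.

    Rows [0, H//2) form the top block and [H//2, H) the bottom block, so an
    odd middle row falls in the bottom block; under ``superior_at='top'`` the
    top block is the superior half, otherwise the bottom block is.
    """
    h = grid.shape[0]
    if h < 2:
        raise ValueError("need at least 2 rows to split")
    top = grid.with_pixels(grid.pixels[: h // 2])
    bottom = grid.with_pixels(grid.pixels[h // 2:])
    if orientation.superior_at == "top":
        return top, bottom
    return bottom, top


def superior_row_range(height: int,
                       orientation: OrientationConvention = OrientationConvention()
                       ) -> tuple[int, int]:
    """Row interval [start, stop) of the superior half on the full grid."""
    if orientation.superior_at == "top":
        return 0, height // 2
    return height // 2, height


def assign_clinical_labels(occluded_half: str, *, is_rvo_hemifield: bool,
                           ) -> dict[str, str]:
    """Map hemifields to clinical labels.

    For BRVO eyes (``is_rvo_hemifield=True``) the occluded half becomes
    "affected" and the other "nonaffected"; fellow eyes reuse the occluded
    eye's mapping on the same hemifield, so callers pass the occluded eye's
    half for fellows too. Control and CRVO eyes keep anatomical labels.
    """
    if not is_rvo_hemifield:
        if occluded_half not in ("none", None):
            raise ValueError("occluded_half must be 'none' for non-hemifield eyes")
        return {"superior": "superior", "inferior": "inferior"}
    if occluded_half not in ("superior", "inferior"):
        raise ValueError("a BRVO eye requires occluded_half 'superior' or 'inferior'")
    other = "inferior" if occluded_half == "superior" else "superior"
    return {occluded_half: "affected", other: "nonaffected"}
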