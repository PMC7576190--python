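"""Raster containers for en-face angiograms and derived binary grids.

An en-face OCTA angiogram is a 2D grayscale map of decorrelation signal
(flow) in one retinal vascular layer — the superficial (SCP) or deep (DCP)
capillary plexus. Every grid carries a physical pixel scale in µm/pixel so
that downstream branch lengths are calibrated; the default convention maps a
6 mm scan onto the image width.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

LAYERS = ("SCP", "DCP")

#: default physical width of a macular OCTA scan, mm
DEFAULT_SCAN_WIDTH_MM = 6.0


def scale_from_scan_width(width_px: int, scan_width_mm: float = DEFAULT_SCAN_WIDTH_MM) -> float:
    """µm per pixel assuming the image spans ``scan_width_mm`` horizontally."""
    if width_px <= 0:
        raise ValueError("image width must be positive")
    return scan_width_mm * 1000.0 / width_px


def _validate_grid(pixels: np.ndarray, scale_um_per_px: float, layer_tag: str) -> None:
    if pixels.ndim != 2 or pixels.size == 0:
        raise ValueError("pixel grid must be a non-empty 2D array")
    if not scale_um_per_px > 0:
        raise ValueError("scale_um_per_px must be positive")
    if layer_tag not in LAYERS:
        raise ValueError(f"layer_tag must be one of {LAYERS}, got {layer_tag!r}")


@dataclass(frozen=True)
class AngioImage:
    """8-bit grayscale en-face angiogram with a physical pixel scale."""

    pixels: np.ndarray
    scale_um_per_px: float
    layer_tag: str = "SCP"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        _validate_grid(px, self.scale_um_per_px, self.layer_tag)
        if px.min() < 0 or px.max() > 255:
            raise ValueError("intensities must lie in the 8-bit range [0, 255]")
        object.__setattr__(self, "pixels", px.astype(np.uint8, copy=False))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "AngioImage":
        return replace(self, pixels=pixels)


@dataclass(frozen=True)
class VesselMask:
    """Binary vessel map (1 = vessel) aligned to its source angiogram."""

    pixels: np.ndarray
    scale_um_per_px: float
    layer_tag: str = "SCP"
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        _validate_grid(px, self.scale_um_per_px, self.layer_tag)
        vals = np.unique(px)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be 0/1")
        object.__setattr__(self, "pixels", px.astype(np.uint8, copy=False))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def vessel_pixel_count(self) -> int:
        return int(self.pixels.sum())

    def with_pixels(self, pixels: np.ndarray) -> "VesselMask":
        return replace(self, pixels=pixels)


def read_angiogram(path: str | Path, scale_um_per_px: float | None = None,
                   layer_tag: str = "SCP",
                   scan_width_mm: float = DEFAULT_SCAN_WIDTH_MM) -> AngioImage:
    """Read an 8-bit grayscale TIFF/PNG angiogram.

    If ``scale_um_per_px`` is omitted it is derived from the scan width and
    the image width in pixels.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        from PIL import Image  # Pillow ships with scikit-image's stack

        arr = np.asarray(Image.open(path).convert("L"))
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse RGB to luma-free mean; inputs should be gray
        arr = arr.mean(axis=2)
    arr = np.clip(arr, 0, 255).astype(np.uint8)
    if scale_um_per_px is None:
        scale_um_per_px = scale_from_scan_width(arr.shape[1], scan_width_mm)
    return AngioImage(arr, scale_um_per_px, layer_tag)


def write_mask(mask: VesselMask, path: str | Path) -> None:
    """Write a mask as 8-bit TIFF (vessel = 255) with a plain-text sidecar."""
    path = Path(path)
    tifffile.imwrite(path, (mask.pixels * 255).astype(np.uint8))
    sidecar = path.with_suffix(path.suffix + ".meta.txt")
    lines = [f"scale_um_per_px={mask.scale_um_per_px!r}", f"layer_tag={mask.layer_tag}"]
    for k in sorted(mask.provenance):
        lines.append(f"{k}={mask.provenance[k]}")
    sidecar.write_text("\n".join(lines) + "\n")


def read_mask(path: str | Path, scale_um_per_px: float | None = None,
              layer_tag: str | None = None) -> VesselMask:
    path = Path(path)
    arr = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".meta.txt")
    meta: dict[str, str] = {}
    if sidecar.exists():
        for line in sidecar.read_text().splitlines():
            if "=" in line:
                k, v = line.split("=", 1)
                meta[k] = v
    if scale_um_per_px is None:
        scale_um_per_px = float(meta.get("scale_um_per_px", scale_from_scan_width(arr.shape[1])))
    if layer_tag is None:
        layer_tag = meta.get("layer_tag", "SCP")
    return VesselMask((np.asarray(arr) > 0).astype(np.uint8), scale_um_per_px, layer_tag,
                      provenance={k: v for k, v in meta.items()
                                  if k not in ("scale_um_per_px", "layer_tag")})
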