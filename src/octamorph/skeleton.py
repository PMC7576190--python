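"""Skeletonization and skeleton-graph branch decomposition.

The vessel mask is thinned to 1-pixel centerlines (Zhang–Suen thinning,
8-connectivity) and the skeleton is decomposed into a graph whose nodes are
endpoints (exactly one 8-neighbor) and junction clusters (8-connected runs
of pixels with three or more neighbors), and whose edges are branches —
ordered pixel paths between two nodes. Each branch carries two calibrated
lengths:

* ``bl_um`` — the actual (along-path) branch length: the sum of pixel steps,
  1 per orthogonal and √2 per diagonal move, times the pixel scale;
* ``el_um`` — the Euclidean chord between the branch's two terminal pixels.

The ratio Σ BL / Σ EL over a region's branches is the vessel tortuosity
(VT); a region of perfectly straight branches has VT = 1.

Conventions (chosen to keep BL ≥ EL provable and bookkeeping exact):

* adjacent junction pixels merge into a single junction node; a branch path
  terminates at (and includes) the first junction-cluster pixel it reaches,
  and EL is measured between the path's own terminal pixels, not cluster
  centroids;
* an isolated closed loop with no junction becomes a single cyclic branch
  whose BL includes the closing step and whose EL is 0; cyclic branches are
  excluded from tortuosity sums (a zero chord would be meaningless) but kept
  in branch counts and BL sums;
* isolated single pixels are segmentation noise: recorded but excluded from
  branch number and all sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

from .images import VesselMask

SQRT2 = float(np.sqrt(2.0))

# fixed 8-neighborhood scan order: row-major
_NEIGH = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class Skeleton:
    """1-pixel-wide centerline grid with physical scale."""

    pixels: np.ndarray
    scale_um_per_px: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("skeleton must be 2D")
        object.__setattr__(self, "pixels", px.astype(np.uint8, copy=False))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class SkeletonNode:
    id: int
    kind: str  # "endpoint" | "junction"
    pixels: tuple[tuple[int, int], ...]

    @property
    def centroid(self) -> tuple[float, float]:
        arr = np.asarray(self.pixels, dtype=float)
        return float(arr[:, 0].mean()), float(arr[:, 1].mean())


@dataclass(frozen=True)
class Branch:
    """One skeleton branch: an ordered 8-connected pixel path between nodes."""

    id: int
    path: tuple[tuple[int, int], ...]
    node_a: int
    node_b: int
    bl_um: float
    el_um: float
    is_cycle: bool = False

    @property
    def n_pixels(self) -> int:
        return len(self.path)

    @property
    def midpoint(self) -> tuple[int, int]:
        return self.path[len(self.path) // 2]


@dataclass(frozen=True)
class SkeletonGraph:
    nodes: tuple[SkeletonNode, ...]
    branches: tuple[Branch, ...]
    scale_um_per_px: float
    n_isolated_pixels: int = 0
    isolated_pixels: tuple[tuple[int, int], ...] = field(default=(), repr=False)

    @property
    def branch_number(self) -> int:
        return len(self.branches)


def _is_simple(on: np.ndarray, r: int, c: int) -> bool:
    """True if removing (r, c) keeps its 8-neighborhood connectivity intact."""
    h, w = on.shape
    ring = []
    for dr, dc in _NEIGH:
        rr, cc = r + dr, c + dc
        if 0 <= rr < h and 0 <= cc < w and on[rr, cc]:
            ring.append((rr, cc))
    if len(ring) < 2:
        return False
    # single 8-connected component among the ON ring pixels themselves
    comp = {ring[0]}
    frontier = [ring[0]]
    rest = set(ring[1:])
    while frontier:
        p = frontier.pop()
        near = {q for q in rest
                if abs(q[0] - p[0]) <= 1 and abs(q[1] - p[1]) <= 1}
        comp |= near
        frontier.extend(near)
        rest -= near
    return not rest


def _enforce_thin(thin: np.ndarray) -> np.ndarray:
    """Remove redundant pixels of 2×2 blocks; thinning can leave a few."""
    out = thin.copy()
    for _ in range(8):  # converges in one or two sweeps
        blocks = find_thick_blocks(out)
        if not blocks:
            break
        for r, c in blocks:
            for rr, cc in ((r, c), (r, c + 1), (r + 1, c), (r + 1, c + 1)):
                if out[rr, cc] and _is_simple(out, rr, cc):
                    out[rr, cc] = False
                    break
    return out


def skeletonize(mask: VesselMask) -> Skeleton:
    """Thin a binary vessel mask to 1-px centerlines.

    Zhang–Suen thinning followed by a deterministic raster-order cleanup of
    any residual 2×2 blocks, so the thinness invariant always holds.
    """
    px = np.asarray(mask.pixels)
    vals = np.unique(px)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("skeletonize expects a binary mask with values 0/1")
    thin = _sk_skeletonize(px.astype(bool), method="zhang")
    thin = _enforce_thin(thin)
    return Skeleton(thin.astype(np.uint8), mask.scale_um_per_px)


def _neighbor_counts(px: np.ndarray) -> np.ndarray:
    k = np.ones((3, 3), dtype=np.uint8)
    k[1, 1] = 0
    return ndimage.convolve(px.astype(np.uint8), k, mode="constant", cval=0)


def find_thick_blocks(px: np.ndarray) -> list[tuple[int, int]]:
    """Top-left corners of 2×2 all-ones blocks (thinness violations)."""
    b = px.astype(bool)
    quad = b[:-1, :-1] & b[:-1, 1:] & b[1:, :-1] & b[1:, 1:]
    return [tuple(map(int, rc)) for rc in np.argwhere(quad)]


def step_length(p: tuple[int, int], q: tuple[int, int]) -> float:
    """Length of one chain step: 1 orthogonal, √2 diagonal."""
    dr, dc = abs(p[0] - q[0]), abs(p[1] - q[1])
    if dr > 1 or dc > 1 or (dr == 0 and dc == 0):
        raise ValueError(f"pixels {p} and {q} are not distinct 8-neighbors")
    return SQRT2 if (dr == 1 and dc == 1) else 1.0


def branch_length(path, scale_um_per_px: float, *, closed: bool = False) -> float:
    """Along-path length in µm; a single-pixel path has length 0."""
    path = list(path)
    if len(path) < 1:
        raise ValueError("path must contain at least one pixel")
    total = 0.0
    for p, q in zip(path[:-1], path[1:]):
        total += step_length(p, q)
    if closed and len(path) > 2:
        total += step_length(path[-1], path[0])
    return total * scale_um_per_px


def euclidean_length(path, scale_um_per_px: float, *, closed: bool = False) -> float:
    """Chord between first and last path pixel in µm; 0 for closed loops."""
    path = list(path)
    if len(path) < 1:
        raise ValueError("path must contain at least one pixel")
    if closed:
        return 0.0
    (r0, c0), (r1, c1) = path[0], path[-1]
    return float(np.hypot(r1 - r0, c1 - c0)) * scale_um_per_px


def build_graph(skel: Skeleton) -> SkeletonGraph:
    """Decompose a thin skeleton into nodes and branches.

    Pixels are classified by 8-neighbor count (1 → endpoint, 2 → slab,
    ≥3 → junction), adjacent junction pixels merge into junction nodes, and
    maximal slab runs between node pixels are traced as branches. Raises on
    non-thin input, naming the violating 2×2 block.
    """
    px = np.asarray(skel.pixels)
    if not np.isin(np.unique(px), (0, 1)).all():
        raise ValueError("skeleton grid must be binary")
    counts = _neighbor_counts(px)
    # X-crossings leave an irreducible 2x2 core (no pixel is removable
    # without detaching an arm); such cores merge into one junction cluster
    # below. A 2x2 block with any removable pixel means the input is
    # genuinely thicker than 1 px.
    on_bool = px.astype(bool)
    for r, c in find_thick_blocks(px):
        if any(_is_simple(on_bool, rr, cc)
               for rr, cc in ((r, c), (r, c + 1), (r + 1, c), (r + 1, c + 1))):
            raise ValueError(
                f"skeleton is not 1-px thin: 2x2 block at ({r}, {c})")
    on = px.astype(bool)
    h, w = px.shape

    def neighbors(p):
        r, c = p
        out = []
        for dr, dc in _NEIGH:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and on[rr, cc]:
                out.append((rr, cc))
        return out

    junction_mask = on & (counts >= 3)
    endpoint_mask = on & (counts == 1)
    slab_mask = on & (counts == 2)
    isolated = [tuple(map(int, rc)) for rc in np.argwhere(on & (counts == 0))]

    # junction clusters → one node each
    lab, n_j = ndimage.label(junction_mask, structure=_STRUCT8)
    nodes: list[SkeletonNode] = []
    node_of: dict[tuple[int, int], int] = {}
    for j in range(1, n_j + 1):
        pix = tuple(tuple(map(int, rc)) for rc in np.argwhere(lab == j))
        nid = len(nodes)
        nodes.append(SkeletonNode(nid, "junction", pix))
        for p in pix:
            node_of[p] = nid
    for rc in np.argwhere(endpoint_mask):
        p = tuple(map(int, rc))
        nid = len(nodes)
        nodes.append(SkeletonNode(nid, "endpoint", (p,)))
        node_of[p] = nid

    scale = skel.scale_um_per_px
    branches: list[Branch] = []
    visited_slab: set[tuple[int, int]] = set()
    seen_direct: set[frozenset] = set()

    def emit(path, closed=False):
        a = node_of.get(path[0], -1)
        b = node_of.get(path[-1], -1)
        branches.append(Branch(
            id=len(branches), path=tuple(path), node_a=a, node_b=b,
            bl_um=branch_length(path, scale, closed=closed),
            el_um=euclidean_length(path, scale, closed=closed),
            is_cycle=closed,
        ))

    node_pixels = sorted(node_of)  # raster order for determinism
    for p in node_pixels:
        for q in neighbors(p):
            if slab_mask[q]:
                if q in visited_slab:
                    continue
                path = [p, q]
                visited_slab.add(q)
                prev, cur = p, q
                while True:
                    nxt = [n for n in neighbors(cur) if n != prev]
                    # slab pixel: exactly 2 neighbors, so exactly one way on
                    nxt = nxt[0]
                    if slab_mask[nxt]:
                        if nxt in visited_slab:  # defensive; cannot recur
                            break
                        visited_slab.add(nxt)
                        path.append(nxt)
                        prev, cur = cur, nxt
                    else:
                        path.append(nxt)
                        break
                emit(path)
            elif q in node_of:
                # direct node-node adjacency; same-cluster contacts are not branches
                if node_of[q] == node_of[p] and junction_mask[p] and junction_mask[q]:
                    continue
                key = frozenset((p, q))
                if key in seen_direct:
                    continue
                seen_direct.add(key)
                emit([p, q])

    # leftover slab pixels form isolated closed loops
    remaining = [tuple(map(int, rc)) for rc in np.argwhere(slab_mask)]
    for start in remaining:
        if start in visited_slab:
            continue
        path = [start]
        visited_slab.add(start)
        prev, cur = None, start
        while True:
            nbrs = [n for n in neighbors(cur) if n != prev]
            nxt = min(nbrs)  # deterministic direction on the first step
            if nxt == start:
                break
            visited_slab.add(nxt)
            path.append(nxt)
            prev, cur = cur, nxt
        emit(path, closed=True)

    return SkeletonGraph(tuple(nodes), tuple(branches), scale,
                         n_isolated_pixels=len(isolated),
                         isolated_pixels=tuple(isolated))


def graph_to_tables(graph: SkeletonGraph):
    """Export (nodes, branches) as pandas DataFrames matching the CSV schema."""
    import pandas as pd

    nrows = [{"id": n.id, "kind": n.kind,
              "y": n.centroid[0], "x": n.centroid[1]} for n in graph.nodes]
    brows = [{"id": b.id, "node_a": b.node_a, "node_b": b.node_b,
              "n_pixels": b.n_pixels, "bl_um": b.bl_um, "el_um": b.el_um,
              "is_cycle": b.is_cycle,
              "mid_y": b.midpoint[0], "mid_x": b.midpoint[1]} for b in graph.branches]
    return (pd.DataFrame(nrows, columns=["id", "kind", "y", "x"]),
            pd.DataFrame(brows, columns=["id", "node_a", "node_b", "n_pixels",
                                         "bl_um", "el_um", "is_cycle",
                                         "mid_y", "mid_x"]))
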