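"""Independent brute-force skeleton-branch tracer used as a test oracle.

Decomposes a thin skeleton into branches by exhaustive component analysis
on the pixel adjacency graph (networkx), independently of the package's
tracer: node pixels (degree != 2) are deleted, every surviving connected
component is a slab run whose unique attachment pixels are re-appended, and
lengths are summed with numpy hypot over coordinate deltas.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

NEIGH = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]


def pixel_graph(px: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    coords = list(map(tuple, np.argwhere(np.asarray(px) > 0)))
    g.add_nodes_from(coords)
    s = set(coords)
    for (r, c) in coords:
        for dr, dc in NEIGH:
            q = (r + dr, c + dc)
            if q in s:
                g.add_edge((r, c), q)
    return g


def path_length(path, scale: float, closed: bool = False) -> float:
    pts = list(path) + ([path[0]] if closed and len(path) > 2 else [])
    d = np.diff(np.asarray(pts, float), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum()) * scale


def trace_branches(px: np.ndarray, scale: float = 1.0):
    """Return a list of dicts {bl, el, n_pixels, cycle} for every branch."""
    g = pixel_graph(px)
    node_px = {p for p in g if g.degree(p) != 2 and g.degree(p) != 0}
    # junction clusters: connected sets of pixels with degree >= 3
    junctions = {p for p in node_px if g.degree(p) >= 3}
    cluster_of = {}
    for i, comp in enumerate(nx.connected_components(g.subgraph(junctions))):
        for p in comp:
            cluster_of[p] = i

    branches = []
    slab = g.copy()
    slab.remove_nodes_from(node_px)
    slab.remove_nodes_from([p for p in g if g.degree(p) == 0])
    for comp in nx.connected_components(slab):
        sub = slab.subgraph(comp)
        ends = [p for p in sub if sub.degree(p) < 2]
        if not ends:  # isolated closed loop
            cycle = list(nx.find_cycle(sub))
            path = [e[0] for e in cycle]
            branches.append({"bl": path_length(path, scale, closed=True),
                             "el": 0.0, "n_pixels": len(path), "cycle": True})
            continue
        if len(comp) == 1:
            order = list(comp)
        else:
            order = nx.shortest_path(sub, ends[0], ends[1])
        # unique node-pixel attachments at each end
        # terminal node pixels: a slab has exactly two neighbors, so each run
        # end attaches to at most one node pixel (a single-pixel run to two);
        # front and back attachment may be the same pixel (a self-loop)
        att_f = sorted(q for q in g.neighbors(order[0]) if q in node_px)
        att_b = sorted(q for q in g.neighbors(order[-1]) if q in node_px)
        if len(order) == 1 and len(att_f) == 2:
            front, back = att_f
        else:
            front = att_f[0] if att_f else None
            back = att_b[0] if att_b else None
        if front is not None:
            order = [front] + order
        if back is not None:
            order = order + [back]
        branches.append({"bl": path_length(order, scale), "el":
                         float(np.hypot(order[-1][0] - order[0][0],
                                        order[-1][1] - order[0][1])) * scale,
                         "n_pixels": len(order), "cycle": False})
    # direct node-node adjacencies (branches without slab pixels)
    seen = set()
    for p in node_px:
        for q in g.neighbors(p):
            if q in node_px and frozenset((p, q)) not in seen:
                seen.add(frozenset((p, q)))
                if p in cluster_of and q in cluster_of \
                        and cluster_of[p] == cluster_of[q]:
                    continue  # same junction cluster, not a branch
                branches.append({"bl": path_length([p, q], scale),
                                 "el": path_length([p, q], scale),
                                 "n_pixels": 2, "cycle": False})
    return branches


def all_masks(shape, max_pixels):
    """Every binary grid of the given shape with 1..max_pixels ON pixels."""
    h, w = shape
    cells = [(r, c) for r in range(h) for c in range(w)]
    for n in range(1, max_pixels + 1):
        for combo in itertools.combinations(cells, n):
            grid = np.zeros(shape, dtype=np.uint8)
            for r, c in combo:
                grid[r, c] = 1
            yield grid
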