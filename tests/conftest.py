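import numpy as np
import pytest

import octamorph as om


def grid_skeleton(rows, scale=1.0):
    """Skeleton from an ASCII art grid ('#' = pixel)."""
    arr = np.array([[1 if ch == "#" else 0 for ch in row] for row in rows],
                   dtype=np.uint8)
    return om.Skeleton(arr, scale)


@pytest.fixture(scope="session")
def dcp_plexus():
    """One default DCP-style plexus shared across tests (seed 11)."""
    image, mask, truth = om.generate_plexus(om.dcp_params(), seed=11)
    return image, mask, truth


@pytest.fixture(scope="session")
def dcp_measured(dcp_plexus):
    """Skeleton graph + full-region record measured from the shared plexus."""
    _, mask, _ = dcp_plexus
    graph = om.build_graph(om.skeletonize(mask))
    record = om.summarize_region(mask, graph, eye_id="fixture", half="full")
    return graph, record


def random_thin_skeleton(rng, shape=(64, 64), n_blobs=6, scale=1.0):
    """Random thin skeleton: skeletonized union of random blobs and bars."""
    mask = np.zeros(shape, dtype=np.uint8)
    h, w = shape
    for _ in range(n_blobs):
        r, c = rng.integers(4, h - 4), rng.integers(4, w - 4)
        rr, cc = rng.integers(2, 10), rng.integers(2, 10)
        mask[max(0, r - rr):r + rr, max(0, c - cc):c + cc] = 1
    vm = om.VesselMask(mask, scale)
    return om.skeletonize(vm)
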