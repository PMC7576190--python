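"""Skeletonization and skeleton-graph branch decomposition."""

import numpy as np
import pytest

import octamorph as om
from octamorph.skeleton import find_thick_blocks, step_length

from conftest import grid_skeleton, random_thin_skeleton
import oracle


def make_mask(arr, scale=1.0):
    return om.VesselMask(np.asarray(arr, dtype=np.uint8), scale)


class TestSkeletonize:
    def test_wide_bar_thins_to_line(self):
        mask = np.zeros((11, 30), dtype=np.uint8)
        mask[3:8, 2:28] = 1  # 5-px-wide horizontal bar
        skel = om.skeletonize(make_mask(mask))
        assert find_thick_blocks(skel.pixels) == []
        g = om.build_graph(skel)
        assert g.branch_number == 1
        (b,) = g.branches
        # still a horizontal line of the same length class
        assert b.el_um == pytest.approx(b.bl_um, rel=0.05)
        assert b.bl_um >= 0.7 * 26

    def test_idempotent_on_thin_line(self):
        line = np.zeros((5, 12), dtype=np.uint8)
        line[2, 1:11] = 1
        skel = om.skeletonize(make_mask(line))
        assert np.array_equal(skel.pixels, line)
        again = om.skeletonize(make_mask(skel.pixels))
        assert np.array_equal(again.pixels, skel.pixels)

    def test_empty_mask_gives_empty_skeleton(self):
        skel = om.skeletonize(make_mask(np.zeros((8, 8))))
        assert skel.pixels.sum() == 0

    def test_graph_rejects_non_binary_grid(self):
        with pytest.raises(ValueError, match="binary"):
            om.build_graph(om.Skeleton(np.array([[2, 0]], dtype=np.uint8), 1.0))

    def test_output_subset_of_mask(self, dcp_plexus):
        _, mask, _ = dcp_plexus
        skel = om.skeletonize(mask)
        assert not np.any(skel.pixels & ~mask.pixels)


class TestBuildGraph:
    def test_plus_sign(self):
        rows = ["....#....",
                "....#....",
                "....#....",
                "....#....",
                "#########",
                "....#....",
                "....#....",
                "....#....",
                "....#...."]
        g = om.build_graph(grid_skeleton(rows))
        kinds = [n.kind for n in g.nodes]
        assert kinds.count("junction") == 1
        assert kinds.count("endpoint") == 4
        assert g.branch_number == 4
        # under 8-connectivity the four pixels next to the crossing are
        # junction pixels too (diagonal contacts), so the cluster has 5
        # pixels and each arm runs 3 unit steps from cluster to endpoint
        (junction,) = [n for n in g.nodes if n.kind == "junction"]
        assert len(junction.pixels) == 5
        for b in g.branches:
            assert b.bl_um == pytest.approx(3.0)
            assert b.el_um == pytest.approx(3.0)

    def test_straight_line(self):
        g = om.build_graph(grid_skeleton(["##########"]))
        assert [n.kind for n in g.nodes].count("endpoint") == 2
        assert [n.kind for n in g.nodes].count("junction") == 0
        assert g.branch_number == 1
        assert g.branches[0].bl_um == pytest.approx(9.0)

    def test_diamond_ring_is_single_cycle(self):
        rows = [".#.",
                "#.#",
                ".#."]
        g = om.build_graph(grid_skeleton(rows))
        assert len(g.nodes) == 0
        assert g.branch_number == 1
        (b,) = g.branches
        assert b.is_cycle
        assert b.bl_um == pytest.approx(4 * np.sqrt(2))
        assert b.el_um == 0.0

    def test_rejects_thick_input(self):
        thick = grid_skeleton(["##.",
                               "##.",
                               ".#."])
        with pytest.raises(ValueError, match="2x2"):
            om.build_graph(thick)

    def test_isolated_pixels_excluded_from_branches(self):
        rows = ["#....",
                ".....",
                "..###"]
        g = om.build_graph(grid_skeleton(rows))
        assert g.branch_number == 1
        assert g.n_isolated_pixels == 1


class TestLengths:
    def test_horizontal_path_scaled(self):
        path = [(0, c) for c in range(10)]
        assert om.branch_length(path, 10.0) == pytest.approx(90.0)
        assert om.euclidean_length(path, 10.0) == pytest.approx(90.0)

    def test_diagonal_path(self):
        path = [(i, i) for i in range(4)]
        assert om.branch_length(path, 10.0) == pytest.approx(3 * np.sqrt(2) * 10)

    def test_l_path_against_coordinate_oracle(self):
        scale = 11.72
        path = [(0, c) for c in range(5)] + [(r, 4) for r in range(1, 5)]
        expect_bl = oracle.path_length(path, scale)
        assert om.branch_length(path, scale) == pytest.approx(expect_bl)
        assert om.euclidean_length(path, scale) == pytest.approx(
            np.hypot(4, 4) * scale)

    def test_chord_ignores_arc_shape(self):
        # a wandering arc from (0,0) to (0,20): EL is the chord only
        path = [(0, 0), (1, 1), (2, 2), (1, 3), (0, 4)] + \
               [(0, c) for c in range(5, 21)]
        assert om.euclidean_length(path, 1.0) == pytest.approx(20.0)

    def test_single_pixel_path_has_zero_length(self):
        assert om.branch_length([(3, 3)], 5.0) == 0.0

    def test_non_adjacent_pixels_rejected(self):
        with pytest.raises(ValueError, match="neighbors"):
            om.branch_length([(0, 0), (0, 2)], 1.0)
        with pytest.raises(ValueError, match="neighbors"):
            step_length((1, 1), (1, 1))


class TestGraphInvariants:
    @pytest.mark.parametrize("seed", range(6))
    def test_bl_ge_el_and_conservation(self, seed):
        rng = np.random.default_rng(seed)
        skel = random_thin_skeleton(rng)
        g = om.build_graph(skel)
        pix = set()
        for b in g.branches:
            assert b.bl_um >= b.el_um - 1e-9
            pix.update(b.path)
        for n in g.nodes:
            pix.update(n.pixels)
        pix.update(g.isolated_pixels)
        total = {tuple(rc) for rc in np.argwhere(skel.pixels > 0)}
        assert pix == total

    @pytest.mark.parametrize("seed", range(4))
    def test_each_slab_pixel_in_exactly_one_branch(self, seed):
        rng = np.random.default_rng(100 + seed)
        skel = random_thin_skeleton(rng)
        g = om.build_graph(skel)
        junction_pixels = {p for n in g.nodes if n.kind == "junction"
                           for p in n.pixels}
        seen = {}
        for b in g.branches:
            for p in b.path:
                if p in junction_pixels:
                    continue  # terminals shared with a junction cluster
                seen[p] = seen.get(p, 0) + (0 if (p == b.path[0] or p == b.path[-1]) else 1)
        assert all(v <= 1 for v in seen.values())

    def test_skeletonize_idempotent_on_random_masks(self):
        rng = np.random.default_rng(7)
        skel = random_thin_skeleton(rng)
        again = om.skeletonize(om.VesselMask(skel.pixels, 1.0))
        assert np.array_equal(again.pixels, skel.pixels)


def _compare_with_oracle(px, scale=1.0):
    g = om.build_graph(om.Skeleton(np.asarray(px, np.uint8), scale))
    mine = sorted((round(b.bl_um, 6), round(b.el_um, 6)) for b in g.branches)
    ref = sorted((round(b["bl"], 6), round(b["el"], 6))
                 for b in oracle.trace_branches(px, scale))
    assert mine == ref, f"branch decomposition mismatch\n{px}"


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_random_thin_skeletons_match_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        skel = random_thin_skeleton(rng, shape=(48, 48))
        _compare_with_oracle(skel.pixels)

    def test_small_sparse_masks_match_oracle(self):
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 300:
            n = int(rng.integers(1, 13))
            grid = np.zeros((8, 8), dtype=np.uint8)
            idx = rng.choice(64, size=n, replace=False)
            grid[np.unravel_index(idx, (8, 8))] = 1
            try:
                om.build_graph(om.Skeleton(grid, 1.0))
            except ValueError:
                continue  # not thin; outside the contract
            _compare_with_oracle(grid)
            checked += 1
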