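"""Skeletonization, graph tracing, and the cleanup rules (10/50/250 μm)."""

import numpy as np
import pytest

from vasculomap.graph import VesselGraph
from vasculomap.synthetic import (
    axial_tube_graph,
    gap_fixture,
    rasterize_tubes,
    spur_fixture,
)
from vasculomap.trace import (
    build_graph,
    measure_radii,
    prune_spurs,
    qc_connectivity_filter,
    reconnect_endpoints,
    skeletonize,
    trace_vessels,
)
from vasculomap.volume import VoxelVolume


def mask_of(graph, shape, spacing=(1.0, 1.0, 1.0)):
    return VoxelVolume(rasterize_tubes(graph, shape, spacing), spacing)


class TestSkeletonize:
    def test_empty_mask_empty_skeleton(self):
        skel = skeletonize(VoxelVolume(np.zeros((10, 10, 10), bool), (1, 1, 1)))
        assert skel.n_voxels == 0

    def test_anisotropic_mask_rejected(self):
        with pytest.raises(ValueError, match="anisotropic"):
            skeletonize(VoxelVolume(np.ones((5, 5, 5), bool), (1, 1, 5)))

    def test_straight_tube_centreline_on_axis(self):
        g = axial_tube_graph(4.0, cube=60.0)
        skel = skeletonize(mask_of(g, (60, 60, 60)))
        pts = skel.positions_um()
        off_axis = np.linalg.norm(pts[:, 1:] - 30.0, axis=1)
        assert off_axis.max() <= np.sqrt(2.0)  # within one voxel of the axis

    def test_torus_preserves_single_cycle(self):
        """Skeleton of a torus mask traces exactly one loop."""
        n = 60
        ii, jj, kk = np.mgrid[0:n, 0:n, 0:7].astype(float)
        rho = np.hypot(ii - 30, jj - 30)
        torus = (np.hypot(rho - 18, kk - 3) <= 3.0)
        skel = skeletonize(VoxelVolume(torus, (1, 1, 1)))
        graph = build_graph(measure_radii(VoxelVolume(torus, (1, 1, 1)), skel))
        cycles = graph.n_segments - graph.n_nodes + graph.n_components()
        assert cycles == 1

    def test_component_count_preserved(self):
        g = VesselGraph()
        for x in (10.0, 40.0):
            a = g.add_node((x, 10, 30))
            b = g.add_node((x, 50, 30))
            g.add_segment(a, b, np.array([[x, 10, 30], [x, 50, 30]]), np.full(2, 3.0))
        mask = mask_of(g, (60, 60, 60))
        skel = skeletonize(mask)
        graph = build_graph(measure_radii(mask, skel))
        assert graph.n_components() == 2


class TestRadii:
    def test_tube_radius_within_one_voxel(self):
        g = axial_tube_graph(4.0, cube=60.0)
        mask = mask_of(g, (60, 60, 60))
        skel = measure_radii(mask, skeletonize(mask))
        interior = np.abs(skel.positions_um()[:, 0] - 30.0) < 20.0
        assert np.all(np.abs(skel.radii_um[interior] - 4.0) <= 1.0)

    def test_isolated_voxel_radius_bounded_by_voxel(self):
        data = np.zeros((9, 9, 9), bool)
        data[4, 4, 4] = True
        vol = VoxelVolume(data, (1, 1, 1))
        skel = measure_radii(vol, skeletonize(vol))
        assert skel.radii_um.max() <= np.sqrt(3.0)

    def test_tapering_cone_monotone_radii(self):
        g = VesselGraph()
        p0, p1 = np.array([10.0, 30, 30]), np.array([90.0, 30, 30])
        a, b = g.add_node(p0), g.add_node(p1)
        t = np.linspace(0, 1, 41)
        poly = p0 + t[:, None] * (p1 - p0)
        g.add_segment(a, b, poly, 8.0 - 5.0 * t)
        mask = mask_of(g, (100, 60, 60))
        skel = measure_radii(mask, skeletonize(mask))
        order = np.argsort(skel.positions_um()[:, 0])
        r = skel.radii_um[order]
        x = skel.positions_um()[order, 0]
        interior = (x > 20) & (x < 80)
        diffs = np.diff(r[interior])
        assert np.all(diffs <= 1.5), "radii should taper monotonically"

    def test_skeleton_outside_mask_rejected(self):
        data = np.zeros((9, 9, 9), bool)
        data[4, 4, 4] = True
        vol = VoxelVolume(data, (1, 1, 1))
        skel = skeletonize(vol)
        with pytest.raises(ValueError):
            measure_radii(vol.like(np.zeros((9, 9, 9), bool)), skel)


class TestBuildGraph:
    def test_x_shape_one_branch_four_endpoints(self):
        g = VesselGraph()
        c = np.array([50.0, 50, 30])
        for d in ([1, 1, 0], [-1, 1, 0], [1, -1, 0], [-1, -1, 0]):
            tip = c + 40.0 * np.array(d) / np.sqrt(2)
            a = g.add_node(c)
            b = g.add_node(tip)
            g.add_segment(a, b, np.vstack([c, tip]), np.full(2, 3.0))
        mask = mask_of(g, (100, 100, 60))
        graph = build_graph(measure_radii(mask, skeletonize(mask)))
        assert len(graph.branch_nodes()) == 1
        assert len(graph.endpoint_nodes()) == 4
        assert graph.n_segments == 4

    def test_close_branch_nodes_merged(self):
        """An inter-node segment of 6 μm (< 10 μm rule) contracts: its two
        branch nodes merge and the segment count drops by one.

        Built directly as a skeleton: an H shape whose crossbar is 6
        voxels at 1 μm spacing.
        """
        from vasculomap.trace import Skeleton

        vox = []
        for y in range(41):
            vox.append((20, y, 5))
            vox.append((26, y, 5))
        for x in range(21, 26):
            vox.append((x, 20, 5))
        indices = np.array(sorted(set(vox)))
        skel = Skeleton(indices, (1.0, 1.0, 1.0), (50, 50, 11),
                        radii_um=np.full(len(indices), 1.0))
        graph = build_graph(skel)
        assert len(graph.branch_nodes()) == 1
        assert self._degree_of_branch(graph) == 4

    @staticmethod
    def _degree_of_branch(graph):
        (node,) = graph.branch_nodes()
        return graph.g.degree(node)

    def test_total_length_matches_skeleton_path_length(self):
        g = axial_tube_graph(3.0, cube=100.0)
        mask = mask_of(g, (100, 100, 100))
        skel = measure_radii(mask, skeletonize(mask))
        graph = build_graph(skel, smooth_window=1)
        # skeleton path length: sum of voxel-step distances along the chain
        pts = skel.positions_um()
        order = np.argsort(pts[:, 0])
        steps = np.linalg.norm(np.diff(pts[order], axis=0), axis=1)
        assert graph.total_length() == pytest.approx(steps.sum(), rel=0.01)

    def test_empty_skeleton_empty_graph(self):
        vol = VoxelVolume(np.zeros((8, 8, 8), bool), (1, 1, 1))
        graph = build_graph(skeletonize(vol))
        assert graph.n_nodes == 0 and graph.n_segments == 0


class TestReconnect:
    def test_gap_8um_joined(self):
        g = gap_fixture(8.0)
        assert g.n_components() == 2
        reconnect_endpoints(g, max_gap=10.0)
        assert g.n_components() == 1

    def test_gap_12um_untouched(self):
        g = gap_fixture(12.0)
        reconnect_endpoints(g, max_gap=10.0)
        assert g.n_components() == 2

    def test_three_endpoints_only_nearest_pair_joined(self):
        """Brute force over pairings confirms the greedy nearest pair."""
        g = VesselGraph()
        origins = [(0.0, 0.0, 0.0), (7.0, 0.0, 0.0), (3.0, 6.0, 0.0)]
        tips = [(-100.0, 0, 0), (107.0, 0, 0), (3.0, 106.0, 0)]
        ends = []
        for o, t in zip(origins, tips):
            a = g.add_node(o)
            b = g.add_node(t)
            g.add_segment(a, b, np.vstack([o, t]), np.full(2, 2.0))
            ends.append(a)
        dists = {
            (i, j): np.linalg.norm(np.array(origins[i]) - np.array(origins[j]))
            for i in range(3) for j in range(i + 1, 3)
        }
        best_pair = min(dists, key=dists.get)
        n_before = g.n_segments
        reconnect_endpoints(g, max_gap=10.0)
        assert g.n_segments == n_before + 1
        u, v = ends[best_pair[0]], ends[best_pair[1]]
        assert g.g.has_edge(u, v)

    def test_never_increases_component_count(self):
        g = gap_fixture(8.0)
        before = g.n_components()
        reconnect_endpoints(g)
        assert g.n_components() <= before

    def test_same_segment_ends_never_joined(self):
        g = VesselGraph()
        a = g.add_node((0.0, 0, 0))
        b = g.add_node((6.0, 0, 0))
        g.add_segment(a, b, np.array([[0.0, 0, 0], [6.0, 0, 0]]), np.full(2, 2.0))
        reconnect_endpoints(g, max_gap=10.0)
        assert g.n_segments == 1


class TestPrune:
    def test_spur_thresholds_bit_exact(self):
        g = spur_fixture(spur_lengths=(30.0, 49.0, 51.0))
        prune_spurs(g, min_len=50.0)
        g.collapse_degree2_nodes()
        terminal = [
            d["length"] for u, v, _k, d in g.segments()
            if g.g.degree(u) == 1 or g.g.degree(v) == 1
        ]
        # 51 μm spur survives; backbone ends survive; 30 and 49 are gone
        assert 51.0 in terminal
        assert 30.0 not in terminal and 49.0 not in terminal
        assert len(g.branch_nodes()) == 1

    def test_isolated_short_segment_removed_by_default(self):
        g = VesselGraph()
        a = g.add_node((0.0, 0, 0))
        b = g.add_node((40.0, 0, 0))
        g.add_segment(a, b, np.array([[0.0, 0, 0], [40.0, 0, 0]]), np.full(2, 2.0))
        prune_spurs(g, min_len=50.0)
        assert g.n_segments == 0
        g2 = VesselGraph()
        a = g2.add_node((0.0, 0, 0))
        b = g2.add_node((40.0, 0, 0))
        g2.add_segment(a, b, np.array([[0.0, 0, 0], [40.0, 0, 0]]), np.full(2, 2.0))
        prune_spurs(g2, min_len=50.0, keep_isolated=True)
        assert g2.n_segments == 1

    def test_fixed_point_no_short_terminal_left(self):
        """Chains of spurs resolve until no terminal segment < 50 μm."""
        g = VesselGraph()
        xs = [0.0, 100.0, 130.0, 160.0]
        nodes = [g.add_node((x, 50.0, 0)) for x in xs]
        for u, v in zip(nodes[:-1], nodes[1:]):
            g.add_segment(u, v, np.vstack([g.node_pos(u), g.node_pos(v)]),
                          np.full(2, 2.0))
        for anchor_x in (100.0, 130.0):
            anchor = nodes[xs.index(anchor_x)]
            tip = g.add_node((anchor_x, 95.0, 0))
            g.add_segment(anchor, tip,
                          np.vstack([g.node_pos(anchor), g.node_pos(tip)]),
                          np.full(2, 2.0))
        prune_spurs(g, min_len=50.0)
        g.collapse_degree2_nodes()
        for u, v, _k, d in g.segments():
            if g.g.degree(u) == 1 or g.g.degree(v) == 1:
                assert d["length"] >= 50.0

    def test_idempotent(self):
        g = spur_fixture()
        prune_spurs(g, min_len=50.0)
        before = sorted(d["length"] for *_x, d in g.segments())
        prune_spurs(g, min_len=50.0)
        after = sorted(d["length"] for *_x, d in g.segments())
        assert before == after

    def test_cycles_never_removed(self):
        g = VesselGraph()
        a = g.add_node((0.0, 0, 0))
        square = np.array([[0.0, 0, 0], [10.0, 0, 0], [10.0, 10, 0],
                           [0.0, 10, 0], [0.0, 0, 0]])
        g.add_segment(a, a, square, np.full(5, 2.0))
        prune_spurs(g, min_len=50.0)
        assert g.n_segments == 1


class TestQC:
    def test_single_long_segment_passes(self):
        g = VesselGraph()
        a = g.add_node((0.0, 0, 0))
        b = g.add_node((1000.0, 0, 0))
        g.add_segment(a, b, np.array([[0.0, 0, 0], [1000.0, 0, 0]]), np.full(2, 3.0))
        res = qc_connectivity_filter(g, min_ratio=250.0)
        assert res.passed and res.ratio_um_per_node == pytest.approx(500.0)

    def test_fragmented_graph_fails(self):
        g = VesselGraph()
        for i in range(20):
            a = g.add_node((i * 30.0, 0, 0))
            b = g.add_node((i * 30.0 + 20.0, 0, 0))
            g.add_segment(a, b, np.vstack([g.node_pos(a), g.node_pos(b)]),
                          np.full(2, 2.0))
        res = qc_connectivity_filter(g, min_ratio=250.0)
        assert not res.passed and res.ratio_um_per_node == pytest.approx(10.0)

    def test_empty_graph_reports_undefined_ratio(self):
        res = qc_connectivity_filter(VesselGraph())
        assert not res.passed and np.isnan(res.ratio_um_per_node)

    def test_ratio_matches_brute_force_recount(self):
        rng = np.random.default_rng(6)
        g = VesselGraph()
        for _ in range(8):
            p = rng.uniform(0, 500, 3)
            q = p + rng.uniform(-80, 80, 3)
            a, b = g.add_node(p), g.add_node(q)
            g.add_segment(a, b, np.vstack([p, q]), np.full(2, 2.0))
        res = qc_connectivity_filter(g)
        total = sum(
            np.linalg.norm(d["polyline"][-1] - d["polyline"][0])
            for *_x, d in g.segments()
        )
        assert res.ratio_um_per_node == pytest.approx(total / g.n_nodes)


class TestRecovery:
    def test_noise_free_network_recovery(self, recovery_results):
        """Well-separated synthetic networks: exact branch count, length
        within 5%, length-weighted mean radius within 15%."""
        for truth, traced in recovery_results:
            assert len(traced.branch_nodes()) == len(truth.graph.branch_nodes())
            tl, rl = truth.graph.total_length(), traced.total_length()
            assert abs(rl - tl) / tl < 0.05
            def wrad(g):
                return sum(
                    d["length"] * d["mean_radius"] for *_x, d in g.segments()
                ) / g.total_length()
            assert abs(wrad(traced) - wrad(truth.graph)) / wrad(truth.graph) < 0.15
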