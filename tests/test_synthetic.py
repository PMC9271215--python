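"""Ground-truth generators: determinism, geometry, and sampling laws."""

import numpy as np
import pytest

from vasculomap.synthetic import (
    SyntheticSpec,
    axial_tube_graph,
    gap_fixture,
    generate_cell_field,
    generate_cortex_phantom,
    generate_vascular_graph,
    lattice_graph,
    make_fixture_suite,
    rasterize_graph,
    rasterize_tubes,
    spur_fixture,
)
from vasculomap.volume import VoxelVolume


def graphs_equal(a, b) -> bool:
    if a.n_nodes != b.n_nodes or a.n_segments != b.n_segments:
        return False
    sa = sorted(a.segments(), key=lambda s: s[2])
    sb = sorted(b.segments(), key=lambda s: s[2])
    return all(
        np.array_equal(da["polyline"], db["polyline"])
        and np.array_equal(da["radii"], db["radii"])
        for (_, _, _, da), (_, _, _, db) in zip(sa, sb)
    )


class TestVascularGraph:
    def test_no_seeds_gives_empty_graph(self):
        spec = SyntheticSpec(n_seed_vessels=0)
        truth = generate_vascular_graph(spec)
        assert truth.graph.n_segments == 0

    def test_same_seed_bitwise_identical(self):
        spec = SyntheticSpec(rng_seed=11)
        a = generate_vascular_graph(spec).graph
        b = generate_vascular_graph(spec).graph
        assert graphs_equal(a, b)

    def test_different_seed_differs(self):
        a = generate_vascular_graph(SyntheticSpec(rng_seed=1)).graph
        b = generate_vascular_graph(SyntheticSpec(rng_seed=2)).graph
        assert not graphs_equal(a, b)

    def test_zero_tortuosity_zero_branching_gives_straight_segments(self):
        spec = SyntheticSpec(tortuosity=0.0, branch_probability=0.0, rng_seed=3)
        truth = generate_vascular_graph(spec)
        assert truth.graph.n_segments == spec.n_seed_vessels
        for _u, _v, _k, d in truth.graph.segments():
            poly = d["polyline"]
            chord = poly[-1] - poly[0]
            chord = chord / np.linalg.norm(chord)
            rel = poly - poly[0]
            cross = np.linalg.norm(np.cross(rel, chord), axis=1)
            assert cross.max() < 1e-9, "polyline points must be collinear"

    def test_coordinates_stay_inside_extent(self):
        spec = SyntheticSpec(rng_seed=7, n_seed_vessels=10)
        truth = generate_vascular_graph(spec)
        ext = np.asarray(spec.volume_extent)
        for _u, _v, _k, d in truth.graph.segments():
            assert np.all(d["polyline"] >= -1e-9)
            assert np.all(d["polyline"] <= ext + 1e-9)
            assert d["length"] > 0

    def test_too_small_volume_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            generate_vascular_graph(
                SyntheticSpec(volume_extent=(6, 6, 6), radius_range=(2, 4))
            )


class TestRasterization:
    def test_single_tube_voxel_set_exact(self):
        """Noise/blur-free raster marks exactly the voxels whose centres
        lie within the radius of the axis (brute-force distance oracle)."""
        g = axial_tube_graph(4.0, cube=40.0)
        mask = rasterize_tubes(g, (40, 40, 40), (1.0, 1.0, 1.0))
        p0 = np.array([0.0, 20.0, 20.0])
        d = np.array([1.0, 0.0, 0.0])
        ii, jj, kk = np.mgrid[0:40, 0:40, 0:40]
        pts = np.stack([ii, jj, kk], axis=-1).astype(float)
        t = np.clip((pts - p0) @ d / 40.0, 0, 1)
        dist = np.linalg.norm(pts - (p0 + t[..., None] * (40.0 * d)), axis=-1)
        expected = dist <= 4.0
        assert np.array_equal(mask, expected)

    def test_tube_volume_matches_analytic(self):
        """Σ tube voxels ≈ π r² L within 10% for r ≥ 2× spacing."""
        g = axial_tube_graph(4.0, cube=100.0)
        mask = rasterize_tubes(g, (100, 100, 100), (1.0, 1.0, 1.0))
        assert mask.sum() == pytest.approx(np.pi * 16 * 100, rel=0.10)

    def test_empty_graph_channels_indistinguishable(self):
        spec = SyntheticSpec(n_seed_vessels=0, volume_extent=(60, 60, 60),
                             voxel_spacing=(1, 1, 1), rng_seed=4)
        truth = generate_vascular_graph(spec)
        ch = rasterize_graph(truth, spec)
        # same background structure, independent noise: means agree
        assert ch.signal.data.mean() == pytest.approx(
            ch.background.data.mean(), rel=0.02
        )

    def test_subvoxel_tube_flagged(self):
        spec = SyntheticSpec(
            volume_extent=(60, 60, 60), voxel_spacing=(1, 1, 5),
            radius_range=(1.0, 1.5), tortuosity=0, branch_probability=0,
            rng_seed=0,
        )
        truth = generate_vascular_graph(spec)
        assert rasterize_graph(truth, spec).subvoxel_tube

    def test_anisotropic_spacing_honoured(self):
        g = axial_tube_graph(4.0, cube=40.0, axis=0)
        iso = rasterize_tubes(g, (40, 40, 40), (1, 1, 1))
        aniso = rasterize_tubes(g, (40, 40, 8), (1, 1, 5))
        assert aniso.shape == (40, 40, 8)
        # same physical volume within discretization error
        assert aniso.sum() * 5 == pytest.approx(iso.sum(), rel=0.25)


class TestCortexPhantom:
    def test_slab_equal_fractions_equal_bands(self):
        ph = generate_cortex_phantom("slab", [0.5, 0.5], (100, 200, 50), 10.0)
        labels, counts = np.unique(ph.data[ph.data > 0], return_counts=True)
        assert list(labels) == [1, 2]
        assert counts[0] == counts[1]

    def test_fewer_than_two_layers_rejected(self):
        with pytest.raises(ValueError, match="2 layers"):
            generate_cortex_phantom("slab", [1.0], (100, 200, 50), 10.0)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            generate_cortex_phantom("slab", [0.5, 0.6], (100, 200, 50), 10.0)

    def test_half_cylinder_outer_surface_at_radius(self, cylinder_phantom):
        ph = cylinder_phantom
        R = ph.meta["outer_radius_um"]
        lab1 = ph.meta["layer1"]
        ii, jj, _ = np.nonzero(np.asarray(ph.data) == lab1)
        rho = np.hypot(
            ii * ph.spacing[0] - ph.meta["axis_ml_um"],
            jj * ph.spacing[1] - ph.meta["axis_dv_um"],
        )
        assert rho.max() <= R + 1e-9
        # outer-most layer-1 voxels hug the outer radius
        assert rho.max() >= R - 2 * ph.spacing[0]

    def test_layer_volumes_match_annular_closed_form(self):
        fractions = [0.1, 0.2, 0.3, 0.3, 0.1]
        ph = generate_cortex_phantom(
            "half_cylinder", fractions, (1000, 600, 100), 5.0
        )
        R = ph.meta["outer_radius_um"]
        r = ph.meta["inner_radius_um"]
        edges = R - np.cumsum(np.concatenate([[0], fractions])) * (R - r)
        vox = ph.voxel_volume_um3
        ap_len = ph.extent[2]
        for i, lab in enumerate(ph.meta["layer_labels"]):
            analytic = 0.5 * np.pi * (edges[i] ** 2 - edges[i + 1] ** 2) * ap_len
            measured = float((np.asarray(ph.data) == lab).sum()) * vox
            assert measured == pytest.approx(analytic, rel=0.02)


class TestCellField:
    def _annotation(self, n=50, spacing=10.0):
        data = np.ones((n, n, n), dtype=np.int32)
        return VoxelVolume(data, (spacing,) * 3)

    def test_zero_density_empty(self):
        ann = self._annotation()
        pts, labels = generate_cell_field({1: 0.0}, ann, 0)
        assert len(pts) == 0

    def test_missing_region_id_raises(self):
        ann = self._annotation()
        with pytest.raises(KeyError, match="99"):
            generate_cell_field({99: 100.0}, ann, 0)

    def test_points_inside_region_mask(self):
        ann = self._annotation()
        ann.data[:25] = 2
        pts, labels = generate_cell_field({2: 3000.0}, ann, 1)
        idx = np.round(pts / 10.0).astype(int)
        assert np.all(np.asarray(ann.data)[tuple(idx.T)] == 2)

    def test_poisson_mean_recovered(self):
        """Mean count over 100 seeded draws within 3 SE of density×volume."""
        ann = self._annotation(n=20, spacing=10.0)  # 0.008 mm³
        density = 12500.0  # cells/mm³ → expectation 100 per draw
        counts = [
            len(generate_cell_field({1: density}, ann, seed)[0])
            for seed in range(100)
        ]
        expect = density * 0.008
        se = np.sqrt(expect / 100)
        assert abs(np.mean(counts) - expect) < 3 * se

    def test_poisson_dispersion_not_rejected(self):
        """Variance/mean ratio of 200 draws consistent with Poisson
        (χ² dispersion test, α = 0.01)."""
        from scipy import stats as sps

        ann = self._annotation(n=20, spacing=10.0)
        counts = np.array([
            len(generate_cell_field({1: 6250.0}, ann, seed)[0])
            for seed in range(200)
        ])
        disp = (len(counts) - 1) * counts.var(ddof=1) / counts.mean()
        lo, hi = sps.chi2.ppf([0.005, 0.995], len(counts) - 1)
        assert lo < disp < hi


class TestFixtureSuite:
    def test_deterministic_and_manifest_complete(self, tmp_path):
        m1 = make_fixture_suite(tmp_path / "a", rng_seed=0)
        m2 = make_fixture_suite(tmp_path / "b", rng_seed=0)
        assert m1 == m2
        files_a = sorted(p.name for p in (tmp_path / "a").iterdir())
        files_b = sorted(p.name for p in (tmp_path / "b").iterdir())
        assert files_a == files_b
        for name in files_a:
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()
        assert {"spurs", "gap_8um", "gap_12um", "tube_r2", "tube_r3",
                "tube_r5", "lattice", "half_cylinder_phantom"} <= set(
            m1["fixtures"]
        )

    def test_lattice_equal_edges_per_axis(self):
        lat = lattice_graph(pitch=100.0, n=3)
        counts = [0, 0, 0]
        for _u, _v, _k, d in lat.segments():
            step = d["polyline"][-1] - d["polyline"][0]
            counts[int(np.argmax(np.abs(step)))] += 1
        assert counts[0] == counts[1] == counts[2]

    def test_spur_and_gap_fixture_geometry(self):
        g = spur_fixture()
        spur_lengths = sorted(
            d["length"] for u, v, _k, d in g.segments()
            if g.g.degree(u) == 1 or g.g.degree(v) == 1
        )[:3]
        assert spur_lengths == [30.0, 49.0, 51.0]
        gap = gap_fixture(8.0)
        assert gap.n_components() == 2
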