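"""Synthetic ground truth: vascular graphs, two-channel rasters, cortex
phantoms, and cell point fields.

Every downstream stage of the pipeline is validated against data produced
here, where centrelines, radii, layer geometry, and cell densities are
known exactly.  The image model emulates dye-filled vasculature imaged by
block-face two-photon tomography: bright tubes in a signal channel over a
shared autofluorescent background that also appears in a second channel,
anisotropic voxel sampling (1 × 1 × 5 μm by default), Gaussian blur, and
additive noise.

All randomness flows from one :class:`numpy.random.Generator` seeded by
the spec; identical spec + seed reproduces outputs bitwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .graph import VesselGraph
from .volume import VoxelVolume


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic vascular image model (lengths in μm)."""

    volume_extent: tuple[float, float, float] = (200.0, 200.0, 200.0)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 5.0)
    n_seed_vessels: int = 6
    radius_range: tuple[float, float] = (2.0, 4.0)
    tortuosity: float = 0.15          # direction jitter per √μm of arc
    branch_probability: float = 0.005  # Bernoulli branch rate per μm
    signal_level: float = 1000.0
    background_level: float = 100.0
    noise_sd: float = 20.0
    psf_sigma: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.volume_extent):
            raise ValueError("volume_extent must be positive")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be positive")
        if self.radius_range[0] <= 0:
            raise ValueError("minimum radius must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.tortuosity < 0:
            raise ValueError("tortuosity must be non-negative")


@dataclass
class GroundTruth:
    """Known-truth bundle: vessel graph, cell points, annotation volume."""

    graph: VesselGraph
    cells: np.ndarray | None = None          # (n, 3) μm
    cell_labels: np.ndarray | None = None
    annotation: VoxelVolume | None = None


@dataclass
class TwoChannelVolume:
    """Signal (vessels + background) and background-only channels."""

    signal: VoxelVolume
    background: VoxelVolume
    subvoxel_tube: bool = False


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


# ------------------------------------------------------------ vessel growth

def generate_vascular_graph(spec: SyntheticSpec) -> GroundTruth:
    """Grow a random vascular network inside the spec's volume.

    Vessels are seeded at random interior points and grown as random
    walks: each 2 μm step perturbs the direction by an isotropic Gaussian
    scaled by ``tortuosity``; branching is Bernoulli per μm of arc.  Each
    segment carries one constant radius drawn uniformly from
    ``radius_range``.  Walks terminate at the volume boundary (truncated
    exactly at the face) or at a length cap.

    With ``tortuosity == 0`` and ``branch_probability == 0`` every vessel
    is a straight two-point segment.
    """
    extent = np.asarray(spec.volume_extent, dtype=float)
    r_max = spec.radius_range[1]
    if np.any(extent < 2.05 * r_max):
        raise ValueError(
            f"volume extent {tuple(extent)} too small for vessels of radius {r_max}"
        )
    rng = np.random.default_rng(spec.rng_seed)
    graph = VesselGraph()
    truth = GroundTruth(graph=graph)
    if spec.n_seed_vessels == 0:
        return truth

    step = 2.0
    max_len = 2.0 * float(np.linalg.norm(extent))
    margin = min(r_max + 1.0, 0.4 * extent.min())
    max_segments = 60 * spec.n_seed_vessels

    # stack of walkers: (start node id, position, direction)
    stack: list[tuple[int, np.ndarray, np.ndarray]] = []
    for _ in range(spec.n_seed_vessels):
        pos = rng.uniform(margin, extent - margin)
        stack.append((graph.add_node(pos), pos, _random_unit(rng)))

    while stack and graph.n_segments < max_segments:
        start_node, pos, direction = stack.pop()
        radius = rng.uniform(*spec.radius_range)
        points = [pos.copy()]
        walked = 0.0
        while True:
            if spec.tortuosity > 0:
                direction = _unit(
                    direction
                    + spec.tortuosity * np.sqrt(step) * rng.normal(size=3) * 0.3
                )
            nxt = pos + step * direction
            if np.any(nxt < 0) or np.any(nxt > extent):
                # truncate the step exactly at the first face crossed
                with np.errstate(divide="ignore", invalid="ignore"):
                    t_lo = np.where(nxt < 0, pos / np.maximum(pos - nxt, 1e-30), 1.0)
                    t_hi = np.where(
                        nxt > extent,
                        (extent - pos) / np.maximum(nxt - pos, 1e-30),
                        1.0,
                    )
                t = float(np.clip(min(t_lo.min(), t_hi.min()), 0.0, 1.0))
                end = pos + t * step * direction
                if np.linalg.norm(end - points[-1]) > 1e-9:
                    points.append(end)
                break
            pos = nxt
            walked += step
            points.append(pos.copy())
            if walked >= max_len:
                break
            if rng.random() < spec.branch_probability * step:
                # end the segment here; spawn continuation + branch walker
                node = graph.add_node(pos)
                poly = np.asarray(points)
                if len(poly) >= 2:
                    graph.add_segment(
                        start_node, node, poly, np.full(len(poly), radius)
                    )
                branch_dir = _unit(direction + 1.2 * _random_unit(rng))
                stack.append((node, pos.copy(), branch_dir))
                stack.append((node, pos.copy(), direction.copy()))
                points = None
                break
        if points is not None and len(points) >= 2:
            end_node = graph.add_node(points[-1])
            poly = np.asarray(points)
            graph.add_segment(start_node, end_node, poly, np.full(len(poly), radius))
    return truth


def generate_recovery_network(
    extent: float = 200.0,
    n_trees: int = 2,
    min_segment: float = 60.0,
    radius_range: tuple[float, float] = (2.0, 3.5),
    clearance: float = 14.0,
    rng: np.random.Generator | int | None = 0,
) -> GroundTruth:
    """Well-separated branching trees for tracing-recovery benchmarks.

    Guarantees: every segment is straight with length ≥ ``min_segment``,
    radii ≥ ``radius_range[0]``, and the surface gap between any two
    non-adjacent segments exceeds ``clearance`` minus the two radii.
    Branch angles are kept wide so junctions are geometrically clean.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ext = np.full(3, float(extent))

    def seg_points(p0, p1):
        n = max(int(np.linalg.norm(p1 - p0) / 2.0), 2)
        t = np.linspace(0, 1, n)[:, None]
        return p0 + t * (p1 - p0)

    for _attempt in range(200):
        segs: list[tuple[np.ndarray, np.ndarray, float, int, int]] = []
        nodes: list[np.ndarray] = []
        ok = True

        def clashes(p0, p1, exclude_nodes):
            pts = seg_points(p0, p1)
            for q0, q1, _r, a, b in segs:
                qts = seg_points(q0, q1)
                d = np.linalg.norm(pts[:, None, :] - qts[None, :, :], axis=2)
                if {a, b} & set(exclude_nodes):
                    # adjacent segment: ignore the neighbourhood of the joint
                    shared = [nodes[i] for i in ({a, b} & set(exclude_nodes))]
                    near = np.zeros(d.shape, bool)
                    for s in shared:
                        near |= (
                            (np.linalg.norm(pts - s, axis=1)[:, None] < 25)
                            | (np.linalg.norm(qts - s, axis=1)[None, :] < 25)
                        )
                    d = np.where(near, np.inf, d)
                if d.min() < clearance:
                    return True
            return False

        for _tree in range(n_trees):
            root = rng.uniform(0.15 * extent, 0.85 * extent, size=3)
            direction = _random_unit(rng)
            length = rng.uniform(min_segment, 1.3 * min_segment)
            tip = root + length * direction
            if np.any(tip < 10) or np.any(tip > ext - 10) or clashes(root, tip, ()):
                ok = False
                break
            i0, i1 = len(nodes), len(nodes) + 1
            nodes += [root, tip]
            segs.append((root, tip, rng.uniform(*radius_range), i0, i1))
            # two children from the trunk tip at wide angles
            placed = 0
            for _try in range(40):
                if placed == 2:
                    break
                child_dir = _unit(direction + rng.uniform(0.9, 1.6) * _random_unit(rng))
                if np.dot(child_dir, direction) < 0.1:
                    continue
                clen = rng.uniform(min_segment, 1.2 * min_segment)
                ctip = tip + clen * child_dir
                if np.any(ctip < 10) or np.any(ctip > ext - 10):
                    continue
                if placed == 1:
                    prev = segs[-1]
                    pdir = _unit(prev[1] - prev[0])
                    if np.dot(child_dir, pdir) > 0.55:  # siblings too parallel
                        continue
                if clashes(tip, ctip, (i1,)):
                    continue
                ic = len(nodes)
                nodes.append(ctip)
                segs.append((tip, ctip, rng.uniform(*radius_range), i1, ic))
                placed += 1
            if placed < 2:
                ok = False
                break
        if ok:
            break
    else:
        raise RuntimeError("failed to place a recovery network; relax parameters")

    graph = VesselGraph()
    ids = [graph.add_node(p) for p in nodes]
    for p0, p1, r, a, b in segs:
        poly = np.vstack([p0, p1])
        graph.add_segment(ids[a], ids[b], poly, np.full(2, r))
    return GroundTruth(graph=graph)


# ------------------------------------------------------------- rasterization

def _rasterize_capsule(mask, p0, p1, radius, spacing):
    """OR into ``mask`` all voxels whose centres lie within ``radius`` μm
    of the segment p0–p1 (exact point-to-segment distance)."""
    spacing = np.asarray(spacing, dtype=float)
    lo = np.floor((np.minimum(p0, p1) - radius) / spacing).astype(int)
    hi = np.ceil((np.maximum(p0, p1) + radius) / spacing).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, mask.shape)
    if np.any(lo >= hi):
        return
    grids = np.meshgrid(
        *[np.arange(l, h) * s for l, h, s in zip(lo, hi, spacing)], indexing="ij"
    )
    pts = np.stack(grids, axis=-1)
    d = p1 - p0
    L2 = float(d @ d)
    if L2 < 1e-18:
        dist = np.linalg.norm(pts - p0, axis=-1)
    else:
        t = np.clip(((pts - p0) @ d) / L2, 0.0, 1.0)
        proj = p0 + t[..., None] * d
        dist = np.linalg.norm(pts - proj, axis=-1)
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    mask[sl] |= dist <= radius


def rasterize_tubes(graph: VesselGraph, shape, spacing) -> np.ndarray:
    """Boolean volume: union of capsules around every segment polyline."""
    mask = np.zeros(shape, dtype=bool)
    for _u, _v, _k, data in graph.segments():
        poly, radii = data["polyline"], data["radii"]
        for i in range(len(poly) - 1):
            r = 0.5 * (radii[i] + radii[i + 1])
            _rasterize_capsule(mask, poly[i], poly[i + 1], r, spacing)
    return mask


def rasterize_graph(truth: GroundTruth, spec: SyntheticSpec) -> TwoChannelVolume:
    """Render the ground-truth graph as a two-channel image volume.

    Signal channel: tubes at ``signal_level`` blurred by the PSF, plus a
    shared low-frequency autofluorescent background and additive Gaussian
    noise.  Background channel: the same background structure with
    independent noise but no tubes, so channel subtraction isolates the
    vasculature.
    """
    spacing = np.asarray(spec.voxel_spacing, dtype=float)
    shape = tuple(
        int(np.ceil(e / s)) for e, s in zip(spec.volume_extent, spacing)
    )
    rng = np.random.default_rng(spec.rng_seed + 1)

    tubes = rasterize_tubes(truth.graph, shape, spacing).astype(np.float64)
    subvoxel = False
    for _u, _v, _k, data in truth.graph.segments():
        if np.any(data["radii"] < 0.5 * spacing.max()):
            subvoxel = True

    if spec.psf_sigma > 0:
        ndimage.gaussian_filter(
            tubes, sigma=spec.psf_sigma / spacing, output=tubes
        )
    signal = spec.signal_level * tubes

    # low-frequency background structure shared by both channels
    bg = np.full(shape, float(spec.background_level))
    if spec.background_level > 0:
        rough = rng.normal(size=shape)
        smooth_sigma = 20.0 / spacing
        low = ndimage.gaussian_filter(rough, sigma=smooth_sigma)
        peak = np.abs(low).max()
        if peak > 0:
            bg *= 1.0 + 0.3 * low / peak

    noise_a = rng.normal(0.0, 1.0, size=shape) if spec.noise_sd > 0 else 0.0
    noise_b = rng.normal(0.0, 1.0, size=shape) if spec.noise_sd > 0 else 0.0
    sig_vol = VoxelVolume(signal + bg + spec.noise_sd * noise_a, tuple(spacing))
    bg_vol = VoxelVolume(bg + spec.noise_sd * noise_b, tuple(spacing))
    return TwoChannelVolume(sig_vol, bg_vol, subvoxel_tube=subvoxel)


# ------------------------------------------------------------ cortex phantom

#: default annotation labels for phantom layers, outer (pial) to inner
PHANTOM_LAYER_LABELS = (1, 2, 3, 4, 5, 6)


def generate_cortex_phantom(
    shape: str,
    layer_fractions,
    extent,
    spacing: float,
    inner_radius: float | None = None,
    outer_radius: float | None = None,
) -> VoxelVolume:
    """Labelled cortex phantom: parallel-band slab or half-cylinder shell.

    ``layer_fractions`` (summing to 1, outer first) divide the cortical
    thickness; label ``i+1`` marks layer ``i``.  Background is 0.  The
    returned volume's ``meta`` records ``layer_labels`` (outer→inner),
    ``layer1`` and ``layer6b`` labels, and the phantom geometry.

    The slab stacks layers along DV with layer 1 on top (dorsal).  The
    half-cylinder is a shell around an AP-parallel axis, layer 1
    outermost, upper (dorsal) half only.
    """
    fractions = np.asarray(layer_fractions, dtype=float)
    if len(fractions) < 2:
        raise ValueError("a cortex phantom needs at least 2 layers")
    if abs(fractions.sum() - 1.0) > 1e-6:
        raise ValueError(f"layer fractions must sum to 1, got {fractions.sum()}")
    extent = np.asarray(extent, dtype=float)
    dims = tuple(int(round(e / spacing)) for e in extent)
    labels = list(PHANTOM_LAYER_LABELS[: len(fractions)])
    if len(labels) < len(fractions):
        labels = list(range(1, len(fractions) + 1))
    data = np.zeros(dims, dtype=np.int32)
    sp = float(spacing)
    meta = {
        "layer_labels": labels,
        "layer1": labels[0],
        "layer6b": labels[-1],
        "background": 0,
        "shape": shape,
    }

    if shape == "slab":
        dv_n = dims[1]
        top = int(round(0.9 * dv_n))      # dorsal cortex surface (voxel index)
        bottom = int(round(0.1 * dv_n))
        thick = top - bottom
        edges = top - np.round(np.cumsum(np.concatenate([[0], fractions])) * thick).astype(int)
        for i, lab in enumerate(labels):
            data[:, edges[i + 1]: edges[i], :] = lab
        meta.update(top_um=top * sp, bottom_um=bottom * sp, thickness_um=thick * sp)
    elif shape == "half_cylinder":
        ml_n, dv_n, _ = dims
        axis_ml = 0.5 * extent[0]
        axis_dv = 0.1 * extent[1]
        R = outer_radius if outer_radius is not None else 0.85 * min(
            0.5 * extent[0], extent[1] - axis_dv
        )
        r = inner_radius if inner_radius is not None else 0.5 * R
        if r <= 0 or r >= R:
            raise ValueError("need 0 < inner_radius < outer_radius")
        ml = (np.arange(dims[0]) * sp)[:, None] - axis_ml
        dv = (np.arange(dims[1]) * sp)[None, :] - axis_dv
        rho = np.hypot(ml, dv)
        upper = dv >= 0
        radial_edges = R - np.cumsum(np.concatenate([[0], fractions])) * (R - r)
        plane = np.zeros(dims[:2], dtype=np.int32)
        for i, lab in enumerate(labels):
            ring = (rho <= radial_edges[i]) & (rho > radial_edges[i + 1]) & upper
            plane[ring] = lab
        data[:] = plane[:, :, None]
        meta.update(
            axis_ml_um=axis_ml, axis_dv_um=axis_dv,
            outer_radius_um=float(R), inner_radius_um=float(r),
        )
    else:
        raise ValueError(f"unknown phantom shape {shape!r}")

    return VoxelVolume(data, (sp, sp, sp), meta=meta)


# ------------------------------------------------------------- cell fields

def generate_cell_field(
    density_by_region: dict[int, float],
    annotation: VoxelVolume,
    rng_seed: int | np.random.Generator = 0,
    label: str = "cell",
) -> tuple[np.ndarray, np.ndarray]:
    """Homogeneous Poisson cell placement per annotation region.

    For each region the count is Poisson(density × region volume) with
    density in cells/mm³; points are uniform over the region's voxels
    (uniform jitter within each voxel).  Returns ``(points_um, labels)``.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    vox_mm3 = annotation.voxel_volume_um3 / 1e9
    spacing = np.asarray(annotation.spacing)
    all_pts, all_lbl = [], []
    for region_id in sorted(density_by_region):
        density = density_by_region[region_id]
        if density < 0:
            raise ValueError(f"negative density for region {region_id}")
        idx = np.argwhere(annotation.data == region_id)
        if len(idx) == 0:
            raise KeyError(f"region ID {region_id} absent from annotation")
        n = rng.poisson(density * len(idx) * vox_mm3)
        if n == 0:
            continue
        choice = idx[rng.integers(0, len(idx), size=n)]
        jitter = rng.uniform(-0.5, 0.5, size=(n, 3))
        pts = (choice + jitter) * spacing + np.asarray(annotation.origin)
        all_pts.append(pts)
        all_lbl.extend([f"{label}:{region_id}"] * n)
    if not all_pts:
        return np.zeros((0, 3)), np.asarray([], dtype=object)
    return np.vstack(all_pts), np.asarray(all_lbl, dtype=object)


def correlated_roi_table(
    n_roi: int = 40,
    r_true: float = 0.9,
    rng: np.random.Generator | int | None = 0,
):
    """Paired regional densities sharing a latent spatial pattern.

    Emulates the cross-region situation where vascular length density and
    a cell-type density co-vary: both are affine images of one latent
    factor plus independent noise, tuned so the population correlation is
    ``r_true``.  Returns a DataFrame with one row per ROI.
    """
    import pandas as pd

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    latent = rng.normal(size=n_roi)
    noise = rng.normal(size=n_roi)
    z = r_true * latent + np.sqrt(max(0.0, 1 - r_true**2)) * noise
    return pd.DataFrame(
        {
            "region_id": np.arange(1, n_roi + 1),
            # plausible scales: length density ~0.9 m/mm³, pericytes ~2500/mm³
            "length_density_m_per_mm3": 0.9 + 0.15 * latent,
            "cell_density_per_mm3": 2500 + 400 * z,
        }
    ).set_index("region_id")


# ------------------------------------------------------------ fixture suite

def make_fixture_suite(out_dir, rng_seed: int = 0) -> dict:
    """Write the canonical named test fixtures and a manifest.

    Contents: a spur ladder ({30, 49, 51} μm terminal branches on a long
    backbone), endpoint-gap pairs ({8, 12} μm), axial tubes of radius
    {2, 3, 5} μm spanning a 400³ μm cube, an isotropic 3D lattice
    network, and a half-cylinder cortex phantom.  Deterministic: the same
    seed yields byte-identical files.
    """
    from . import io as vio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"rng_seed": rng_seed, "fixtures": {}}

    g = spur_fixture()
    vio.write_graph(out, g, stem="spurs")
    manifest["fixtures"]["spurs"] = {
        "stem": "spurs", "spur_lengths_um": [30, 49, 51], "backbone_um": 500
    }

    for gap in (8, 12):
        vio.write_graph(out, gap_fixture(gap), stem=f"gap_{gap}um")
        manifest["fixtures"][f"gap_{gap}um"] = {
            "stem": f"gap_{gap}um", "gap_um": gap, "segment_um": 100
        }

    for r in (2, 3, 5):
        vio.write_graph(out, axial_tube_graph(r), stem=f"tube_r{r}")
        manifest["fixtures"][f"tube_r{r}"] = {
            "stem": f"tube_r{r}", "radius_um": r, "cube_um": 400,
            "poiseuille_k": float(np.pi * r**4 / 8.0),
        }

    lat = lattice_graph()
    vio.write_graph(out, lat, stem="lattice")
    manifest["fixtures"]["lattice"] = {
        "stem": "lattice", "pitch_um": 100, "n_cells": 4, "radius_um": 3,
        "edges_per_axis": lat.n_segments // 3,
    }

    phantom = generate_cortex_phantom(
        "half_cylinder", [0.1, 0.2, 0.3, 0.3, 0.1], (1000, 600, 300), 10.0
    )
    vio.write_nrrd(out / "half_cylinder_phantom.nrrd", phantom)
    manifest["fixtures"]["half_cylinder_phantom"] = {
        "file": "half_cylinder_phantom.nrrd", **phantom.meta
    }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def spur_fixture(spur_lengths=(30.0, 49.0, 51.0), backbone: float = 500.0) -> VesselGraph:
    """Long straight backbone with short terminal branches (spurs)."""
    g = VesselGraph()
    a = g.add_node((0.0, 100.0, 100.0))
    xs = np.linspace(backbone / (len(spur_lengths) + 1), backbone, len(spur_lengths) + 1)
    prev = a
    for i, x in enumerate(xs[:-1]):
        node = g.add_node((x, 100.0, 100.0))
        p0, p1 = g.node_pos(prev), g.node_pos(node)
        g.add_segment(prev, node, np.vstack([p0, p1]), np.full(2, 3.0))
        tip = g.add_node((x, 100.0 + spur_lengths[i], 100.0))
        g.add_segment(node, tip, np.vstack([p1, g.node_pos(tip)]), np.full(2, 2.0))
        prev = node
    end = g.add_node((backbone, 100.0, 100.0))
    g.add_segment(prev, end, np.vstack([g.node_pos(prev), g.node_pos(end)]), np.full(2, 3.0))
    return g


def gap_fixture(gap_um: float, segment_um: float = 100.0) -> VesselGraph:
    """Two collinear segments whose facing endpoints are ``gap_um`` apart."""
    g = VesselGraph()
    a = g.add_node((0.0, 50.0, 50.0))
    b = g.add_node((segment_um, 50.0, 50.0))
    c = g.add_node((segment_um + gap_um, 50.0, 50.0))
    d = g.add_node((2 * segment_um + gap_um, 50.0, 50.0))
    for u, v in ((a, b), (c, d)):
        g.add_segment(u, v, np.vstack([g.node_pos(u), g.node_pos(v)]), np.full(2, 3.0))
    return g


def axial_tube_graph(radius: float, cube: float = 400.0, axis: int = 0) -> VesselGraph:
    """One straight tube spanning a cube along a Cartesian axis."""
    g = VesselGraph()
    mid = cube / 2.0
    p0 = np.full(3, mid)
    p1 = np.full(3, mid)
    p0[axis] = 0.0
    p1[axis] = cube
    a = g.add_node(p0)
    b = g.add_node(p1)
    g.add_segment(a, b, np.vstack([p0, p1]), np.full(2, float(radius)))
    return g


def lattice_graph(pitch: float = 100.0, n: int = 4, radius: float = 3.0) -> VesselGraph:
    """Isotropic cubic lattice network with equal edge counts per axis."""
    g = VesselGraph()
    ids = {}
    for i in range(n + 1):
        for j in range(n + 1):
            for k in range(n + 1):
                ids[(i, j, k)] = g.add_node((i * pitch, j * pitch, k * pitch))
    for (i, j, k), u in ids.items():
        for di, dj, dk in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
            nb = (i + di, j + dj, k + dk)
            if nb in ids:
                v = ids[nb]
                g.add_segment(
                    u, v, np.vstack([g.node_pos(u), g.node_pos(v)]),
                    np.full(2, radius),
                )
    return g
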