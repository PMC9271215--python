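"""Regional and voxel-level vascular statistics.

Length density is reported in m/mm³ (total centreline length per tissue
volume; 1 m/mm³ ≡ 1 μm/μm³ × 10⁻⁶... concretely, μm of vessel per mm³
divided by 10⁶).  Branching density is branch nodes per mm³.  Regional
mean radius is length-weighted by default.  Segment length is
apportioned to regions by arc length of the polyline inside each
region's voxels, so segments straddling a border credit each side with
exactly the length it contains.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .graph import VesselGraph
from .volume import VoxelVolume

UM_PER_MM3_TO_M_PER_MM3 = 1e-6

#: radius cutoffs (μm) used for the large-vessel length fraction:
#: 5 μm for display-style large/small split, 3 μm for large-vasculature
#: analysis; both are parameters of region_vascular_stats.
LARGE_VESSEL_RADIUS_DISPLAY = 5.0
LARGE_VESSEL_RADIUS_ANALYSIS = 3.0


def _densify(poly: np.ndarray, radii: np.ndarray, step: float):
    """Resample a polyline at ≤ ``step`` μm; returns midpoints, step
    lengths, and midpoint radii (linearly interpolated)."""
    mids, lens, rads = [], [], []
    for i in range(len(poly) - 1):
        p0, p1 = poly[i], poly[i + 1]
        seg = float(np.linalg.norm(p1 - p0))
        if seg < 1e-12:
            continue
        k = max(int(np.ceil(seg / step)), 1)
        t = (np.arange(k) + 0.5) / k
        mids.append(p0 + t[:, None] * (p1 - p0))
        lens.append(np.full(k, seg / k))
        rads.append(radii[i] + t * (radii[i + 1] - radii[i]))
    if not mids:
        return np.zeros((0, 3)), np.zeros(0), np.zeros(0)
    return np.vstack(mids), np.concatenate(lens), np.concatenate(rads)


def _lookup_labels(annotation: VoxelVolume, points_um: np.ndarray) -> np.ndarray:
    idx = np.round(annotation.world_to_index(points_um)).astype(int)
    shape = np.asarray(annotation.shape)
    ok = np.all((idx >= 0) & (idx < shape), axis=1)
    labels = np.zeros(len(points_um), dtype=np.asarray(annotation.data).dtype)
    if ok.any():
        labels[ok] = np.asarray(annotation.data)[tuple(idx[ok].T)]
    return labels


def region_vascular_stats(
    graph: VesselGraph,
    annotation: VoxelVolume,
    step_um: float | None = None,
    large_radius_um: float = LARGE_VESSEL_RADIUS_DISPLAY,
    weighted_radius: bool = True,
) -> pd.DataFrame:
    """Per-region vessel statistics table.

    Columns: ``volume_mm3``, ``total_length_um``, ``length_density_m_per_mm3``,
    ``n_branch_nodes``, ``branch_density_per_mm3``, ``mean_radius_um``,
    ``large_vessel_fraction`` (fraction of length with radius >
    ``large_radius_um``).  Regions with no vessels report zero densities
    but their true volume.
    """
    if step_um is None:
        step_um = 0.5 * min(annotation.spacing)
    data = np.asarray(annotation.data)
    region_ids, counts = np.unique(data, return_counts=True)
    vox_mm3 = annotation.voxel_volume_um3 / 1e9
    volume = {int(r): float(c) * vox_mm3 for r, c in zip(region_ids, counts)}

    length = {int(r): 0.0 for r in region_ids}
    rad_len = {int(r): 0.0 for r in region_ids}
    rad_sum = {int(r): 0.0 for r in region_ids}
    rad_n = {int(r): 0 for r in region_ids}
    large = {int(r): 0.0 for r in region_ids}
    branches = {int(r): 0 for r in region_ids}

    for _u, _v, _k, d in graph.segments():
        mids, lens, rads = _densify(d["polyline"], d["radii"], step_um)
        labels = _lookup_labels(annotation, mids)
        for lab in np.unique(labels):
            sel = labels == lab
            key = int(lab)
            if key not in length:
                continue
            L = float(lens[sel].sum())
            length[key] += L
            rad_len[key] += float((lens[sel] * rads[sel]).sum())
            rad_sum[key] += float(rads[sel].mean()) * 1.0
            rad_n[key] += 1
            large[key] += float(lens[sel][rads[sel] > large_radius_um].sum())

    for nid in graph.branch_nodes():
        lab = int(_lookup_labels(annotation, graph.node_pos(nid)[None, :])[0])
        if lab in branches:
            branches[lab] += 1

    rows = []
    for r in sorted(volume):
        vol = volume[r]
        L = length[r]
        if weighted_radius:
            mean_r = rad_len[r] / L if L > 0 else np.nan
        else:
            mean_r = rad_sum[r] / rad_n[r] if rad_n[r] else np.nan
        rows.append(
            dict(
                region_id=r,
                volume_mm3=vol,
                total_length_um=L,
                length_density_m_per_mm3=L / vol * UM_PER_MM3_TO_M_PER_MM3,
                n_branch_nodes=branches[r],
                branch_density_per_mm3=branches[r] / vol,
                mean_radius_um=mean_r,
                large_vessel_fraction=(large[r] / L) if L > 0 else 0.0,
            )
        )
    return pd.DataFrame(rows).set_index("region_id")


def voxelize_density(
    graph: VesselGraph,
    extent_um,
    bin_um: float = 20.0,
    smooth_sigma_bins: float = 2.0,
    mode: str = "length",
) -> VoxelVolume:
    """Bin vessel measure on a coarse grid and Gaussian-smooth it.

    ``mode``: ``length`` (μm of centreline per bin), ``branches``
    (branch-node count per bin), or ``radius_length`` (radius-weighted
    length, for mean-radius maps when divided by the length volume).
    Smoothing uses σ = ``smooth_sigma_bins`` bins and conserves total
    mass away from the volume border.
    """
    if bin_um <= 0:
        raise ValueError("bin size must be positive")
    shape = tuple(int(np.ceil(e / bin_um)) for e in extent_um)
    acc = np.zeros(shape)

    if mode in ("length", "radius_length"):
        for _u, _v, _k, d in graph.segments():
            mids, lens, rads = _densify(d["polyline"], d["radii"], bin_um / 4.0)
            if not len(mids):
                continue
            idx = np.floor(mids / bin_um).astype(int)
            ok = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
            w = lens if mode == "length" else lens * rads
            np.add.at(acc, tuple(idx[ok].T), w[ok])
    elif mode == "branches":
        for nid in graph.branch_nodes():
            idx = np.floor(graph.node_pos(nid) / bin_um).astype(int)
            if np.all(idx >= 0) and np.all(idx < np.asarray(shape)):
                acc[tuple(idx)] += 1.0
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if smooth_sigma_bins > 0:
        acc = ndimage.gaussian_filter(acc, sigma=smooth_sigma_bins)
    return VoxelVolume(acc, (bin_um,) * 3, meta={"mode": mode})


def layer_profile(
    graph: VesselGraph,
    annotation: VoxelVolume,
    layer_of_label: dict[int, str],
    region_of_label: dict[int, int] | None = None,
    step_um: float | None = None,
) -> pd.DataFrame:
    """Per-(region, layer) vascular length density table.

    ``layer_of_label`` maps annotation labels to layer names; labels
    missing from it are ignored.  ``region_of_label`` optionally groups
    labels into parent regions (default: each label is its own region).
    """
    if not layer_of_label:
        raise ValueError("annotation lacks layer labels")
    if step_um is None:
        step_um = 0.5 * min(annotation.spacing)
    if region_of_label is None:
        region_of_label = {lab: lab for lab in layer_of_label}
    vox_mm3 = annotation.voxel_volume_um3 / 1e9
    data = np.asarray(annotation.data)

    acc: dict[tuple[int, str], float] = {}
    vol: dict[tuple[int, str], float] = {}
    for lab, layer in layer_of_label.items():
        key = (region_of_label[lab], layer)
        vol[key] = vol.get(key, 0.0) + float((data == lab).sum()) * vox_mm3
        acc.setdefault(key, 0.0)

    for _u, _v, _k, d in graph.segments():
        mids, lens, _ = _densify(d["polyline"], d["radii"], step_um)
        labels = _lookup_labels(annotation, mids)
        for lab in np.unique(labels):
            lab = int(lab)
            if lab not in layer_of_label:
                continue
            key = (region_of_label[lab], layer_of_label[lab])
            acc[key] += float(lens[labels == lab].sum())

    rows = [
        dict(
            region_id=region,
            layer=layer,
            volume_mm3=vol[(region, layer)],
            total_length_um=acc[(region, layer)],
            length_density_m_per_mm3=(
                acc[(region, layer)] / vol[(region, layer)] * UM_PER_MM3_TO_M_PER_MM3
                if vol[(region, layer)] > 0
                else np.nan
            ),
        )
        for (region, layer) in sorted(acc)
    ]
    return pd.DataFrame(rows)
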