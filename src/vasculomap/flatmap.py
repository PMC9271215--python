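"""Laplace-equation isocortical flatmap.

The cortical depth coordinate is the solution of the Laplace equation on
cortex voxels with Dirichlet value 1 on the pial (layer 1) surface, 0 on
the white-matter (layer 6b) surface, and zero flux through every other
cortical boundary.  Ascending-gradient streamlines carry each cortex
voxel to its pial surface point; the flatmap coordinates are the
anterior–posterior (AP) position of that point (y) and the signed
surface arc length — azimuth — from the dorsal-ridge reference within
the coronal plane (x).

Axis convention: arrays are indexed (ML, DV, AP); dorsal = larger DV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import ndimage

from .volume import VoxelVolume

_FACES = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)], dtype=int
)


@dataclass
class PotentialField:
    """Laplace depth potential over the cortex and its unit gradient."""

    potential: VoxelVolume              # NaN outside cortex, in [0, 1] inside
    gradient: np.ndarray                # shape + (3,), unit vectors
    cortex_mask: np.ndarray
    surface1_mask: np.ndarray           # pial Dirichlet voxels (value 1)
    surface0_mask: np.ndarray           # white-matter Dirichlet voxels (value 0)


@dataclass
class FlatmapProjection:
    """Per-voxel flat coordinates: azimuth arc (x), AP (y), depth potential."""

    flat_x: np.ndarray                  # μm, NaN where unresolved/non-cortex
    flat_y: np.ndarray
    depth: np.ndarray
    surface_points: np.ndarray          # shape + (3,) μm
    unresolved: int
    spacing: tuple[float, float, float]

    def lookup(self, grid_um: float = 10.0):
        """Resampled (flat_x, flat_y, depth) lookup volumes at ``grid_um``.

        The native-resolution arrays are authoritative; coarser grids are
        produced by striding (e.g. 20 μm from 10 μm)."""
        stride = max(int(round(grid_um / self.spacing[0])), 1)
        sl = (slice(None, None, stride),) * 3
        return self.flat_x[sl], self.flat_y[sl], self.depth[sl]


def solve_laplace(
    annotation: VoxelVolume,
    layer1_labels=None,
    layer6b_labels=None,
    cortex_labels=None,
    rtol: float = 1e-10,
) -> PotentialField:
    """Solve the depth-potential Laplace problem on an annotation volume.

    Dirichlet 1 on layer-1 voxels 6-adjacent to non-cortex, Dirichlet 0
    on layer-6b voxels 6-adjacent to non-cortex, natural (zero-flux)
    conditions elsewhere: the finite-difference Laplacian simply omits
    links leaving the cortex.  Solved as a sparse SPD system
    (conjugate gradients, Jacobi preconditioner).

    Label sets default to the phantom metadata stored in
    ``annotation.meta`` (``layer1``, ``layer6b``, ``layer_labels``).
    """
    meta = annotation.meta
    if layer1_labels is None:
        layer1_labels = [meta["layer1"]]
    if layer6b_labels is None:
        layer6b_labels = [meta["layer6b"]]
    if cortex_labels is None:
        cortex_labels = meta.get("layer_labels")
    data = np.asarray(annotation.data)
    layer1_labels = np.atleast_1d(layer1_labels)
    layer6b_labels = np.atleast_1d(layer6b_labels)
    cortex = (
        np.isin(data, np.atleast_1d(cortex_labels))
        if cortex_labels is not None
        else data != 0
    )
    outside = ~cortex
    struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    touches_out = ndimage.binary_dilation(outside, structure=struct) & cortex
    surface1 = np.isin(data, layer1_labels) & touches_out
    surface0 = np.isin(data, layer6b_labels) & touches_out
    if not surface1.any():
        raise ValueError("no layer-1 surface adjacent to non-cortex found")
    if not surface0.any():
        raise ValueError("no layer-6b surface adjacent to non-cortex found")

    unknown = cortex & ~surface1 & ~surface0
    uidx = np.full(data.shape, -1, dtype=np.int64)
    coords = np.argwhere(unknown)
    uidx[tuple(coords.T)] = np.arange(len(coords))

    rows, cols, vals = [], [], []
    b = np.zeros(len(coords))
    diag = np.zeros(len(coords))
    shape = np.asarray(data.shape)
    for face in _FACES:
        nb = coords + face
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        nb_ok = nb[ok]
        src = np.flatnonzero(ok)
        in_cortex = cortex[tuple(nb_ok.T)]
        src = src[in_cortex]
        nb_ok = nb_ok[in_cortex]
        diag_add = np.zeros(len(coords))
        np.add.at(diag_add, src, 1.0)
        diag += diag_add
        j = uidx[tuple(nb_ok.T)]
        free = j >= 0
        rows.extend(src[free])
        cols.extend(j[free])
        vals.extend(np.full(free.sum(), -1.0))
        fixed = ~free
        fixed_val = surface1[tuple(nb_ok[fixed].T)].astype(float)  # 1 on pial, 0 on wm
        np.add.at(b, src[fixed], fixed_val)

    n = len(coords)
    potential = np.full(data.shape, np.nan)
    potential[surface1] = 1.0
    potential[surface0] = 0.0
    if n:
        A = sp.csr_matrix(
            (np.concatenate([vals, diag]),
             (np.concatenate([rows, np.arange(n)]),
              np.concatenate([cols, np.arange(n)]))),
            shape=(n, n),
        )
        M = sp.diags(1.0 / A.diagonal())
        x, info = spla.cg(A, b, rtol=rtol, maxiter=20000, M=M)
        if info != 0:
            raise RuntimeError(f"Laplace solver did not converge (info={info})")
        potential[tuple(coords.T)] = x

    grad = _unit_gradient(potential, cortex, annotation.spacing)
    return PotentialField(
        annotation.like(potential), grad, cortex, surface1, surface0
    )


def _unit_gradient(potential, cortex, spacing):
    """Unit gradient of the potential, defined on cortex voxels.

    Non-cortex values are filled with the nearest cortex potential before
    differencing so boundary voxels get one-sided-consistent gradients.
    """
    filled = potential.copy()
    missing = ~np.isfinite(filled)
    if missing.any():
        _, nearest = ndimage.distance_transform_edt(
            missing, sampling=spacing, return_indices=True
        )
        filled[missing] = filled[tuple(ind[missing] for ind in nearest)]
    # slight smoothing before differencing: staircased Dirichlet corners
    # can have an exactly-zero discrete gradient, which would stall
    # streamlines seeded there
    filled = ndimage.gaussian_filter(filled, sigma=0.7)
    g = np.stack(np.gradient(filled, *spacing), axis=-1)
    norm = np.linalg.norm(g, axis=-1)
    norm[norm == 0] = 1.0
    g = g / norm[..., None]
    g[~cortex] = 0.0
    return g


# -------------------------------------------------------------- projection

def _coronal_azimuth(field: PotentialField, spacing, smooth_window: int = 5):
    """Per-coronal-plane surface contours with signed azimuth arc length.

    For each AP plane: pial surface voxels are ordered by angle around
    the plane's cortex centroid, positions smoothed by a short moving
    average to suppress voxel staircase, and cumulative arc length is
    measured from the dorsal-ridge reference (maximum-DV surface point;
    ties resolved to the ML-median).  Arc is signed: +ML side positive.

    Returns {ap_index: (points_ml_dv μm, signed_arc μm)}.
    """
    out = {}
    s_ml, s_dv, _ = spacing
    for k in range(field.surface1_mask.shape[2]):
        pts_idx = np.argwhere(field.surface1_mask[:, :, k])
        if len(pts_idx) == 0:
            continue
        cortex_idx = np.argwhere(field.cortex_mask[:, :, k])
        centroid = cortex_idx.mean(axis=0)
        pts = pts_idx * np.array([s_ml, s_dv])
        theta = np.arctan2(
            pts_idx[:, 1] - centroid[1], pts_idx[:, 0] - centroid[0]
        )
        # place the angular branch cut away from the contour: along the
        # ray from the surface's mean through the centroid
        away = centroid - pts_idx.mean(axis=0)
        cut_angle = np.arctan2(away[1], away[0])
        order = np.argsort((theta - cut_angle) % (2.0 * np.pi))
        pts = pts[order]
        if len(pts) >= smooth_window:
            kern = np.ones(smooth_window) / smooth_window
            sm = np.column_stack(
                [
                    np.convolve(
                        np.pad(pts[:, i], smooth_window // 2, mode="edge"),
                        kern,
                        mode="valid",
                    )
                    for i in range(2)
                ]
            )
        else:
            sm = pts
        steps = np.linalg.norm(np.diff(sm, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(steps)])
        # dorsal ridge: maximum DV; ties -> ML median of the maximal set
        dv = pts[:, 1]
        top = np.flatnonzero(dv >= dv.max() - 1e-9)
        ridge = top[np.argsort(pts[top, 0])[len(top) // 2]]
        signed = arc - arc[ridge]
        # orient so the +ML side of the ridge is positive
        ml_rel = pts[:, 0] - pts[ridge, 0]
        if np.sum(signed * ml_rel) < 0:
            signed = -signed
        out[k] = (sm, signed)
    return out


def build_projection(
    field: PotentialField,
    annotation: VoxelVolume,
    step_voxels: float = 0.5,
    budget_factor: float = 10.0,
) -> FlatmapProjection:
    """Trace every cortex voxel up the potential gradient to the pial
    surface and assign flat coordinates.

    Streamlines take fixed steps of ``step_voxels`` × voxel with
    trilinearly interpolated gradients; a voxel is flagged unresolved if
    it fails to reach the surface within the step budget (10× the
    cortical depth by default).  flat_y is the AP coordinate of the hit
    point; flat_x the signed azimuth arc of the nearest surface contour
    point in the hit coronal plane.
    """
    spacing = np.asarray(annotation.spacing)
    shape = field.cortex_mask.shape
    pot = np.asarray(field.potential.data)
    filled_pot = pot.copy()
    miss = ~np.isfinite(filled_pot)
    if miss.any():
        _, nearest = ndimage.distance_transform_edt(
            miss, return_indices=True
        )
        filled_pot[miss] = filled_pot[tuple(ind[miss] for ind in nearest)]

    starts = np.argwhere(field.cortex_mask).astype(float)
    pos = starts.copy()
    n = len(pos)
    active = np.ones(n, dtype=bool)
    hit = np.full((n, 3), np.nan)

    step = step_voxels  # in voxel units (isotropic annotation expected)
    depth_extent = shape[1]  # DV span as a conservative thickness bound
    max_steps = int(budget_factor * depth_extent / step) + 10

    grad_comps = [field.gradient[..., i] for i in range(3)]
    surf1 = field.surface1_mask
    cortex = field.cortex_mask

    for _ in range(max_steps):
        if not active.any():
            break
        p = pos[active]
        vox = np.clip(np.round(p).astype(int), 0, np.asarray(shape) - 1)
        p_pot = ndimage.map_coordinates(filled_pot, p.T, order=1, mode="nearest")
        # arrival: inside a pial Dirichlet voxel, at potential ≈ 1, or
        # exited the cortex on the high-potential side (the discrete
        # pial surface is staircased; some exit columns have no
        # 6-adjacent Dirichlet voxel to land in)
        arrived = (
            surf1[tuple(vox.T)]
            | (p_pot >= 0.999)
            | (~cortex[tuple(vox.T)] & (p_pot > 0.5))
        )
        if arrived.any():
            idx = np.flatnonzero(active)[arrived]
            hit[idx] = pos[idx]
            act = active.copy()
            act[idx] = False
            active = act
            p = pos[active]
            if not active.any():
                break
        g = np.stack(
            [ndimage.map_coordinates(gc, p.T, order=1, mode="nearest")
             for gc in grad_comps],
            axis=1,
        )
        norms = np.linalg.norm(g, axis=1)
        norms[norms == 0] = 1.0
        pos[active] = p + step * g / norms[:, None]

    unresolved = int(np.isnan(hit[:, 0]).sum())
    contours = _coronal_azimuth(field, spacing)

    flat_x = np.full(shape, np.nan)
    flat_y = np.full(shape, np.nan)
    depth = np.asarray(pot).copy()
    surface_points = np.full(shape + (3,), np.nan)

    resolved = np.isfinite(hit[:, 0])
    hit_um = hit[resolved] * spacing
    vox_list = starts[resolved].astype(int)
    ap_idx = np.clip(np.round(hit[resolved][:, 2]).astype(int), 0, shape[2] - 1)
    for ap in np.unique(ap_idx):
        if ap not in contours:
            continue
        sm, signed = contours[ap]
        sel = ap_idx == ap
        pts2d = hit_um[sel][:, :2]
        d2 = (
            (pts2d[:, None, 0] - sm[None, :, 0]) ** 2
            + (pts2d[:, None, 1] - sm[None, :, 1]) ** 2
        )
        nearest = np.argmin(d2, axis=1)
        # sub-voxel arc: project the hit point onto the two contour
        # segments flanking the nearest vertex and keep the closer foot
        arc = signed[nearest].astype(float)
        best = np.sqrt(d2[np.arange(len(nearest)), nearest])
        for side in (-1, 1):
            nb = np.clip(nearest + side, 0, len(sm) - 1)
            seg = sm[nb] - sm[nearest]
            L2 = np.einsum("ij,ij->i", seg, seg)
            valid = L2 > 1e-12
            t = np.zeros(len(nb))
            t[valid] = (
                np.einsum("ij,ij->i", pts2d - sm[nearest], seg)[valid] / L2[valid]
            )
            t = np.clip(t, 0.0, 1.0)
            foot = sm[nearest] + t[:, None] * seg
            d_foot = np.linalg.norm(pts2d - foot, axis=1)
            upd = valid & (d_foot < best)
            arc[upd] = (
                signed[nearest][upd]
                + t[upd] * (signed[nb][upd] - signed[nearest][upd])
            )
            best[upd] = d_foot[upd]
        vx = vox_list[sel]
        flat_x[tuple(vx.T)] = arc
        flat_y[tuple(vx.T)] = hit_um[sel][:, 2]
        surface_points[tuple(vx.T)] = hit_um[sel]
    return FlatmapProjection(
        flat_x, flat_y, depth, surface_points, unresolved, tuple(spacing)
    )


# ---------------------------------------------------------- signal mapping

@dataclass
class FlatImage:
    """2D flattened image: values + bin edges (μm); NaN marks empty pixels."""

    values: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    reducer: str = "mean"


def project_signal(
    signal: VoxelVolume,
    proj: FlatmapProjection,
    annotation: VoxelVolume,
    layers=None,
    reducer: str = "mean",
    bin_um: float = 20.0,
) -> FlatImage:
    """Aggregate a registered 3D signal onto the flatmap.

    ``layers``: annotation labels to include (None = every mapped
    voxel).  ``reducer``: ``mean`` | ``max`` | ``sum`` applied over the
    voxels landing in each flat pixel; pixels receiving no voxels are
    NaN (missing), never zero.
    """
    if signal.shape != annotation.shape:
        raise ValueError("signal and annotation grids differ")
    mask = np.isfinite(proj.flat_x)
    if layers is not None:
        mask &= np.isin(np.asarray(annotation.data), np.atleast_1d(layers))
    xs = proj.flat_x[mask]
    ys = proj.flat_y[mask]
    vals = np.asarray(signal.data, dtype=float)[mask]
    if len(xs) == 0:
        return FlatImage(np.full((1, 1), np.nan), np.array([0, bin_um]),
                         np.array([0, bin_um]), reducer)
    x_edges = np.arange(xs.min() - bin_um, xs.max() + 2 * bin_um, bin_um)
    y_edges = np.arange(ys.min() - bin_um, ys.max() + 2 * bin_um, bin_um)
    xi = np.clip(np.digitize(xs, x_edges) - 1, 0, len(x_edges) - 2)
    yi = np.clip(np.digitize(ys, y_edges) - 1, 0, len(y_edges) - 2)
    out_shape = (len(x_edges) - 1, len(y_edges) - 1)
    if reducer == "mean":
        total = np.zeros(out_shape)
        count = np.zeros(out_shape)
        np.add.at(total, (xi, yi), vals)
        np.add.at(count, (xi, yi), 1.0)
        with np.errstate(invalid="ignore"):
            img = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    elif reducer == "sum":
        img = np.zeros(out_shape)
        np.add.at(img, (xi, yi), vals)
        count = np.zeros(out_shape)
        np.add.at(count, (xi, yi), 1.0)
        img[count == 0] = np.nan
    elif reducer == "max":
        img = np.full(out_shape, -np.inf)
        np.maximum.at(img, (xi, yi), vals)
        img[~np.isfinite(img)] = np.nan
    else:
        raise ValueError(f"unknown reducer {reducer!r}")
    return FlatImage(img, x_edges, y_edges, reducer)
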