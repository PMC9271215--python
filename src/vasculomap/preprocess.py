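"""Raw two-channel volumes → isotropic, background-subtracted binary mask.

The binarization rule marks a voxel as vessel when it passes either a
fixed global threshold (6× the non-empty-space mean) or a lower threshold
(2.4× the mean) after subtracting a circular 35th-percentile local
ranking filter, which adapts to smooth intensity gradients.

"Non-empty space" is not an imaging standard, so it is pinned down here
as: voxels whose intensity exceeds a small absolute floor, by default 1%
of the volume's 99.9th-percentile intensity — i.e. tissue, excluding the
empty space around the sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import ForegroundStats, VoxelVolume


@dataclass(frozen=True)
class BinarizeParams:
    """Thresholds and filter geometry for vessel binarization."""

    fixed_factor: float = 6.0        # condition (a): vol ≥ factor × mean
    ranked_factor: float = 2.4       # condition (b): vol − rank ≥ factor × mean
    rank_percentile: float = 35.0
    rank_radius_um: float = 20.0     # circular in-plane footprint radius
    floor_fraction: float = 0.01     # non-empty floor vs 99.9th percentile


def interpolate_isotropic(
    vol: VoxelVolume, target_spacing: float = 1.0, order: int = 3
) -> VoxelVolume:
    """Resample to isotropic spacing with cubic (spline) interpolation.

    The physical extent is preserved to within one voxel.  Downsampling
    (target coarser than every input axis) is allowed but flagged in the
    output's ``meta``.
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    zoom = np.asarray(vol.spacing) / float(target_spacing)
    if np.allclose(zoom, 1.0):
        return vol.like(vol.data.copy())
    out = ndimage.zoom(
        np.asarray(vol.data, dtype=float), zoom, order=order,
        mode="nearest", grid_mode=True,
    )
    meta = {}
    if np.all(zoom < 1.0):
        meta["downsampled"] = True
    return VoxelVolume(
        out, (target_spacing,) * 3, vol.axes, vol.origin, {**vol.meta, **meta}
    )


def subtract_background(signal: VoxelVolume, background: VoxelVolume) -> VoxelVolume:
    """Per-voxel channel subtraction, clamped at zero.

    Removes shared autofluorescent background; negative differences are
    non-physical and clipped.
    """
    if signal.shape != background.shape:
        raise ValueError(
            f"channel shapes differ: signal {signal.shape} vs background {background.shape}"
        )
    if not np.allclose(signal.spacing, background.spacing):
        raise ValueError(
            f"channel spacings differ: {signal.spacing} vs {background.spacing}"
        )
    diff = np.asarray(signal.data, dtype=float) - np.asarray(background.data, dtype=float)
    np.maximum(diff, 0.0, out=diff)
    return signal.like(diff)


def foreground_stats(
    vol: VoxelVolume, floor_fraction: float = 0.01
) -> ForegroundStats:
    """Mean intensity over non-empty (tissue) voxels.

    The tissue mask keeps voxels above ``floor_fraction`` of the volume's
    99.9th-percentile intensity, excluding empty imaging space from the
    average that the vessel thresholds are scaled by.
    """
    data = np.asarray(vol.data, dtype=float)
    ceiling = np.percentile(data, 99.9)
    if ceiling <= 0:
        raise ValueError("volume has no positive intensities; cannot form tissue mask")
    mask = data > floor_fraction * ceiling
    if not np.any(mask):
        raise ValueError("tissue mask empty at the configured floor")
    return ForegroundStats(float(data[mask].mean()), mask)


def _circular_footprint(radius_px: float) -> np.ndarray:
    r = max(int(round(radius_px)), 1)
    yy, xx = np.mgrid[-r: r + 1, -r: r + 1]
    return (yy**2 + xx**2) <= r**2


def rank_filter_inplane(
    vol: VoxelVolume, percentile: float, radius_um: float
) -> np.ndarray:
    """Percentile filter with a circular 2D footprint per imaging plane.

    Planes are ML–DV (the original imaging plane); the filter runs
    independently on each AP slice.
    """
    data = np.asarray(vol.data, dtype=float)
    radius_px = radius_um / min(vol.spacing[0], vol.spacing[1])
    foot = _circular_footprint(radius_px)
    out = np.empty_like(data)
    for k in range(data.shape[2]):
        out[:, :, k] = ndimage.percentile_filter(
            data[:, :, k], percentile, footprint=foot, mode="nearest"
        )
    return out


def binarize_vessels(
    vol: VoxelVolume,
    stats: ForegroundStats | None = None,
    params: BinarizeParams = BinarizeParams(),
) -> VoxelVolume:
    """Two-condition vessel binarization (fixed OR rank-filtered threshold).

    mask = (vol ≥ 6·m) OR (vol − rank35(vol) ≥ 2.4·m), with m the
    non-empty-space mean.  Monotone in intensity: raising a voxel's value
    never removes it from the mask.
    """
    if stats is None:
        stats = foreground_stats(vol, params.floor_fraction)
    m = stats.nonempty_mean
    if m <= 0:
        raise ValueError("non-empty mean is zero; empty or invalid input")
    data = np.asarray(vol.data, dtype=float)
    cond_a = data >= params.fixed_factor * m
    ranked = rank_filter_inplane(vol, params.rank_percentile, params.rank_radius_um)
    cond_b = (data - ranked) >= params.ranked_factor * m
    return vol.like(cond_a | cond_b)
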