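"""3D image volumes with physical voxel spacing.

All geometry in this package is expressed in micrometres (μm).  A
:class:`VoxelVolume` couples a scalar array with per-axis spacing and
semantic axis labels.  The convention throughout is axis order
``(ML, DV, AP)``: medial-lateral, dorsal-ventral (depth, dorsal = larger
index), anterior-posterior.  Voxel centre of index ``i`` along an axis
sits at ``origin + i * spacing`` μm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical axis labels, in storage order.
DEFAULT_AXES = ("ML", "DV", "AP")


@dataclass
class VoxelVolume:
    """A 3D scalar image with physical spacing.

    Parameters
    ----------
    data : ndarray
        3D array of intensities or integer labels.
    spacing : tuple of float
        Voxel pitch per axis in μm; must be positive.
    axes : tuple of str
        Semantic labels, a permutation of ``("ML", "DV", "AP")``.
    origin : tuple of float
        μm offset of voxel ``(0, 0, 0)``'s centre.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    axes: tuple[str, str, str] = DEFAULT_AXES
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if sorted(self.axes) != sorted(DEFAULT_AXES):
            raise ValueError(
                f"axes must be a permutation of {DEFAULT_AXES}, got {self.axes}"
            )
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size in μm (number of voxels × spacing) per axis."""
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing))

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))

    def is_isotropic(self, rtol: float = 1e-6) -> bool:
        s = self.spacing
        return abs(s[0] - s[1]) <= rtol * s[0] and abs(s[0] - s[2]) <= rtol * s[0]

    def world_to_index(self, points_um: np.ndarray) -> np.ndarray:
        """Map μm coordinates to (fractional) voxel indices."""
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (fractional) voxel indices to μm coordinates of voxel centres."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def like(self, data: np.ndarray, **meta) -> "VoxelVolume":
        """New volume sharing this volume's geometry."""
        return VoxelVolume(
            data, self.spacing, self.axes, self.origin, {**self.meta, **meta}
        )


@dataclass
class ForegroundStats:
    """Summary of non-empty (tissue) intensities used by the binarizer.

    ``nonempty_mean`` is the mean intensity over the tissue mask; vessel
    thresholds are expressed as multiples of it.
    """

    nonempty_mean: float
    nonempty_mask: np.ndarray

    def __post_init__(self) -> None:
        if not np.any(self.nonempty_mask):
            raise ValueError("non-empty mask is empty: no tissue in volume")
        if self.nonempty_mean <= 0:
            raise ValueError("non-empty mean must be positive")
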