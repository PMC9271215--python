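"""Candidate-based cell detection, 2D→3D count conversion, and regional
cell-density estimation.

Detection mirrors a classifier-in-the-loop design: candidate locations
are strict local intensity maxima within an 8 μm radius; around each
candidate, two patch windows are cut — 101 × 101 μm at 1 μm/px and
501 × 501 μm resampled to 201 × 201 px — each stacked with a marker
plane that is 1 at the candidate pixel and 0 elsewhere, plus an optional
low-resolution full-frame context (12 × 8 mm at 201 × 201 px).  The
classifier itself is pluggable; the bundled baseline thresholds
handcrafted contrast/size features, so a learned model can be dropped
into the same seam.

2D counts convert to 3D densities via empirical 3D/2D ratios: 1.4 for
cytoplasmic and 1.5 for nuclear labels, 2.1 for pericytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

#: published 3D/2D conversion factors by signal kind
CONVERSION_FACTORS = {"cytoplasmic": 1.4, "nuclear": 1.5, "pericyte": 2.1}

SMALL_WINDOW_UM = 101.0    # at 1 μm/px -> 101 px
LARGE_WINDOW_UM = 501.0    # resampled to 201 px (~2.49 μm/px)
LARGE_WINDOW_PX = 201
FULL_FRAME_UM = (12000.0, 8000.0)
FULL_FRAME_PX = 201


@dataclass
class CellCandidate:
    position_um: np.ndarray
    peak_intensity: float
    patch_small: np.ndarray | None = None   # (101, 101, 2): image + marker
    patch_large: np.ndarray | None = None   # (201, 201, 2)
    patch_frame: np.ndarray | None = None
    padded_fraction: float = 0.0
    score: float = 0.0
    label: str | None = None


@dataclass
class ConversionFactor:
    factor: float
    kind: str = "custom"
    per_roi_mean: float | None = None
    per_roi_sd: float | None = None
    pooled_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.factor < 1.0:
            raise ValueError("3D/2D conversion factor must be ≥ 1")


# ------------------------------------------------------------ candidates

def detect_candidates(
    image: np.ndarray,
    spacing_um: float | tuple = 1.0,
    radius_um: float = 8.0,
    floor: float | None = None,
) -> list[CellCandidate]:
    """Strict local maxima within ``radius_um`` as cell candidates.

    A voxel qualifies when it equals the maximum of its circular
    neighbourhood, is strictly above the neighbourhood minimum (no flat
    plateaus), and exceeds ``floor``.  Plateau ties resolve to the
    lexicographically smallest coordinate; output is position-sorted.
    """
    image = np.asarray(image, dtype=float)
    spacing = np.broadcast_to(np.asarray(spacing_um, dtype=float), (image.ndim,))
    rad_px = radius_um / spacing
    grids = np.meshgrid(
        *[np.arange(-int(np.ceil(r)), int(np.ceil(r)) + 1) * s
          for r, s in zip(rad_px, spacing)],
        indexing="ij",
    )
    foot = sum(g**2 for g in grids) <= radius_um**2
    mx = ndimage.maximum_filter(image, footprint=foot, mode="nearest")
    mn = ndimage.minimum_filter(image, footprint=foot, mode="nearest")
    peaks = (image >= mx) & (image > mn)
    if floor is not None:
        peaks &= image > floor
    coords = np.argwhere(peaks)
    # lexicographic greedy de-duplication of plateau/near ties
    kept: list[np.ndarray] = []
    kept_um: list[np.ndarray] = []
    for c in coords[np.lexsort(coords.T[::-1])]:
        cu = c * spacing
        if any(np.linalg.norm(cu - k) < radius_um for k in kept_um):
            continue
        kept.append(c)
        kept_um.append(cu)
    return [
        CellCandidate(position_um=cu.astype(float), peak_intensity=float(image[tuple(c)]))
        for c, cu in zip(kept, kept_um)
    ]


def _window(image, spacing, center_um, window_um, out_px):
    """Crop a centred window, resampled to ``out_px``², zero-padded at
    borders.  Returns (patch, padded_fraction)."""
    half = window_um / 2.0
    axes_um = [
        np.linspace(c - half, c + half, out_px) for c in center_um[:2]
    ]
    coords = np.meshgrid(*[a / s for a, s in zip(axes_um, spacing[:2])], indexing="ij")
    coords = np.stack([c.ravel() for c in coords])
    patch = ndimage.map_coordinates(
        image, coords, order=1, mode="constant", cval=0.0
    ).reshape(out_px, out_px)
    inside = np.ones(coords.shape[1], dtype=bool)
    for c, nmax in zip(coords, image.shape):
        inside &= (c >= 0) & (c <= nmax - 1)
    return patch, 1.0 - inside.mean()


def extract_patches(
    image: np.ndarray,
    candidate: CellCandidate,
    spacing_um: float | tuple = 1.0,
    include_full_frame: bool = False,
) -> CellCandidate:
    """Fill the candidate's multi-resolution patch windows.

    Each window is stacked with a marker plane (1 at the candidate's
    centre pixel).  2D images only; the candidate must lie inside.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("patch extraction expects a 2D plane")
    spacing = np.broadcast_to(np.asarray(spacing_um, dtype=float), (2,))
    pos = np.asarray(candidate.position_um[:2], dtype=float)
    idx = pos / spacing
    if np.any(idx < 0) or np.any(idx > np.asarray(image.shape) - 1):
        raise ValueError(f"candidate at {pos} μm lies outside the image")

    small_px = int(SMALL_WINDOW_UM)  # 1 μm/px
    small, pad_small = _window(image, spacing, pos, SMALL_WINDOW_UM, small_px)
    large, pad_large = _window(image, spacing, pos, LARGE_WINDOW_UM, LARGE_WINDOW_PX)

    def with_marker(patch):
        marker = np.zeros_like(patch)
        marker[patch.shape[0] // 2, patch.shape[1] // 2] = 1.0
        return np.stack([patch, marker], axis=-1)

    candidate.patch_small = with_marker(small)
    candidate.patch_large = with_marker(large)
    candidate.padded_fraction = max(pad_small, pad_large)
    if include_full_frame:
        frame = np.asarray(
            ndimage.zoom(
                image,
                [FULL_FRAME_PX / s for s in image.shape],
                order=1,
            )
        )[:FULL_FRAME_PX, :FULL_FRAME_PX]
        marker = np.zeros_like(frame)
        fi = np.clip(
            (idx / np.asarray(image.shape) * FULL_FRAME_PX).astype(int),
            0, FULL_FRAME_PX - 1,
        )
        marker[tuple(fi)] = 1.0
        candidate.patch_frame = np.stack([frame, marker], axis=-1)
    return candidate


# ------------------------------------------------------------- classifiers

def baseline_blob_classifier(
    min_contrast: float = 50.0,
    min_size_px: int = 3,
    max_size_px: int = 2000,
    positive_label: str = "cell",
    negative_label: str = "other",
):
    """Handcrafted-feature classifier: peak contrast over the local
    background plus a half-max blob-size gate on the small window."""

    def classify(candidate: CellCandidate) -> str:
        patch = candidate.patch_small[..., 0]
        c = patch.shape[0] // 2
        background = float(np.median(np.concatenate([
            patch[0, :], patch[-1, :], patch[:, 0], patch[:, -1]
        ])))
        peak = float(patch[c, c])
        contrast = peak - background
        if contrast < min_contrast:
            return negative_label
        core = patch[c - 15: c + 16, c - 15: c + 16]
        size = int((core > background + contrast / 2.0).sum())
        return positive_label if min_size_px <= size <= max_size_px else negative_label

    return classify


def classify_candidates(
    candidates: list[CellCandidate],
    classifier,
    class_set: tuple[str, ...] = ("cell", "other"),
    keep: tuple[str, ...] | None = None,
) -> list[CellCandidate]:
    """Apply a pluggable classifier; return candidates labelled in ``keep``
    (default: everything except the last class, treated as reject)."""
    if keep is None:
        keep = tuple(class_set[:-1])
    out = []
    for cand in candidates:
        label = classifier(cand)
        if label not in class_set:
            raise ValueError(f"classifier returned {label!r}, not in {class_set}")
        cand.label = label
        if label in keep:
            out.append(cand)
    return out


# ----------------------------------------------------- conversion & density

def estimate_conversion_factor(
    count_2d: int,
    count_3d: int,
    per_roi_pairs=None,
    kind: str = "custom",
) -> ConversionFactor:
    """3D/2D conversion factor from paired manual counts.

    The pooled factor is total_3d / total_2d rounded to one decimal;
    with per-ROI (count_2d, count_3d) pairs, the mean ± SD of per-ROI
    ratios is reported alongside.
    """
    if count_2d <= 0:
        raise ValueError("2D count must be positive")
    pooled = count_3d / count_2d
    factor = round(pooled, 1)
    mean = sd = None
    if per_roi_pairs is not None:
        ratios = np.array([c3 / c2 for c2, c3 in per_roi_pairs], dtype=float)
        mean = float(ratios.mean())
        sd = float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0
    return ConversionFactor(factor, kind, mean, sd, pooled_ratio=pooled)


def compute_density(
    count_2d_by_region: dict[int, float],
    factor: ConversionFactor | float,
    region_volumes_mm3: dict[int, float],
) -> pd.DataFrame:
    """3D cell density per region: (2D count × factor) / region volume."""
    f = factor.factor if isinstance(factor, ConversionFactor) else float(factor)
    rows = []
    for region, count in sorted(count_2d_by_region.items()):
        if region not in region_volumes_mm3:
            raise KeyError(f"missing volume for region {region}")
        vol = region_volumes_mm3[region]
        if vol <= 0:
            raise ValueError(f"non-positive volume for region {region}")
        rows.append(
            dict(
                region_id=region,
                count_2d=count,
                count_3d_estimate=count * f,
                volume_mm3=vol,
                density_per_mm3=count * f / vol,
            )
        )
    return pd.DataFrame(rows).set_index("region_id")


# --------------------------------------------------------------- evaluation

@dataclass(frozen=True)
class DetectionScore:
    precision: float
    recall: float
    f1: float
    n_matched: int


def evaluate_detection(
    detections: np.ndarray,
    truth: np.ndarray,
    match_radius_um: float = 8.0,
) -> DetectionScore:
    """Greedy one-to-one nearest matching within a radius → P/R/F1."""
    det = np.asarray(detections, dtype=float).reshape(-1, 3)
    tru = np.asarray(truth, dtype=float).reshape(-1, 3)
    if len(det) == 0 or len(tru) == 0:
        f1 = 1.0 if len(det) == len(tru) == 0 else 0.0
        return DetectionScore(
            1.0 if len(det) == 0 else 0.0, 1.0 if len(tru) == 0 else 0.0, f1, 0
        )
    d = np.linalg.norm(det[:, None, :] - tru[None, :, :], axis=2)
    pairs = np.argwhere(d <= match_radius_um)
    order = np.argsort(d[tuple(pairs.T)], kind="stable")
    used_d: set[int] = set()
    used_t: set[int] = set()
    matched = 0
    for pi in order:
        i, j = pairs[pi]
        if i in used_d or j in used_t:
            continue
        used_d.add(int(i))
        used_t.add(int(j))
        matched += 1
    precision = matched / len(det)
    recall = matched / len(tru)
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return DetectionScore(precision, recall, f1, matched)
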