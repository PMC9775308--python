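"""Plane-wise preprocessing and segmentation primitives.

These are the shared stages of the epidermal and adipose pipelines: per-plane
median filtering, linear intensity rescaling, rolling-ball background
subtraction, hysteresis thresholding, and disk-based morphological cleanup.
All spatial filters operate strictly within XY planes (no cross-plane mixing)
because the axial step is ~4x coarser than the lateral sampling; edges are
handled by reflection so tile borders do not acquire dark rims.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk
from skimage.restoration import rolling_ball

from .grids import BinaryVolume, VoxelGrid

#: 26-connectivity structuring element for 3D component linking
FULL_CONNECTIVITY = np.ones((3, 3, 3), dtype=bool)


@dataclass
class FilterParams:
    """Tunable parameters of the plane-wise segmentation chain.

    Defaults are implementation choices (the processing chain is fixed, the
    numeric radii and thresholds are configurable); thresholds are fractions
    of the per-volume maximum after rescaling.
    """

    median_radius_px: int = 1
    rolling_ball_radius_px: int = 50
    hysteresis_low: float = 0.2
    hysteresis_high: float = 0.5
    disk_radius_px: int = 4

    def __post_init__(self) -> None:
        if self.median_radius_px < 0:
            raise ValueError("median radius must be >= 0")
        if self.rolling_ball_radius_px <= 0:
            raise ValueError("rolling-ball radius must be > 0")
        if not (0 <= self.hysteresis_low < self.hysteresis_high <= 1):
            raise ValueError("need 0 <= hysteresis_low < hysteresis_high <= 1")
        if self.disk_radius_px < 0:
            raise ValueError("disk radius must be >= 0")

    @classmethod
    def from_json(cls, path: str | Path) -> "FilterParams":
        """Load the ``"filters"`` block of a JSON config file."""
        with open(path) as fh:
            cfg = json.load(fh)
        return cls(**cfg.get("filters", cfg))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"filters": asdict(self)}, fh, indent=2)


def median_filter_xy(grid: VoxelGrid, radius_px: int) -> VoxelGrid:
    """Median-filter each z-plane independently with a (2r+1)² window."""
    if radius_px < 0:
        raise ValueError("radius must be >= 0")
    if radius_px == 0:
        return grid.with_data(grid.data.copy())
    size = 2 * radius_px + 1
    out = ndi.median_filter(grid.data, size=(1, size, size), mode="mirror")
    return grid.with_data(out)


def rescale_linear(grid: VoxelGrid, low_pct: float = 0.0, high_pct: float = 100.0) -> VoxelGrid:
    """Affinely map the [low_pct, high_pct] intensity percentiles onto [0, 1].

    Values outside the percentile window are clipped.  A constant volume has
    no dynamic range to stretch; it maps to all-zero with a warning.
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    lo, hi = np.percentile(grid.data, [low_pct, high_pct])
    if hi <= lo:
        warnings.warn("degenerate volume (no intensity range); returning zeros", stacklevel=2)
        return grid.with_data(np.zeros_like(grid.data, dtype=float))
    out = np.clip((grid.data.astype(float) - lo) / (hi - lo), 0.0, 1.0)
    return grid.with_data(out)


def rolling_ball_xy(grid: VoxelGrid, radius_px: int) -> VoxelGrid:
    """Subtract a rolling-ball background estimate from each XY plane.

    The background is the surface traced by a ball of the given pixel radius
    rolled under the intensity landscape; subtracting it flattens smooth
    autofluorescence while preserving features smaller than the ball.
    The output is pointwise >= 0 and <= the input.
    """
    if radius_px <= 0:
        raise ValueError("radius must be > 0")
    if radius_px >= max(grid.shape[1], grid.shape[2]):
        raise ValueError("rolling-ball radius exceeds plane extent")
    data = grid.data.astype(float)
    out = np.empty_like(data)
    # large balls roll over fine detail anyway, so estimate the background on
    # a downsampled plane (standard rolling-ball acceleration); exact rolling
    # is kept for small radii
    shrink = max(1, radius_px // 16)
    for z in range(data.shape[0]):
        plane = data[z]
        if shrink > 1:
            small = ndi.zoom(plane, 1.0 / shrink, order=1)
            bg_small = rolling_ball(small, radius=max(1, round(radius_px / shrink)))
            background = ndi.zoom(bg_small, np.array(plane.shape) / np.array(small.shape), order=1)
            background = _match_shape_2d(background, plane.shape)
        else:
            background = rolling_ball(plane, radius=radius_px)
        # the ball never rises above the surface, but guard against rounding
        background = np.minimum(background, plane)
        out[z] = plane - background
    return grid.with_data(out)


def _match_shape_2d(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    out = arr[: shape[0], : shape[1]]
    pad = [(0, s - o) for s, o in zip(shape, out.shape)]
    if any(p != (0, 0) for p in pad):
        out = np.pad(out, pad, mode="edge")
    return out


def hysteresis_threshold(grid: VoxelGrid, low: float, high: float) -> BinaryVolume:
    """Two-threshold segmentation with 26-connected seed propagation.

    ``low`` and ``high`` are fractions of the volume maximum.  A voxel is kept
    if it is >= low*max and 26-connected (in 3D) to some voxel >= high*max,
    so weak signal survives only when attached to confident signal.
    """
    if low >= high:
        raise ValueError("low threshold must be < high threshold")
    vmax = float(grid.data.max())
    if vmax <= 0:
        return BinaryVolume(np.zeros(grid.shape, dtype=bool), grid.voxel_size)
    low_mask = grid.data >= low * vmax
    high_mask = grid.data >= high * vmax
    labels, n = ndi.label(low_mask, structure=FULL_CONNECTIVITY)
    if n == 0:
        return BinaryVolume(np.zeros(grid.shape, dtype=bool), grid.voxel_size)
    seeded = np.unique(labels[high_mask])
    keep = np.zeros(n + 1, dtype=bool)
    keep[seeded] = True
    keep[0] = False
    return BinaryVolume(keep[labels], grid.voxel_size)


def _pad_reflect_2d(plane: np.ndarray, pad: int) -> np.ndarray:
    return np.pad(plane, pad, mode="reflect")


def morph_close_open(mask: BinaryVolume, disk_radius_px: int) -> BinaryVolume:
    """Plane-wise morphological closing then opening with a 2D disk.

    Closing bridges gaps smaller than the disk; opening then removes isolated
    specks smaller than the disk.  Planes are reflect-padded before the
    operations so a solid slab is not eroded at tile borders.  Radius 0 is the
    identity.
    """
    if disk_radius_px < 0:
        raise ValueError("radius must be >= 0")
    if disk_radius_px == 0:
        return BinaryVolume(mask.mask.copy(), mask.voxel_size)
    footprint = disk(disk_radius_px)
    # border effects of the compound ops reach 2r into the padding
    pad = 2 * disk_radius_px + 2
    out = np.empty_like(mask.mask)
    for z in range(mask.shape[0]):
        plane = _pad_reflect_2d(mask.mask[z], pad)
        plane = ndi.binary_closing(plane, structure=footprint)
        plane = ndi.binary_opening(plane, structure=footprint)
        out[z] = plane[pad:-pad, pad:-pad]
    return BinaryVolume(out, mask.voxel_size)


def volume_fraction(mask: BinaryVolume) -> float:
    """Fraction of voxels occupied by the segmented structure."""
    if mask.mask.size == 0:
        raise ValueError("zero-size volume")
    return float(np.count_nonzero(mask.mask)) / mask.mask.size
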