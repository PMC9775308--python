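"""Epidermal segmentation, volumetric thickness, and suprabasal marker intensity.

The epidermis presents as a contiguous bright slab at the top of the construct
in the nuclear, cytokeratin-10 and involucrin channels.  Each channel runs
through the shared plane-wise chain (median filter, linear rescale,
rolling-ball background subtraction); the channels are fused by voxelwise
maximum, hysteresis-thresholded, and morphologically cleaned.  Thickness is
read per XY column from the top/bottom extent of the binary volume and scaled
by the axial voxel size, giving a volumetric thickness map rather than a
single cross-section.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filters import (
    FilterParams,
    hysteresis_threshold,
    median_filter_xy,
    morph_close_open,
    rescale_linear,
    rolling_ball_xy,
)
from .grids import BinaryVolume, VoxelGrid


@dataclass
class ThicknessMap:
    """Per-XY-column layer thickness in µm with a validity mask.

    ``valid`` marks columns that contain any of the layer; columns without
    signal are excluded from all summaries.
    """

    thickness_um: np.ndarray
    valid: np.ndarray
    dz_um: float

    def __post_init__(self) -> None:
        self.thickness_um = np.asarray(self.thickness_um, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.thickness_um.shape != self.valid.shape:
            raise ValueError("thickness and validity maps must share shape")

    def valid_values(self) -> np.ndarray:
        return self.thickness_um[self.valid]


@dataclass
class EpidermisResult:
    """Pooled epidermal summaries across analysis sub-volumes."""

    median_thickness_um: float
    mean_thickness_um: float
    marker_mean_intensity: dict = field(default_factory=dict)
    n_subvolumes: int = 1


#: over-subtraction guard: the fraction of the confident-foreground voxels
#: (those at or above the hysteresis seed level) that must survive background
#: subtraction for the subtraction to be accepted
OVERSUBTRACTION_GUARD = 0.5


def preprocess_channel(grid: VoxelGrid, params: FilterParams) -> VoxelGrid:
    """Median filter, linear rescale and rolling-ball correct one channel.

    The rolling-ball step is guarded against over-subtraction.  A ball
    narrower than the structure of interest tracks the structure itself and
    subtracts it as "background" — a stained layer spanning a whole plane at
    near-uniform brightness would vanish entirely.  The guard compares the
    confident foreground (voxels >= the hysteresis seed fraction of the
    maximum) before and after subtraction: if fewer than half of those voxels
    survive, the ball radius is judged mismatched to the scene and the
    unsubtracted (rescaled) channel is used instead.
    """
    g = median_filter_xy(grid, params.median_radius_px)
    g = rescale_linear(g)
    # a ball must fit inside the plane; clamp for small tiles
    radius = min(params.rolling_ball_radius_px, min(grid.shape[1], grid.shape[2]) // 2)
    sub = rolling_ball_xy(g, max(radius, 1))
    seed_before = g.data >= params.hysteresis_high * g.data.max() if g.data.max() > 0 else None
    if seed_before is not None and seed_before.any():
        if sub.data.max() <= 0:  # subtraction removed everything
            return g
        survived = sub.data[seed_before] >= params.hysteresis_high * sub.data.max()
        if survived.mean() < OVERSUBTRACTION_GUARD:
            return g
    return sub


def segment_epidermis(
    nuclei: VoxelGrid,
    k10: VoxelGrid,
    involucrin: VoxelGrid,
    params: FilterParams | None = None,
) -> BinaryVolume:
    """Segment the epidermal slab from its three marker channels.

    The three stains jointly localize the epidermis (nuclei everywhere in the
    living layers, cytokeratin 10 suprabasally, involucrin in the cornified
    layer); they are fused by voxelwise maximum of the preprocessed channels
    so the union of the marker domains is segmented.
    """
    params = params or FilterParams()
    if not (nuclei.shape == k10.shape == involucrin.shape):
        raise ValueError("channel shapes differ")
    if not (nuclei.voxel_size == k10.voxel_size == involucrin.voxel_size):
        raise ValueError("channel voxel sizes differ")
    fused = np.maximum.reduce(
        [preprocess_channel(g, params).data for g in (nuclei, k10, involucrin)]
    )
    fused_grid = VoxelGrid(fused, nuclei.voxel_size, "epidermis-fused")
    mask = hysteresis_threshold(fused_grid, params.hysteresis_low, params.hysteresis_high)
    return morph_close_open(mask, params.disk_radius_px)


def thickness_map(mask: BinaryVolume) -> ThicknessMap:
    """Per-column layer thickness from the outermost z-extents of a mask.

    For each (y, x) column containing signal the thickness is
    ``(z_top - z_bottom + 1) * dz`` — the voxel-count convention, so a layer
    one plane thick reads one z-step, not zero.  Columns with internal gaps
    use the outermost extents (gaps are expected to have been closed by the
    morphological cleanup).
    """
    m = mask.mask
    dz = mask.voxel_size[0]
    any_col = m.any(axis=0)
    nz = m.shape[0]
    bottom = np.argmax(m, axis=0)
    top = nz - 1 - np.argmax(m[::-1], axis=0)
    thickness = np.where(any_col, (top - bottom + 1) * dz, 0.0)
    return ThicknessMap(thickness, any_col, dz)


def summarize_thickness(
    maps: list[ThicknessMap],
    marker_mean_intensity: dict | None = None,
    per_tile: bool = False,
) -> EpidermisResult:
    """Pool valid-column thicknesses across sub-volumes into one summary.

    By default all valid columns are pooled before taking the mean/median;
    with ``per_tile=True`` each map is averaged first and the summaries are
    taken over the per-tile means.
    """
    if not maps:
        raise ValueError("need at least one thickness map")
    if per_tile:
        values = np.array([m.valid_values().mean() for m in maps if m.valid.any()])
    else:
        pools = [m.valid_values() for m in maps]
        values = np.concatenate(pools) if pools else np.array([])
    if values.size == 0:
        raise ValueError("no valid columns in any map")
    return EpidermisResult(
        median_thickness_um=float(np.median(values)),
        mean_thickness_um=float(np.mean(values)),
        marker_mean_intensity=marker_mean_intensity or {},
        n_subvolumes=len(maps),
    )


def marker_intensity(grids: list[VoxelGrid]) -> float:
    """Mean pixel intensity of pooled z-maximum projections.

    Each volume is max-projected along z; the projections are pooled and the
    mean pixel value returned.  Computed on the whole unsegmented field, with
    no background subtraction, as a simple per-sample expression readout.
    """
    if not grids:
        raise ValueError("need at least one volume")
    projections = [g.data.max(axis=0).ravel() for g in grids]
    return float(np.concatenate(projections).mean())
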