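"""Voxel-grid containers and TIFF stack I/O.

Confocal volumes are carried as :class:`VoxelGrid` (a 3D intensity array in
``(z, y, x)`` order with physical voxel dimensions in µm) and segmentations as
:class:`BinaryVolume` (a boolean mask aligned to its source grid).  Voxels are
typically anisotropic — the default acquisition geometry is 0.7 × 0.7 µm
laterally and 3 µm axially — so every downstream physical measurement carries
the voxel size along with the array.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

#: default (dz, dy, dx) in µm for the confocal acquisition geometry
DEFAULT_VOXEL_SIZE = (3.0, 0.7, 0.7)


@dataclass
class VoxelGrid:
    """A 3D scalar intensity volume with physical voxel dimensions.

    Parameters
    ----------
    data : ndarray
        Non-negative intensities, shape ``(nz, ny, nx)``.
    voxel_size : tuple of float
        ``(dz, dy, dx)`` in µm; all entries must be positive.
    channel : str
        Free-text channel label (e.g. ``"nuclei"``, ``"collagen-iv"``).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be three positive values, got {self.voxel_size}")
        self.voxel_size = vs
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, channel: str | None = None) -> "VoxelGrid":
        """A new grid sharing this grid's geometry but carrying new voxel data."""
        return VoxelGrid(data, self.voxel_size, self.channel if channel is None else channel)

    def physical_extent(self) -> tuple[float, float, float]:
        """(z, y, x) extent in µm."""
        return tuple(n * v for n, v in zip(self.data.shape, self.voxel_size))


@dataclass
class BinaryVolume:
    """A boolean mask geometrically aligned to a :class:`VoxelGrid`."""

    mask: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {self.mask.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape


def read_stack(
    path: str | Path,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    channel: str = "",
) -> VoxelGrid:
    """Read a single- or multi-page grayscale TIFF stack as a VoxelGrid.

    Pages map to z-planes.  RGB / multi-sample TIFFs are rejected: each
    fluorescence channel must be its own grayscale stack.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected grayscale pages, got array of shape {data.shape}")
    if data.shape[-1] in (3, 4) and data.ndim == 3 and data.shape[0] > 8 and data.shape[-1] < 8:
        # heuristic guard: a (r, c, 3/4) array is an RGB page, not a 3/4-plane stack
        raise ValueError(f"{path}: RGB/multi-sample TIFF not supported; provide one grayscale stack per channel")
    if data.size == 0:
        raise ValueError(f"{path}: zero-size image")
    return VoxelGrid(data, voxel_size, channel)


def write_stack(path: str | Path, grid: VoxelGrid | BinaryVolume) -> None:
    """Write a grid as a multi-page TIFF; masks are written as 8-bit 0/255."""
    if isinstance(grid, BinaryVolume):
        data = grid.mask.astype(np.uint8) * 255
    else:
        data = grid.data
    tifffile.imwrite(Path(path), data, photometric="minisblack")


def extract_subvolumes(
    grid: VoxelGrid, count: int, xy_size: tuple[float, float]
) -> list[VoxelGrid]:
    """Cut ``count`` non-overlapping analysis tiles of a physical XY size.

    Tiles keep the full z-depth, are laid contiguously along x and centred in
    the grid, mirroring how adjacent confocal sub-volumes tile a strip across
    the specimen centre.  ``xy_size`` is ``(y, x)`` in µm.

    Each returned tile records its origin (z0, y0, x0) voxel offset in
    ``tile.origin`` for reporting.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    _, dy, dx = grid.voxel_size
    ny_tile = int(round(xy_size[0] / dy))
    nx_tile = int(round(xy_size[1] / dx))
    if ny_tile < 1 or nx_tile < 1:
        raise ValueError("tile size smaller than one voxel")
    nz, ny, nx = grid.shape
    total_x = nx_tile * count
    if ny_tile > ny or total_x > nx:
        raise ValueError(
            f"requested tiling {count} x ({ny_tile} x {nx_tile}) voxels exceeds grid extent ({ny} x {nx})"
        )
    y0 = (ny - ny_tile) // 2
    x_start = (nx - total_x) // 2
    tiles = []
    for i in range(count):
        x0 = x_start + i * nx_tile
        tile = VoxelGrid(
            grid.data[:, y0 : y0 + ny_tile, x0 : x0 + nx_tile].copy(),
            grid.voxel_size,
            grid.channel,
        )
        tile.origin = (0, y0, x0)  # type: ignore[attr-defined]
        tiles.append(tile)
    return tiles
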