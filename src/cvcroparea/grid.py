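"""Regular geographic grids and radiometric unit conversions.

All rasters in this package live on a north-up, pixel-center-registered
grid: raster row 0 is the northernmost row, pixel indexing is half-open
[0, n), and a pixel's representative coordinate is its center.  No module
resamples or reprojects; inputs that do not share a grid are rejected.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SceneGrid",
    "validate_grid_alignment",
    "db_to_linear",
    "linear_to_db",
]


@dataclass(frozen=True)
class SceneGrid:
    """A north-up regular raster grid.

    Parameters
    ----------
    origin_x, origin_y:
        Map coordinates of the outer corner of the top-left pixel.
    pixel_size_x:
        Pixel width in map units (positive).
    pixel_size_y:
        Pixel height in map units; negative by the north-up convention.
    width, height:
        Raster dimensions in pixels.
    crs_id:
        Authority code string, e.g. ``"EPSG:32618"``.
    """

    origin_x: float
    origin_y: float
    pixel_size_x: float
    pixel_size_y: float
    width: int
    height: int
    crs_id: str = "EPSG:32618"

    def __post_init__(self) -> None:
        if self.pixel_size_x == 0 or self.pixel_size_y == 0:
            raise ValueError("pixel sizes must be nonzero")
        if self.width < 1 or self.height < 1:
            raise ValueError("grid dimensions must be >= 1 pixel")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates of all pixel centers as (xs, ys) 2-D arrays."""
        cols = np.arange(self.width) + 0.5
        rows = np.arange(self.height) + 0.5
        xs = self.origin_x + cols * self.pixel_size_x
        ys = self.origin_y + rows * self.pixel_size_y
        return np.meshgrid(xs, ys)

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        x2 = self.origin_x + self.width * self.pixel_size_x
        y2 = self.origin_y + self.height * self.pixel_size_y
        return (
            min(self.origin_x, x2),
            min(self.origin_y, y2),
            max(self.origin_x, x2),
            max(self.origin_y, y2),
        )


def validate_grid_alignment(grids: list[SceneGrid], tolerance: float = 1e-6) -> bool:
    """True iff all grids are mutually co-registered.

    Grids align when they share the CRS, dimensions, pixel sizes and origin
    (origins and sizes compared within ``tolerance`` map units).  Callers
    must refuse misaligned inputs; nothing in this package resamples.
    """
    if len(grids) < 2:
        raise ValueError("need at least two grids to compare")
    ref = grids[0]
    for g in grids[1:]:
        if g.crs_id != ref.crs_id:
            return False
        if (g.width, g.height) != (ref.width, ref.height):
            return False
        if abs(g.pixel_size_x - ref.pixel_size_x) > tolerance:
            return False
        if abs(g.pixel_size_y - ref.pixel_size_y) > tolerance:
            return False
        if abs(g.origin_x - ref.origin_x) > tolerance:
            return False
        if abs(g.origin_y - ref.origin_y) > tolerance:
            return False
    return True


def db_to_linear(x_db):
    """Convert backscatter from decibels to linear power units."""
    return np.power(10.0, np.asarray(x_db, dtype=float) / 10.0)


def linear_to_db(x):
    """Convert backscatter from linear power to decibels.

    Raises
    ------
    ValueError
        If any finite input is nonpositive (linear power must be > 0).
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr[np.isfinite(arr)] <= 0):
        raise ValueError("linear power must be positive for dB conversion")
    return 10.0 * np.log10(arr)
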