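"""In-memory containers shared across the pipeline.

Conventions
-----------
* Intensities are linear power (never dB); invalid pixels are NaN.
* Classification rasters are uint8 with values 0 (non-crop), 1 (crop)
  and ``MASK`` (255) for pixels excluded from analysis.
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon
from shapely.geometry.base import BaseGeometry

from .grid import SceneGrid

#: Integer code marking masked pixels in classification rasters.
MASK: int = 255

CATEGORIES = ("crop", "built-up", "forest")


@dataclass
class RadarStack:
    """A dated, co-registered stack of backscatter images in linear power.

    ``values`` has shape ``(n_dates, height, width)``; dates are strictly
    increasing calendar dates.  Negative finite intensities are not
    allowed — linear power is nonnegative, and invalid pixels are NaN.
    """

    grid: SceneGrid
    dates: list[_dt.date]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError("stack values must be (dates, height, width)")
        if self.values.shape != (len(self.dates), self.grid.height, self.grid.width):
            raise ValueError(
                f"stack shape {self.values.shape} does not match "
                f"{len(self.dates)} dates and grid {self.grid.shape}"
            )
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise ValueError("dates must be strictly increasing")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < 0:
            raise ValueError("linear-power intensities cannot be negative")

    @property
    def n_dates(self) -> int:
        return len(self.dates)

    def copy(self) -> "RadarStack":
        return RadarStack(self.grid, list(self.dates), self.values.copy())


@dataclass
class LandCoverRaster:
    """Categorical land-cover raster (CDL-style) with an integer legend."""

    grid: SceneGrid
    codes: np.ndarray
    legend: dict[int, str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.shape != self.grid.shape:
            raise ValueError("land-cover raster does not match its grid")
        present = set(int(c) for c in np.unique(self.codes))
        missing = present - set(int(k) for k in self.legend)
        if missing:
            raise ValueError(f"codes missing from legend: {sorted(missing)}")


@dataclass
class CVRaster:
    """Per-pixel temporal coefficient of variation CV = sigma / mu.

    ``sigma`` is the population temporal standard deviation and ``mu`` the
    temporal mean over valid dates; ``cv`` is NaN wherever ``mu <= 0`` or
    fewer than the required number of valid dates were available.
    """

    grid: SceneGrid
    cv: np.ndarray
    sigma: np.ndarray
    mu: np.ndarray
    n_valid_dates: np.ndarray

    def __post_init__(self) -> None:
        for name in ("cv", "sigma", "mu", "n_valid_dates"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} does not match grid shape")
            setattr(self, name, arr)


@dataclass
class BinaryCropMap:
    """Per-pixel crop map: 0 non-crop, 1 crop, MASK excluded."""

    grid: SceneGrid
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.shape != self.grid.shape:
            raise ValueError("label raster does not match its grid")
        bad = set(np.unique(self.labels)) - {0, 1, MASK}
        if bad:
            raise ValueError(f"labels must be 0, 1 or {MASK}; found {sorted(bad)}")

    def copy(self) -> "BinaryCropMap":
        return BinaryCropMap(self.grid, self.labels.copy())


@dataclass
class TruthPolygon:
    """A ground-truth region labeled crop, built-up or forest."""

    field_id: str
    category: str
    geometry: BaseGeometry
    area_ha: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )
        if not self.geometry.is_valid:
            raise ValueError(f"invalid geometry for polygon {self.field_id!r}")
        if not self.area_ha:
            self.area_ha = float(self.geometry.area) / 10_000.0

    @property
    def is_crop(self) -> bool:
        return self.category == "crop"


def rectangle_polygon(x0: float, y0: float, x1: float, y1: float) -> Polygon:
    """Axis-aligned rectangle as a shapely polygon."""
    return Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])
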