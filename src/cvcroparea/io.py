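"""Raster and vector I/O.

Rasters are GeoTIFFs: georeferencing travels in the standard GeoTIFF tags
(ModelPixelScale, ModelTiepoint, a minimal GeoKey directory carrying the
EPSG code) plus the GDAL nodata tag, written and read through tifffile.
Backscatter stacks are multi-band float32 (one band per date, linear
power, nodata NaN) with a ``date,band_index`` CSV sidecar; classification
rasters are single-band uint8 with nodata 255; land cover is a single
int32 band with a JSON legend sidecar.  Vector truth is GeoJSON with
``category`` and ``field_id`` properties.

Nothing here resamples or reprojects: grids must already be co-registered
(`validate_grid_alignment`), and misalignment is a hard error downstream.
"""
from __future__ import annotations

import datetime as _dt
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import mapping, shape

from .containers import MASK, BinaryCropMap, LandCoverRaster, RadarStack, TruthPolygon
from .grid import SceneGrid

__all__ = [
    "read_stack",
    "write_stack",
    "read_raster",
    "write_raster",
    "read_crop_map",
    "write_crop_map",
    "read_landcover",
    "write_landcover",
    "read_polygons",
    "write_polygons",
]

logger = logging.getLogger(__name__)

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113


def _geo_extratags(grid: SceneGrid, nodata: str):
    epsg = 0
    if grid.crs_id.upper().startswith("EPSG:"):
        epsg = int(grid.crs_id.split(":")[1])
    # minimal GeoKey directory: projected model, pixel-is-area, EPSG code
    keys = [1, 1, 0, 3, 1024, 0, 1, 1, 1025, 0, 1, 1, 3072, 0, 1, epsg]
    return [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.pixel_size_x, -grid.pixel_size_y, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0)),
        (_TAG_GEO_KEYS, "H", len(keys), tuple(keys)),
        (_TAG_GDAL_NODATA, "s", 0, nodata),
    ]


def _grid_from_page(page, width: int, height: int) -> SceneGrid:
    tags = page.tags
    scale = tags.get(_TAG_PIXEL_SCALE)
    tie = tags.get(_TAG_TIEPOINT)
    if scale is None or tie is None:
        raise ValueError("raster lacks georeferencing tags")
    sx, sy = float(scale.value[0]), float(scale.value[1])
    ox, oy = float(tie.value[3]), float(tie.value[4])
    crs_id = "EPSG:0"
    geok = tags.get(_TAG_GEO_KEYS)
    if geok is not None:
        vals = list(geok.value)
        for i in range(4, len(vals), 4):
            if vals[i] == 3072:
                crs_id = f"EPSG:{vals[i + 3]}"
    return SceneGrid(ox, oy, sx, -sy, width, height, crs_id)


def write_raster(path: str | Path, values: np.ndarray, grid: SceneGrid,
                 nodata: str = "nan") -> None:
    """Write a 2-D or (bands, h, w) array as a georeferenced TIFF."""
    values = np.asarray(values)
    tifffile.imwrite(
        path,
        values,
        photometric="minisblack",
        extratags=_geo_extratags(grid, nodata),
        metadata=None,
    )


def read_raster(path: str | Path) -> tuple[np.ndarray, SceneGrid, str | None]:
    """Read a georeferenced TIFF; returns (values, grid, nodata string)."""
    with tifffile.TiffFile(path) as tif:
        values = tif.asarray()
        page = tif.pages[0]
        height, width = page.shape[-2], page.shape[-1]
        grid = _grid_from_page(page, width, height)
        nd = page.tags.get(_TAG_GDAL_NODATA)
        nodata = None if nd is None else str(nd.value).strip("\x00")
    return values, grid, nodata


def write_stack(stack: RadarStack, stack_path: str | Path,
                dates_path: str | Path) -> None:
    """Write a backscatter stack as multi-band float32 TIFF + dates CSV."""
    write_raster(stack_path, stack.values.astype(np.float32), stack.grid, nodata="nan")
    pd.DataFrame(
        {"date": [d.isoformat() for d in stack.dates],
         "band_index": np.arange(1, stack.n_dates + 1)}
    ).to_csv(dates_path, index=False)


def read_stack(stack_path: str | Path, dates_path: str | Path) -> RadarStack:
    """Read a multi-band stack plus its dates sidecar.

    Bands are reordered so dates ascend; intensities <= 0 are coerced to
    NaN (linear power must be positive) with a logged count.
    """
    values, grid, _ = read_raster(stack_path)
    if values.ndim == 2:
        values = values[None]
    table = pd.read_csv(dates_path)
    if "date" not in table.columns:
        raise ValueError("dates sidecar must have a 'date' column")
    if len(table) != values.shape[0]:
        raise ValueError(
            f"stack has {values.shape[0]} bands but dates table has {len(table)} rows"
        )
    try:
        dates = [
            _dt.date.fromisoformat(str(d)[:10]) for d in table["date"]
        ]
    except ValueError as exc:
        raise ValueError(f"unparseable date in {dates_path}: {exc}") from exc
    if "band_index" in table.columns:
        order = np.asarray(table["band_index"], dtype=int) - 1
        values = values[order]
    idx = np.argsort(np.array(dates, dtype="datetime64[D]"), kind="stable")
    dates = [dates[i] for i in idx]
    values = np.asarray(values[idx], dtype=np.float32)

    nonpositive = np.isfinite(values) & (values <= 0)
    if nonpositive.any():
        logger.warning(
            "coerced %d nonpositive intensities to NaN", int(nonpositive.sum())
        )
        values = values.copy()
        values[nonpositive] = np.nan
    return RadarStack(grid, dates, values)


def write_crop_map(cmap: BinaryCropMap, path: str | Path) -> None:
    write_raster(path, cmap.labels.astype(np.uint8), cmap.grid, nodata=str(MASK))


def read_crop_map(path: str | Path) -> BinaryCropMap:
    values, grid, _ = read_raster(path)
    return BinaryCropMap(grid, values.astype(np.uint8))


def write_landcover(lc: LandCoverRaster, raster_path: str | Path,
                    legend_path: str | Path) -> None:
    write_raster(raster_path, lc.codes.astype(np.int32), lc.grid, nodata="-1")
    with open(legend_path, "w") as fh:
        json.dump({str(k): v for k, v in lc.legend.items()}, fh, indent=1)


def read_landcover(raster_path: str | Path, legend_path: str | Path) -> LandCoverRaster:
    values, grid, _ = read_raster(raster_path)
    with open(legend_path) as fh:
        legend = {int(k): str(v) for k, v in json.load(fh).items()}
    return LandCoverRaster(grid, values.astype(np.int64), legend)


def write_polygons(polygons: list[TruthPolygon], path: str | Path,
                   crs_id: str | None = None) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"field_id": p.field_id, "category": p.category,
                           "area_ha": p.area_ha},
            "geometry": mapping(p.geometry),
        }
        for p in polygons
    ]
    payload = {"type": "FeatureCollection", "features": features}
    if crs_id:
        payload["crs"] = {"type": "name", "properties": {"name": crs_id}}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_polygons(path: str | Path, raster_crs: str | None = None) -> list[TruthPolygon]:
    """Read truth polygons from GeoJSON.

    Every feature must carry a ``category`` in {crop, built-up, forest};
    invalid (e.g. self-intersecting) geometries are rejected.  When both
    the file and the caller provide a CRS they must match.
    """
    with open(path) as fh:
        payload = json.load(fh)
    file_crs = payload.get("crs", {}).get("properties", {}).get("name")
    if raster_crs and file_crs and file_crs != raster_crs:
        raise ValueError(f"polygon CRS {file_crs} does not match raster {raster_crs}")
    polygons = []
    for feat in payload.get("features", []):
        props = feat.get("properties", {})
        if "category" not in props:
            raise ValueError("polygon feature lacks a 'category' property")
        geom = shape(feat["geometry"])
        polygons.append(
            TruthPolygon(
                field_id=str(props.get("field_id", f"feature-{len(polygons)}")),
                category=props["category"],
                geometry=geom,
                area_ha=float(props.get("area_ha", 0.0)),
            )
        )
    return polygons
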