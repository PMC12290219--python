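"""File I/O: single-band GeoTIFF rasters, point tables, mask polygons.

Rasters are plain single-band GeoTIFFs with an axis-aligned geotransform,
written and read through :mod:`tifffile` with the standard GeoTIFF tags
(ModelPixelScale, ModelTiepoint, GeoKeyDirectory) plus the widely honored
GDAL_NODATA and GDAL_METADATA ASCII tags.  Travel-time output is float32;
+infinity does not survive most GeoTIFF consumers, so infinite and masked
cells are both written as the nodata sentinel (default -9999) while the
counts of each, and the edge model used, are recorded in GDAL_METADATA.
In memory, infinite travel time stays a true IEEE +inf.

Points come from headered CSV (default columns "x","y"; '.' decimal, no
locale inference) or point GeoJSON; mask polygons from GeoJSON (the first
Polygon/MultiPolygon feature is used).
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import shape as shapely_shape

from .errors import FormatError, PointsError, ValidationError
from .friction import FrictionSurface
from .grid import GEOGRAPHIC, PLANAR, Extent, GridSpec
from .engine import TravelTimeRaster

DEFAULT_NODATA = -9999.0

# TIFF tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_MODEL_TRANSFORMATION = 34264
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_METADATA = 42112
_TAG_GDAL_NODATA = 42113

# GeoTIFF keys
_KEY_MODEL_TYPE = 1024  # 1 = projected, 2 = geographic
_KEY_RASTER_TYPE = 1025  # 1 = PixelIsArea
_KEY_GEOGRAPHIC_TYPE = 2048  # 4326 = WGS 84


def _geokey_directory(crs_kind: str) -> tuple[int, ...]:
    keys = [(_KEY_MODEL_TYPE, 0, 1, 2 if crs_kind == GEOGRAPHIC else 1), (_KEY_RASTER_TYPE, 0, 1, 1)]
    if crs_kind == GEOGRAPHIC:
        keys.append((_KEY_GEOGRAPHIC_TYPE, 0, 1, 4326))
    header = (1, 1, 0, len(keys))
    return header + tuple(v for key in keys for v in key)


def _gdal_metadata_xml(items: dict) -> str:
    root = ET.Element("GDALMetadata")
    for name, value in items.items():
        item = ET.SubElement(root, "Item", name=str(name))
        item.text = str(value)
    return ET.tostring(root, encoding="unicode")


def _parse_gdal_metadata(text: str) -> dict:
    try:
        root = ET.fromstring(text)
    except ET.ParseError:
        return {}
    return {item.get("name"): (item.text or "") for item in root.iter("Item")}


def _write_raster(
    path: Union[str, Path],
    grid: GridSpec,
    data: np.ndarray,
    nodata: float,
    metadata: "dict | None" = None,
    dtype=np.float32,
) -> Path:
    path = Path(path)
    geokeys = _geokey_directory(grid.crs_kind)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.resolution_x, grid.resolution_y, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.extent.xmin, grid.extent.ymax, 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys),
        (_TAG_GDAL_NODATA, "s", 0, f"{nodata:g}"),
    ]
    if metadata:
        extratags.append((_TAG_GDAL_METADATA, "s", 0, _gdal_metadata_xml(metadata)))
    tifffile.imwrite(path, np.ascontiguousarray(data, dtype=dtype), extratags=extratags)
    return path


def _read_geo_tags(page: "tifffile.TiffPage", path: Path) -> tuple[GridSpec, float | None, dict]:
    tags = page.tags
    if _TAG_MODEL_TRANSFORMATION in tags:
        t = np.asarray(tags[_TAG_MODEL_TRANSFORMATION].value, dtype=float).reshape(4, 4)
        if t[0, 1] != 0.0 or t[1, 0] != 0.0:
            raise FormatError(f"{path}: rotated/sheared geotransform is not supported")
        sx, sy = t[0, 0], -t[1, 1]
        x0, y0 = t[0, 3], t[1, 3]
    elif _TAG_MODEL_PIXEL_SCALE in tags and _TAG_MODEL_TIEPOINT in tags:
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value
        tie = tags[_TAG_MODEL_TIEPOINT].value
        sx, sy = float(scale[0]), float(scale[1])
        i, j = float(tie[0]), float(tie[1])
        x0 = float(tie[3]) - i * sx
        y0 = float(tie[4]) + j * sy
    else:
        raise FormatError(f"{path}: no georeferencing (ModelPixelScale/ModelTiepoint) found")

    if _TAG_GEO_KEY_DIRECTORY not in tags:
        raise FormatError(f"{path}: no CRS (GeoKeyDirectory tag missing)")
    keys = tags[_TAG_GEO_KEY_DIRECTORY].value
    model_type = None
    for k in range(4, len(keys) - 3, 4):
        if keys[k] == _KEY_MODEL_TYPE:
            model_type = keys[k + 3]
    if model_type == 2:
        crs_kind = GEOGRAPHIC
    elif model_type == 1:
        crs_kind = PLANAR
    else:
        raise FormatError(f"{path}: unsupported or missing GTModelType in GeoKeyDirectory")

    nrow, ncol = page.shape[:2]
    grid = GridSpec(
        extent=Extent(xmin=x0, xmax=x0 + ncol * sx, ymin=y0 - nrow * sy, ymax=y0),
        resolution_x=sx,
        resolution_y=sy,
        nrow=nrow,
        ncol=ncol,
        crs_kind=crs_kind,
    )
    nodata = None
    if _TAG_GDAL_NODATA in tags:
        try:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip().strip("\x00"))
        except ValueError:
            nodata = None
    meta = {}
    if _TAG_GDAL_METADATA in tags:
        meta = _parse_gdal_metadata(str(tags[_TAG_GDAL_METADATA].value))
    return grid, nodata, meta


def read_raster(path: Union[str, Path]):
    """Low-level read: (grid, values, nodata, metadata) from a single-band GeoTIFF."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise FormatError(f"{path}: expected a single band, found {len(tif.pages)} pages")
        page = tif.pages[0]
        if getattr(page, "samplesperpixel", 1) != 1:
            raise FormatError(
                f"{path}: expected a single band, found {page.samplesperpixel} samples per pixel"
            )
        grid, nodata, meta = _read_geo_tags(page, path)
        values = page.asarray()
    return grid, np.asarray(values), nodata, meta


def read_friction_raster(path: Union[str, Path]) -> FrictionSurface:
    """Read a friction surface from a single-band GeoTIFF.

    Cells equal to the file's nodata sentinel, and any non-finite cells,
    become the nodata mask.  Remaining values are validated strictly
    positive (a zero-friction cell would mean infinite speed and is
    treated as data corruption).
    """
    grid, values, nodata, _ = read_raster(path)
    values = values.astype(float)
    mask = ~np.isfinite(values)
    if nodata is not None:
        mask |= values == nodata
    try:
        return FrictionSurface(grid=grid, values=values, nodata_mask=mask)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_friction_raster(
    surface: FrictionSurface,
    path: Union[str, Path],
    nodata: float = DEFAULT_NODATA,
) -> Path:
    """Write a friction surface as a float64 GeoTIFF (native precision)."""
    data = np.where(surface.nodata_mask, nodata, surface.values)
    return _write_raster(path, surface.grid, data, nodata, dtype=np.float64)


def write_travel_time(
    raster: TravelTimeRaster,
    path: Union[str, Path],
    nodata: float = DEFAULT_NODATA,
) -> Path:
    """Write a travel-time raster as float32 GeoTIFF.

    Infinite (unreachable) and masked cells are both encoded as the nodata
    sentinel; their separate counts and the edge model used are recorded
    in the GDAL_METADATA tag so the distinction is recoverable.
    """
    minutes = raster.minutes
    inf_cells = np.isinf(minutes) & ~raster.nodata_mask
    data = np.where(raster.nodata_mask | inf_cells, nodata, minutes)
    metadata = {
        "infinite_cells": int(inf_cells.sum()),
        "masked_cells": int(raster.nodata_mask.sum()),
        "averaging": raster.model.averaging,
        "distance_mode": raster.model.resolve_distance_mode(raster.grid),
        "units": "minutes",
    }
    return _write_raster(path, raster.grid, data, nodata, metadata, dtype=np.float32)


def read_travel_time(path: Union[str, Path]) -> tuple[TravelTimeRaster, dict]:
    """Read a travel-time GeoTIFF written by :func:`write_travel_time`.

    Nodata cells are restored as NaN/nodata; the file metadata (with the
    infinite/masked counts) is returned alongside, since the sentinel
    conflates the two on disk.
    """
    grid, values, nodata, meta = read_raster(path)
    values = values.astype(float)
    mask = ~np.isfinite(values)
    if nodata is not None:
        mask |= values == nodata
    minutes = np.where(mask, np.nan, values)
    raster = TravelTimeRaster(grid=grid, minutes=minutes, nodata_mask=mask)
    return raster, meta


# --- points ------------------------------------------------------------------


def read_points(
    path: Union[str, Path],
    x_col: str = "x",
    y_col: str = "y",
) -> pd.DataFrame:
    """Read point locations from a headered CSV or a point GeoJSON.

    Returns a DataFrame with columns ``x`` and ``y`` in file order; every
    coordinate must be present, numeric and finite.
    """
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        return _read_points_geojson(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise PointsError(f"{path}: file is empty") from None
    if df.empty:
        raise PointsError(f"{path}: no data rows")
    for col in (x_col, y_col):
        if col not in df.columns:
            raise PointsError(
                f"{path}: missing column {col!r}; available columns: {list(df.columns)}"
            )
    out = pd.DataFrame(
        {
            "x": pd.to_numeric(df[x_col], errors="coerce"),
            "y": pd.to_numeric(df[y_col], errors="coerce"),
        }
    )
    bad = ~np.isfinite(out["x"]) | ~np.isfinite(out["y"])
    if bad.any():
        first = int(np.flatnonzero(bad)[0])
        raise PointsError(
            f"{path}: non-numeric or missing coordinate at data row {first + 1} "
            f"(x={df[x_col].iloc[first]!r}, y={df[y_col].iloc[first]!r})"
        )
    return out.reset_index(drop=True)


def _read_points_geojson(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise PointsError(f"{path}: invalid GeoJSON ({exc})") from None
    coords: list[tuple[float, float]] = []
    for geom in _iter_geometries(obj):
        if geom.get("type") == "Point":
            x, y = geom["coordinates"][:2]
            coords.append((float(x), float(y)))
        elif geom.get("type") == "MultiPoint":
            coords.extend((float(x), float(y)) for x, y in geom["coordinates"])
    if not coords:
        raise PointsError(f"{path}: no Point features found")
    return pd.DataFrame(coords, columns=["x", "y"])


def _iter_geometries(obj: dict):
    t = obj.get("type")
    if t == "FeatureCollection":
        for feature in obj.get("features", []):
            if feature.get("geometry"):
                yield feature["geometry"]
    elif t == "Feature":
        if obj.get("geometry"):
            yield obj["geometry"]
    elif t is not None:
        yield obj


def write_points(points, path: Union[str, Path]) -> Path:
    """Write (x, y) points to CSV with an ``x,y`` header."""
    df = pd.DataFrame(np.asarray(points, dtype=float), columns=["x", "y"])
    df.to_csv(path, index=False)
    return Path(path)


def read_polygon(path: Union[str, Path]) -> shapely.Geometry:
    """Read the first Polygon/MultiPolygon feature from a GeoJSON file."""
    path = Path(path)
    with open(path) as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid GeoJSON ({exc})") from None
    for geom in _iter_geometries(obj):
        if geom.get("type") in ("Polygon", "MultiPolygon"):
            return shapely_shape(geom)
    raise FormatError(f"{path}: no Polygon or MultiPolygon feature found")
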