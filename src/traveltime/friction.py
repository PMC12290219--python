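"""Friction-surface preparation.

A friction surface assigns each raster cell a traversal cost in minutes per
meter (the reciprocal of speed); higher friction means slower movement.
This module prepares such a surface for an area of interest: accept either
a named global surface (fetched through a pluggable adapter and snapped to
the 30-arc-second lattice) or a user-supplied raster (cropped to the area
of interest, never resampled), and optionally mask cells outside a land or
study-area polygon so they become impassable.

A synthetic generator (:func:`synth_friction`) provides deterministic test
surfaces, including a two-component "corridor with barrier" layout used to
exercise the infinite-travel-time contract for disconnected areas.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol, Union

import numpy as np
import shapely
from shapely.geometry import box

from .errors import FetchError, OfflineError, ValidationError
from .grid import (
    GEOGRAPHIC,
    RES_30_ARCSEC,
    Extent,
    GridSpec,
    snap_extent,
)

#: The named 2020 global surfaces: walking-only and motorised travel.
SURFACE_NAMES = ("walk2020", "motor2020")

#: Friction above this (minutes per meter) almost certainly indicates a
#: unit mistake (e.g. minutes per km); we warn but do not convert.
_PLAUSIBLE_MAX_FRICTION = 10.0


@dataclass
class FrictionSurface:
    """A grid plus per-cell friction in minutes per meter.

    ``nodata_mask`` is True where the cell is impassable or absent; the
    mask is authoritative — values under masked cells carry no meaning and
    are stored as NaN.  Every unmasked value must be finite and strictly
    positive.
    """

    grid: GridSpec
    values: np.ndarray
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValidationError(
                f"friction array shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.grid.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.grid.shape:
            raise ValidationError(
                f"nodata mask shape {self.nodata_mask.shape} does not match grid {self.grid.shape}"
            )
        unmasked = self.values[~self.nodata_mask]
        n_nonfinite = int(np.sum(~np.isfinite(unmasked)))
        n_nonpositive = int(np.sum(unmasked[np.isfinite(unmasked)] <= 0))
        if n_nonfinite or n_nonpositive:
            raise ValidationError(
                "friction values must be finite and strictly positive on unmasked cells: "
                f"{n_nonfinite} non-finite, {n_nonpositive} non-positive"
            )
        if unmasked.size and float(np.max(unmasked)) > _PLAUSIBLE_MAX_FRICTION:
            warnings.warn(
                f"friction values up to {np.max(unmasked):g} min/m exceed {_PLAUSIBLE_MAX_FRICTION}; "
                "check the units are minutes per meter",
                stacklevel=2,
            )
        # masked cells carry no value semantics
        self.values = np.where(self.nodata_mask, np.nan, self.values)

    @property
    def n_unmasked(self) -> int:
        return int(np.sum(~self.nodata_mask))

    def copy(self) -> "FrictionSurface":
        return FrictionSurface(self.grid, self.values.copy(), self.nodata_mask.copy())


class FetchAdapter(Protocol):
    """Seam for retrieving a named global surface over a snapped grid.

    Implementations may hit a remote server; tests supply in-memory
    adapters so everything runs offline.
    """

    def fetch(self, name: str, grid: GridSpec) -> FrictionSurface: ...


class CallableFetcher:
    """Adapt a plain callable ``(name, grid) -> FrictionSurface``."""

    def __init__(self, fn: Callable[[str, GridSpec], FrictionSurface]):
        self._fn = fn

    def fetch(self, name: str, grid: GridSpec) -> FrictionSurface:
        return self._fn(name, grid)


class CachedFetcher:
    """Disk cache around another adapter, keyed by (name, snapped extent).

    A repeated request for the same name and extent is served from the
    cached GeoTIFF, byte-identical to the first.
    """

    def __init__(self, adapter: FetchAdapter, cache_dir: Union[str, Path]):
        self.adapter = adapter
        self.cache_dir = Path(cache_dir)
        self.cache_dir.mkdir(parents=True, exist_ok=True)

    def cache_path(self, name: str, grid: GridSpec) -> Path:
        e = grid.extent
        key = f"{name}_{e.xmin:.10f}_{e.xmax:.10f}_{e.ymin:.10f}_{e.ymax:.10f}_{grid.nrow}_{grid.ncol}"
        digest = hashlib.sha1(key.encode()).hexdigest()[:16]
        return self.cache_dir / f"{name}_{digest}.tif"

    def fetch(self, name: str, grid: GridSpec) -> FrictionSurface:
        from .io import read_friction_raster, write_friction_raster

        path = self.cache_path(name, grid)
        if not path.exists():
            surface = self.adapter.fetch(name, grid)
            write_friction_raster(surface, path)
        return read_friction_raster(path)


def _as_extent(aoi) -> Extent:
    if isinstance(aoi, Extent):
        return aoi
    if isinstance(aoi, shapely.Geometry):
        minx, miny, maxx, maxy = aoi.bounds
        return Extent(xmin=minx, xmax=maxx, ymin=miny, ymax=maxy)
    if isinstance(aoi, (tuple, list)) and len(aoi) == 4:
        return Extent(*aoi)
    raise ValidationError(f"cannot interpret area of interest of type {type(aoi).__name__}")


def crop_surface(surface: FrictionSurface, aoi) -> FrictionSurface:
    """Crop a surface to the cell range covering the area of interest.

    No resampling: the output grid is a sub-block of the input grid and
    every output value equals the corresponding input value.  Cells that
    intersect the AOI bounding box at all are retained.
    """
    ext = _as_extent(aoi)
    g = surface.grid
    eps = 1e-9
    col0 = int(math.floor((ext.xmin - g.extent.xmin) / g.resolution_x + eps))
    col1 = int(math.ceil((ext.xmax - g.extent.xmin) / g.resolution_x - eps))
    row0 = int(math.floor((g.extent.ymax - ext.ymax) / g.resolution_y + eps))
    row1 = int(math.ceil((g.extent.ymax - ext.ymin) / g.resolution_y - eps))
    col0, col1 = max(col0, 0), min(col1, g.ncol)
    row0, row1 = max(row0, 0), min(row1, g.nrow)
    if col0 >= col1 or row0 >= row1:
        raise ValidationError(
            f"area of interest {ext.as_tuple()} does not overlap the raster extent "
            f"{g.extent.as_tuple()}"
        )
    new_extent = Extent(
        xmin=g.extent.xmin + col0 * g.resolution_x,
        xmax=g.extent.xmin + col1 * g.resolution_x,
        ymin=g.extent.ymax - row1 * g.resolution_y,
        ymax=g.extent.ymax - row0 * g.resolution_y,
    )
    new_grid = GridSpec(
        extent=new_extent,
        resolution_x=g.resolution_x,
        resolution_y=g.resolution_y,
        nrow=row1 - row0,
        ncol=col1 - col0,
        crs_kind=g.crs_kind,
    )
    return FrictionSurface(
        grid=new_grid,
        values=surface.values[row0:row1, col0:col1].copy(),
        nodata_mask=surface.nodata_mask[row0:row1, col0:col1].copy(),
    )


def mask_surface(surface: FrictionSurface, polygon) -> FrictionSurface:
    """Mask cells whose CENTER falls outside ``polygon`` (same CRS as the grid).

    All-or-nothing by cell center, not fractional coverage; unmasked values
    are never modified, and masking is idempotent (the masked set only
    grows under successive masks).
    """
    if not isinstance(polygon, shapely.Geometry):
        raise ValidationError(f"mask must be a shapely geometry, got {type(polygon).__name__}")
    e = surface.grid.extent
    if not polygon.intersects(box(e.xmin, e.ymin, e.xmax, e.ymax)):
        raise ValidationError(
            f"mask polygon (bounds {polygon.bounds}) is disjoint from the surface extent "
            f"{e.as_tuple()}; the masked surface would be empty"
        )
    xs, ys = surface.grid.center_coords()
    xx, yy = np.meshgrid(xs, ys)
    # boundary counts as inside: a center on the polygon edge is retained
    inside = shapely.intersects_xy(polygon, xx.ravel(), yy.ravel()).reshape(surface.grid.shape)
    new_mask = surface.nodata_mask | ~inside
    return FrictionSurface(surface.grid, surface.values.copy(), new_mask)


def prepare_friction(
    source,
    aoi,
    mask=None,
    *,
    resolution: float = RES_30_ARCSEC,
    fetcher: "FetchAdapter | None" = None,
) -> FrictionSurface:
    """Prepare a friction surface for an area of interest.

    Parameters
    ----------
    source
        Either a named global surface (``"walk2020"`` or ``"motor2020"``,
        requiring a configured ``fetcher``), an in-memory
        :class:`FrictionSurface`, or a path to a single-band friction
        GeoTIFF.
    aoi
        Area of interest: an :class:`~traveltime.grid.Extent`, a 4-tuple
        (xmin, xmax, ymin, ymax), or a shapely polygon (its bounding box
        is used as the requested extent).
    mask
        Optional shapely polygon; cells whose center falls outside it are
        set to nodata (see :func:`mask_surface`).
    resolution
        Lattice resolution for named surfaces (default 30 arc seconds).
    fetcher
        Adapter used to retrieve named surfaces; required for named
        sources, ignored otherwise.

    For a named surface the result grid is ``snap_extent(aoi, resolution)``;
    for a user raster the raster's own grid is kept (cropped to the AOI's
    cell range, no resampling).
    """
    ext = _as_extent(aoi)
    if isinstance(source, str) and source in SURFACE_NAMES:
        if fetcher is None:
            raise OfflineError(
                f"named surface {source!r} requested but no fetch adapter is configured; "
                "running offline — supply a raster or configure a fetcher"
            )
        target = snap_extent(ext, resolution)
        surface = fetcher.fetch(source, target)
        if not surface.grid.approx_equal(target):
            raise FetchError(
                f"fetch adapter returned grid {surface.grid.shape} over "
                f"{surface.grid.extent.as_tuple()}, expected {target.shape} over "
                f"{target.extent.as_tuple()}"
            )
    elif isinstance(source, (str, Path)):
        if not Path(source).exists():
            raise ValidationError(
                f"unknown surface {source!r}: not one of {SURFACE_NAMES} and not an existing file"
            )
        from .io import read_friction_raster

        surface = crop_surface(read_friction_raster(source), ext)
    elif isinstance(source, FrictionSurface):
        surface = crop_surface(source, ext)
    else:
        raise ValidationError(f"cannot interpret friction source of type {type(source).__name__}")

    if mask is not None:
        surface = mask_surface(surface, mask)
    if surface.n_unmasked == 0:
        raise ValidationError(
            f"friction surface has no usable cells in the area of interest: "
            f"{surface.grid.size} cells, all nodata"
        )
    return surface


def synth_friction(
    nrow: int,
    ncol: int,
    pattern: str = "uniform",
    base_value: float = 0.012,
    seed: "int | None" = None,
    *,
    grid: "GridSpec | None" = None,
) -> FrictionSurface:
    """Generate a deterministic synthetic friction surface for testing.

    Patterns
    --------
    ``uniform``
        Every cell exactly ``base_value``.
    ``gradient``
        Linear west→east ramp from ``base_value`` to ``5 * base_value``.
    ``random``
        Per-cell log-uniform draws in [``base_value``, ``5 * base_value``]
        (seeded, reproducible).
    ``corridor_with_barrier``
        Uniform friction with the middle column fully masked, splitting
        the grid into two disconnected components — the disconnected-island
        situation where travel time from the far side is infinite.

    The default grid is geographic at 30 arc seconds with its south-west
    corner at (0, 0), i.e. equatorial cells of the global surface lattice.
    ``base_value`` defaults to 0.012 min/m, a typical minimum walking
    friction in urban areas.
    """
    if nrow < 1 or ncol < 1:
        raise ValidationError(f"synthetic surface needs nrow, ncol >= 1, got {nrow}x{ncol}")
    if base_value <= 0:
        raise ValidationError(f"base_value must be positive, got {base_value}")
    if grid is None:
        grid = GridSpec(
            extent=Extent(0.0, ncol * RES_30_ARCSEC, 0.0, nrow * RES_30_ARCSEC),
            resolution_x=RES_30_ARCSEC,
            resolution_y=RES_30_ARCSEC,
            nrow=nrow,
            ncol=ncol,
            crs_kind=GEOGRAPHIC,
        )
    elif grid.shape != (nrow, ncol):
        raise ValidationError(f"supplied grid shape {grid.shape} != ({nrow}, {ncol})")

    mask = np.zeros((nrow, ncol), dtype=bool)
    if pattern == "uniform":
        values = np.full((nrow, ncol), base_value, dtype=float)
    elif pattern == "gradient":
        ramp = np.linspace(base_value, 5.0 * base_value, ncol)
        values = np.tile(ramp, (nrow, 1))
    elif pattern == "random":
        rng = np.random.default_rng(seed)
        values = np.exp(
            rng.uniform(np.log(base_value), np.log(5.0 * base_value), size=(nrow, ncol))
        )
    elif pattern == "corridor_with_barrier":
        if ncol < 3:
            raise ValidationError(
                f"corridor_with_barrier needs ncol >= 3 to hold two components, got {ncol}"
            )
        values = np.full((nrow, ncol), base_value, dtype=float)
        mask[:, ncol // 2] = True
    else:
        raise ValidationError(
            f"unknown pattern {pattern!r}: expected one of "
            "uniform, gradient, random, corridor_with_barrier"
        )
    return FrictionSurface(grid=grid, values=values, nodata_mask=mask)


def barrier_column(ncol: int) -> int:
    """Column index of the masked barrier in ``corridor_with_barrier``."""
    return ncol // 2
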