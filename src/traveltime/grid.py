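"""Raster grid conventions.

A travel-time grid is an axis-aligned, north-up lattice of square-ish cells
described by :class:`GridSpec`.  Geographic grids live on the canonical
global 30-arc-second lattice (1/120 of a degree, ~1 km at the equator)
anchored at (-180, -90), the resolution of the 2020 global walking and
motorised friction surfaces; :func:`snap_extent` moves a requested bounding
box onto that lattice.  Distances between cell centers are great-circle
(haversine) on a sphere in geographic mode and Euclidean in planar mode.

Conventions
-----------
* Row 0 is the northernmost row (north-up).
* Cell membership is half-open: a point on an interior grid line belongs to
  the cell to its east/south; the extent's far edges (xmax, ymin) are closed
  so no in-extent point is orphaned.
* Extents that would cross the antimeridian are rejected, not wrapped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import GridError, OutOfBoundsError

#: IUGG mean Earth radius in meters (spherical model; at ~1 km cells the
#: difference from ellipsoidal geodesics is far below friction uncertainty).
EARTH_RADIUS_M = 6_371_008.8

#: 30 arc seconds in decimal degrees — the global friction-surface lattice.
RES_30_ARCSEC = 1.0 / 120.0

#: Anchor of the global lattice: lattice lines sit at anchor + k * resolution.
GLOBAL_ANCHOR = (-180.0, -90.0)

GEOGRAPHIC = "geographic"
PLANAR = "planar"


@dataclass(frozen=True)
class Extent:
    """Axis-aligned bounding box, (xmin, xmax, ymin, ymax).

    Units are decimal degrees for geographic grids, map units otherwise.
    """

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmin < self.xmax):
            raise GridError(f"extent requires xmin < xmax, got {self.xmin} >= {self.xmax}")
        if not (self.ymin < self.ymax):
            raise GridError(f"extent requires ymin < ymax, got {self.ymin} >= {self.ymax}")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    def validate_geographic(self) -> None:
        """Reject extents outside the lon/lat domain (incl. antimeridian wraps)."""
        if self.xmin < -180.0 or self.xmax > 180.0:
            raise GridError(
                f"geographic extent x-bounds ({self.xmin}, {self.xmax}) outside [-180, 180]; "
                "antimeridian-crossing extents are not supported"
            )
        if self.ymin < -90.0 or self.ymax > 90.0:
            raise GridError(
                f"geographic extent y-bounds ({self.ymin}, {self.ymax}) outside [-90, 90]"
            )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.xmin, self.xmax, self.ymin, self.ymax)


@dataclass(frozen=True)
class CellIndex:
    """Zero-based (row, col); row 0 is the northernmost row."""

    row: int
    col: int


@dataclass(frozen=True)
class GridSpec:
    """An axis-aligned north-up raster grid.

    Invariant: ``ncol * resolution_x == extent.width`` and
    ``nrow * resolution_y == extent.height`` to one part in 1e9.
    """

    extent: Extent
    resolution_x: float
    resolution_y: float
    nrow: int
    ncol: int
    crs_kind: str = GEOGRAPHIC

    def __post_init__(self) -> None:
        if self.crs_kind not in (GEOGRAPHIC, PLANAR):
            raise GridError(f"crs_kind must be {GEOGRAPHIC!r} or {PLANAR!r}, got {self.crs_kind!r}")
        if self.nrow < 1 or self.ncol < 1:
            raise GridError(f"grid must have positive dimensions, got {self.nrow}x{self.ncol}")
        if self.resolution_x <= 0 or self.resolution_y <= 0:
            raise GridError("resolutions must be strictly positive")
        for n, res, span, axis in (
            (self.ncol, self.resolution_x, self.extent.width, "x"),
            (self.nrow, self.resolution_y, self.extent.height, "y"),
        ):
            if abs(n * res - span) > 1e-9 * max(1.0, abs(span)):
                raise GridError(
                    f"{axis}-axis inconsistent: {n} cells x {res} != extent span {span}"
                )
        if self.crs_kind == GEOGRAPHIC:
            self.extent.validate_geographic()

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrow, self.ncol)

    @property
    def size(self) -> int:
        return self.nrow * self.ncol

    def contains_cell(self, cell: CellIndex) -> bool:
        return 0 <= cell.row < self.nrow and 0 <= cell.col < self.ncol

    def approx_equal(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        """Same lattice within ``tol`` (absorbs float drift from file round trips)."""
        return (
            self.shape == other.shape
            and self.crs_kind == other.crs_kind
            and abs(self.resolution_x - other.resolution_x) <= tol
            and abs(self.resolution_y - other.resolution_y) <= tol
            and all(
                abs(a - b) <= tol
                for a, b in zip(self.extent.as_tuple(), other.extent.as_tuple())
            )
        )

    # --- coordinate mapping -------------------------------------------------

    def cell_center(self, cell: CellIndex) -> tuple[float, float]:
        """(x, y) of the center of ``cell``; raises for out-of-range cells."""
        if not self.contains_cell(cell):
            raise OutOfBoundsError(
                f"cell ({cell.row}, {cell.col}) outside grid of shape {self.nrow}x{self.ncol}"
            )
        x = self.extent.xmin + (cell.col + 0.5) * self.resolution_x
        y = self.extent.ymax - (cell.row + 0.5) * self.resolution_y
        return (x, y)

    def center_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Vectors of all column-center x's (ncol,) and row-center y's (nrow,)."""
        xs = self.extent.xmin + (np.arange(self.ncol) + 0.5) * self.resolution_x
        ys = self.extent.ymax - (np.arange(self.nrow) + 0.5) * self.resolution_y
        return xs, ys

    def point_to_cell(self, x: float, y: float) -> CellIndex:
        """Cell containing (x, y) under the half-open convention.

        A point on an interior grid line belongs to the cell to its
        east/south; points exactly on xmax or ymin map to the last
        column/row.  Points outside the extent raise
        :class:`OutOfBoundsError`.
        """
        e = self.extent
        if not (e.xmin <= x <= e.xmax and e.ymin <= y <= e.ymax):
            raise OutOfBoundsError(
                f"point ({x}, {y}) outside grid extent "
                f"({e.xmin}, {e.xmax}, {e.ymin}, {e.ymax})"
            )
        col = int(math.floor((x - e.xmin) / self.resolution_x))
        row = int(math.floor((e.ymax - y) / self.resolution_y))
        # far edges are closed
        col = min(col, self.ncol - 1)
        row = min(row, self.nrow - 1)
        return CellIndex(row=row, col=col)


def _snap_index(value: float, anchor: float, resolution: float) -> int:
    # nearest lattice line, ties toward +infinity
    return int(math.floor((value - anchor) / resolution + 0.5))


def snap_extent(
    requested: Extent,
    resolution: float,
    *,
    anchor: tuple[float, float] = GLOBAL_ANCHOR,
    crs_kind: str = GEOGRAPHIC,
) -> GridSpec:
    """Snap a requested extent onto the global lattice and return its grid.

    Each of the four bounds is moved independently to the NEAREST lattice
    line (multiples of ``resolution`` offset from ``anchor``; ties round
    toward +infinity).  Snapping an already-aligned extent is the identity.

    Raises :class:`GridError` if the snapped extent collapses to zero rows
    or columns on either axis.
    """
    if resolution <= 0:
        raise GridError(f"resolution must be positive, got {resolution}")
    if crs_kind == GEOGRAPHIC:
        requested.validate_geographic()
    ax, ay = anchor
    ix0 = _snap_index(requested.xmin, ax, resolution)
    ix1 = _snap_index(requested.xmax, ax, resolution)
    iy0 = _snap_index(requested.ymin, ay, resolution)
    iy1 = _snap_index(requested.ymax, ay, resolution)
    ncol = ix1 - ix0
    nrow = iy1 - iy0
    if ncol < 1:
        raise GridError(
            f"snapped extent degenerate on the x axis: xmin {requested.xmin} and "
            f"xmax {requested.xmax} snap to the same lattice line at resolution {resolution}"
        )
    if nrow < 1:
        raise GridError(
            f"snapped extent degenerate on the y axis: ymin {requested.ymin} and "
            f"ymax {requested.ymax} snap to the same lattice line at resolution {resolution}"
        )
    snapped = Extent(
        xmin=ax + ix0 * resolution,
        xmax=ax + ix1 * resolution,
        ymin=ay + iy0 * resolution,
        ymax=ay + iy1 * resolution,
    )
    return GridSpec(
        extent=snapped,
        resolution_x=resolution,
        resolution_y=resolution,
        nrow=nrow,
        ncol=ncol,
        crs_kind=crs_kind,
    )


# --- distances ---------------------------------------------------------------


def haversine_m(
    lon1: "float | np.ndarray",
    lat1: "float | np.ndarray",
    lon2: "float | np.ndarray",
    lat2: "float | np.ndarray",
) -> "float | np.ndarray":
    """Great-circle distance in meters on a sphere of radius ``EARTH_RADIUS_M``.

    Vectorized over numpy arrays; inputs in decimal degrees.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.minimum(1.0, np.sqrt(a)))
    if np.ndim(d) == 0:
        return float(d)
    return d


def great_circle_distance(p1: Iterable[float], p2: Iterable[float]) -> float:
    """Haversine distance in meters between two (lon, lat) points in degrees."""
    lon1, lat1 = p1
    lon2, lat2 = p2
    return float(haversine_m(lon1, lat1, lon2, lat2))
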