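"""Travel-time computation over a friction surface.

The friction raster is viewed as an 8-connected (queen's move) weighted
graph on its unmasked cells.  The cost of stepping between two adjacent
cells is the distance between their centers multiplied by an average of
the two cells' friction values:

* ``mean_friction`` (default): ``d * (f_a + f_b) / 2`` — arithmetic mean
  of the two resistances;
* ``mean_conductance``: ``d / ((1/f_a + 1/f_b) / 2)`` — harmonic mean of
  the resistances, i.e. arithmetic mean of the speeds, matching
  transition-matrix (conductance) implementations.

Distances are great-circle between cell centers on geographic grids (so a
diagonal step costs its true geodesic length — no separate sqrt(2) factor)
and Euclidean on planar grids.  Travel time to the nearest of a set of
source locations is then a multi-source shortest-path problem, solved with
Dijkstra's algorithm seeded at every source cell; cells in components
containing no source get +infinity, and masked cells are nodata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .errors import OutOfBoundsError, ValidationError
from .friction import FrictionSurface
from .grid import GEOGRAPHIC, PLANAR, CellIndex, GridSpec, haversine_m

AVERAGING_MODES = ("mean_friction", "mean_conductance")
DISTANCE_MODES = ("geodesic", "planar")

#: Label value for unreachable cells in the nearest-source raster.
LABEL_NODATA = -1


@dataclass(frozen=True)
class EdgeModel:
    """How raster adjacency is turned into edge costs.

    ``distance_mode=None`` resolves to geodesic on geographic grids and
    planar on projected grids.  Connectivity is fixed at 8.
    """

    averaging: str = "mean_friction"
    distance_mode: "str | None" = None
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.averaging not in AVERAGING_MODES:
            raise ValidationError(
                f"averaging must be one of {AVERAGING_MODES}, got {self.averaging!r}"
            )
        if self.distance_mode is not None and self.distance_mode not in DISTANCE_MODES:
            raise ValidationError(
                f"distance_mode must be one of {DISTANCE_MODES} or None, got {self.distance_mode!r}"
            )
        if self.connectivity != 8:
            raise ValidationError("only 8-connectivity is supported")

    def resolve_distance_mode(self, grid: GridSpec) -> str:
        if self.distance_mode is not None:
            return self.distance_mode
        return "geodesic" if grid.crs_kind == GEOGRAPHIC else "planar"


@dataclass
class SourceSet:
    """Validated source locations snapped to grid cells.

    ``cells`` holds the deduplicated source cells in order of first
    appearance; ``cell_point_index[i]`` is the index (into ``points``) of
    the first point that landed in ``cells[i]`` and is the label that cell
    family carries in :func:`nearest_source_labels`.
    """

    points: list[tuple[float, float]]
    cells: list[CellIndex]
    cell_point_index: list[int] = field(default_factory=list)

    @classmethod
    def from_points(
        cls,
        points: Sequence[Sequence[float]],
        grid: GridSpec,
        nodata_mask: "np.ndarray | None" = None,
        *,
        drop_bad: bool = False,
    ) -> "SourceSet":
        """Snap coordinate pairs to cells, validating against the grid/mask.

        By default a point outside the extent or on a masked cell is a hard
        error (a silently dropped source would quietly change every
        downstream travel time); with ``drop_bad=True`` such points are
        dropped with a warning instead.  At least one valid source must
        remain.
        """
        pts = [(float(p[0]), float(p[1])) for p in points]
        if not pts:
            raise ValidationError("source set is empty: at least one point is required")
        kept: list[tuple[float, float]] = []
        cells: list[CellIndex] = []
        index_of_cell: dict[CellIndex, int] = {}
        cell_point_index: list[int] = []
        n_dropped = 0
        for i, (x, y) in enumerate(pts):
            try:
                cell = grid.point_to_cell(x, y)
            except OutOfBoundsError:
                if drop_bad:
                    n_dropped += 1
                    continue
                raise OutOfBoundsError(
                    f"source point {i} at ({x}, {y}) is outside the grid extent "
                    f"{grid.extent.as_tuple()}"
                ) from None
            if nodata_mask is not None and nodata_mask[cell.row, cell.col]:
                if drop_bad:
                    n_dropped += 1
                    continue
                raise ValidationError(
                    f"source point {i} at ({x}, {y}) falls on a masked (nodata) cell "
                    f"({cell.row}, {cell.col})"
                )
            kept.append((x, y))
            if cell not in index_of_cell:
                index_of_cell[cell] = len(cells)
                cells.append(cell)
                cell_point_index.append(i)
        if n_dropped:
            warnings.warn(
                f"dropped {n_dropped} source point(s) outside the extent or on masked cells",
                stacklevel=2,
            )
        if not cells:
            raise ValidationError(
                "no usable source cells: every supplied point is outside the extent "
                "or on a masked cell"
            )
        return cls(points=pts, cells=cells, cell_point_index=cell_point_index)


@dataclass
class TravelTimeRaster:
    """Per-cell minimum travel time in minutes to the nearest source.

    Source cells are exactly 0; unmasked cells with no path to any source
    are +inf; masked cells are NaN with ``nodata_mask`` True.
    """

    grid: GridSpec
    minutes: np.ndarray
    nodata_mask: np.ndarray
    model: EdgeModel = field(default_factory=EdgeModel)

    def __post_init__(self) -> None:
        self.minutes = np.asarray(self.minutes, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.minutes.shape != self.grid.shape or self.nodata_mask.shape != self.grid.shape:
            raise ValidationError("travel-time array shape does not match grid")
        finite_part = self.minutes[~self.nodata_mask]
        if finite_part.size and np.nanmin(finite_part) < 0:
            raise ValidationError("travel times must be non-negative")

    @property
    def n_infinite(self) -> int:
        return int(np.sum(np.isinf(self.minutes[~self.nodata_mask])))

    def finite_minutes(self) -> np.ndarray:
        vals = self.minutes[~self.nodata_mask]
        return vals[np.isfinite(vals)]


# --- edge construction -------------------------------------------------------


def _step_distances(grid: GridSpec, distance_mode: str):
    """Per-row distances for horizontal, vertical and diagonal steps.

    Returns (d_horiz[nrow], d_vert[nrow-1], d_diag[nrow-1]).  On a
    geographic grid the horizontal and diagonal step lengths shrink with
    |latitude| (cos-latitude); haversine distance between two centers
    depends only on their latitudes and the longitude difference, so one
    value per row (or row pair) suffices.
    """
    nrow = grid.nrow
    if distance_mode == "planar":
        dx, dy = grid.resolution_x, grid.resolution_y
        return (
            np.full(nrow, dx),
            np.full(max(nrow - 1, 0), dy),
            np.full(max(nrow - 1, 0), float(np.hypot(dx, dy))),
        )
    _, ys = grid.center_coords()
    dlon = grid.resolution_x
    d_horiz = haversine_m(0.0, ys, dlon, ys)
    d_vert = haversine_m(0.0, ys[:-1], 0.0, ys[1:]) if nrow > 1 else np.zeros(0)
    d_diag = haversine_m(0.0, ys[:-1], dlon, ys[1:]) if nrow > 1 else np.zeros(0)
    return np.atleast_1d(d_horiz), np.atleast_1d(d_vert), np.atleast_1d(d_diag)


def _combine(f_a: np.ndarray, f_b: np.ndarray, d: np.ndarray, averaging: str) -> np.ndarray:
    if averaging == "mean_friction":
        return d * (f_a + f_b) / 2.0
    # mean_conductance: harmonic mean of frictions = arithmetic mean of speeds
    return d * 2.0 * f_a * f_b / (f_a + f_b)


def edge_cost(
    surface: FrictionSurface,
    a: CellIndex,
    b: CellIndex,
    model: "EdgeModel | None" = None,
) -> float:
    """Cost in minutes of stepping between 8-neighbor cells ``a`` and ``b``.

    Symmetric and strictly positive.  Raises if the cells are not
    8-neighbors or if either endpoint is masked (a masked endpoint means
    the edge is absent, not free).
    """
    model = model or EdgeModel()
    g = surface.grid
    for c in (a, b):
        if not g.contains_cell(c):
            raise OutOfBoundsError(f"cell ({c.row}, {c.col}) outside grid {g.shape}")
    dr, dc = b.row - a.row, b.col - a.col
    if (dr, dc) == (0, 0) or abs(dr) > 1 or abs(dc) > 1:
        raise ValidationError(f"cells ({a.row},{a.col}) and ({b.row},{b.col}) are not 8-neighbors")
    if surface.nodata_mask[a.row, a.col] or surface.nodata_mask[b.row, b.col]:
        raise ValidationError("no edge: one endpoint is a masked cell")
    mode = model.resolve_distance_mode(g)
    if mode == "planar":
        d = float(np.hypot(dc * g.resolution_x, dr * g.resolution_y))
    else:
        xa, ya = g.cell_center(a)
        xb, yb = g.cell_center(b)
        d = float(haversine_m(xa, ya, xb, yb))
    return float(
        _combine(
            surface.values[a.row, a.col],
            surface.values[b.row, b.col],
            np.asarray(d),
            model.averaging,
        )
    )


def build_graph(surface: FrictionSurface, model: "EdgeModel | None" = None):
    """Sparse upper-triangle adjacency of the 8-connected unmasked graph.

    Returns a ``(n, n)`` CSR matrix over flattened cell indices
    (``row * ncol + col``); each undirected edge appears once.
    """
    model = model or EdgeModel()
    g = surface.grid
    nrow, ncol = g.shape
    n = g.size
    mode = model.resolve_distance_mode(g)
    d_horiz, d_vert, d_diag = _step_distances(g, mode)
    f = surface.values
    open_ = ~surface.nodata_mask
    flat = np.arange(n).reshape(nrow, ncol)

    rows_i: list[np.ndarray] = []
    rows_j: list[np.ndarray] = []
    wts: list[np.ndarray] = []

    def add_edges(sl_a, sl_b, d_per_row: np.ndarray, row_slice):
        ok = open_[sl_a] & open_[sl_b]
        if not ok.any():
            return
        d = np.broadcast_to(d_per_row[row_slice][:, None], ok.shape)
        w = _combine(f[sl_a], f[sl_b], d, model.averaging)
        rows_i.append(flat[sl_a][ok])
        rows_j.append(flat[sl_b][ok])
        wts.append(w[ok])

    if ncol > 1:  # east
        add_edges(np.s_[:, :-1], np.s_[:, 1:], d_horiz, np.s_[:])
    if nrow > 1:  # south
        add_edges(np.s_[:-1, :], np.s_[1:, :], d_vert, np.s_[:])
    if nrow > 1 and ncol > 1:  # south-east and south-west diagonals
        add_edges(np.s_[:-1, :-1], np.s_[1:, 1:], d_diag, np.s_[:])
        add_edges(np.s_[:-1, 1:], np.s_[1:, :-1], d_diag, np.s_[:])

    if rows_i:
        i = np.concatenate(rows_i)
        j = np.concatenate(rows_j)
        w = np.concatenate(wts)
    else:
        i = j = np.zeros(0, dtype=int)
        w = np.zeros(0)
    return coo_matrix((w, (i, j)), shape=(n, n)).tocsr()


# --- shortest paths ----------------------------------------------------------


def _source_flat_indices(sources: SourceSet, grid: GridSpec) -> np.ndarray:
    return np.array([c.row * grid.ncol + c.col for c in sources.cells], dtype=int)


def _coerce_sources(surface: FrictionSurface, points, drop_bad: bool) -> SourceSet:
    if isinstance(points, SourceSet):
        for c in points.cells:
            if not surface.grid.contains_cell(c):
                raise OutOfBoundsError(f"source cell ({c.row}, {c.col}) outside grid")
            if surface.nodata_mask[c.row, c.col]:
                raise ValidationError(f"source cell ({c.row}, {c.col}) is masked")
        return points
    return SourceSet.from_points(points, surface.grid, surface.nodata_mask, drop_bad=drop_bad)


def calculate_travel_time(
    surface: FrictionSurface,
    points,
    model: "EdgeModel | None" = None,
    *,
    drop_bad: bool = False,
) -> TravelTimeRaster:
    """Minimum travel time in minutes from every cell to the nearest source.

    ``points`` is a SourceSet or a sequence of (x, y) coordinates.  The
    result is the length of the cheapest 8-connected path from each
    unmasked cell to ANY source cell: exactly 0 at sources, +inf for
    unmasked cells whose component contains no source (e.g. islands with
    no station), NaN/nodata for masked cells.  Deterministic regardless of
    source ordering.
    """
    model = model or EdgeModel()
    sources = _coerce_sources(surface, points, drop_bad)
    graph = build_graph(surface, model)
    src = _source_flat_indices(sources, surface.grid)
    dist = dijkstra(graph, directed=False, indices=src, min_only=True)
    minutes = np.asarray(dist, dtype=float).reshape(surface.grid.shape)
    minutes[surface.nodata_mask] = np.nan
    return TravelTimeRaster(
        grid=surface.grid,
        minutes=minutes,
        nodata_mask=surface.nodata_mask.copy(),
        model=model,
    )


def nearest_source_labels(
    surface: FrictionSurface,
    points,
    model: "EdgeModel | None" = None,
    *,
    drop_bad: bool = False,
) -> np.ndarray:
    """Label each reachable cell with the source achieving its minimum time.

    Labels are indices into the supplied point sequence; points sharing a
    cell resolve to the first of them, and exact ties between distinct
    source cells go to the lowest source index.  Unreachable and masked
    cells get ``LABEL_NODATA`` (-1).
    """
    model = model or EdgeModel()
    sources = _coerce_sources(surface, points, drop_bad)
    graph = build_graph(surface, model)
    src = _source_flat_indices(sources, surface.grid)
    dist = dijkstra(graph, directed=False, indices=src)  # (n_sources, n_cells)
    best = np.argmin(dist, axis=0)  # first minimum wins ties -> lowest source index
    unreachable = ~np.isfinite(dist[best, np.arange(dist.shape[1])])
    point_index = np.asarray(sources.cell_point_index, dtype=int)
    labels = point_index[best]
    labels[unreachable] = LABEL_NODATA
    labels = labels.reshape(surface.grid.shape)
    labels[surface.nodata_mask] = LABEL_NODATA
    return labels
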