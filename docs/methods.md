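# Methods

## Problem and model

The package computes accessibility surfaces: given a friction raster whose
cell values are the cost of traversal in minutes per meter, and a set of
source coordinates, it returns a raster in which each cell holds the lowest
travel time in minutes to the nearest source. The raster is modelled as an
undirected weighted graph over its unmasked cells with 8-connectivity; the
result is the multi-source shortest-path distance from every cell to the
source set.

### Edge costs

For adjacent cells *a*, *b* with frictions `f_a`, `f_b` (min/m) and
center-to-center distance `d` (m):

* `mean_friction` (default): `d · (f_a + f_b) / 2`. Arithmetic mean of the
  two resistances — the convention of the accessibility-mapping lineage
  behind the global friction surfaces.
* `mean_conductance`: `d / ((1/f_a + 1/f_b)/2)`, i.e. distance times the
  harmonic mean of the frictions, equivalently the arithmetic mean of the
  two speeds. Matches transition-matrix (conductance-based) raster-cost
  implementations.

Both are exposed because published raster-cost tools disagree on this
averaging and the choice is rarely stated; the one used is recorded in the
output file's metadata. The two coincide exactly when `f_a = f_b`, so they
differ only across friction gradients (the harmonic mean is always ≤ the
arithmetic mean, so `mean_conductance` times are ≤ `mean_friction` times).

Distances are haversine great-circle on a sphere of radius 6,371,008.8 m
(IUGG mean radius) for geographic grids and Euclidean in map units for
projected grids. Diagonal steps therefore cost their true center-to-center
length — there is no separate √2 factor, and on geographic grids
horizontal and diagonal steps shrink with cos(latitude). The spherical
model is deterministic and within ~0.3% of ellipsoidal geodesics,
negligible against friction-surface uncertainty at ~1 km cells.

### Shortest paths

All deduplicated source cells are seeded at distance 0 and a single
multi-source Dijkstra pass (`scipy.sparse.csgraph.dijkstra`, `min_only`)
yields the minimum over sources for every cell at once. The graph
construction — per-row geodesic step lengths, mask handling, averaging —
is this package's own; the engine contains no randomness, so identical
inputs give bitwise-identical outputs. Unmasked cells in components
containing no source are +∞ (IEEE infinity in memory); masked cells are
NaN with the nodata mask set. Catchment labels (`nearest_source_labels`)
run one Dijkstra per distinct source cell and take the argmin, so exact
ties resolve to the lowest source index; points sharing a cell collapse to
the first of them.

## Grid conventions

* Global lattice: lattice lines at multiples of the resolution from the
  anchor (−180, −90); the 2020 surfaces use 1/120° (30 arc seconds).
* Snapping: each requested bound moves independently to the **nearest**
  lattice line, ties toward +∞. This moves every bound by at most half a
  cell, is idempotent, and is the identity on aligned extents. Nearest-line
  rounding is the rule consistent with the hosted surfaces' behaviour on
  the Singapore extent (two bounds move down, two move up); outward
  expansion would have grown all four. The anchor is a parameter should a
  future surface source behave differently.
* North-up: row 0 is the northernmost row.
* Point-in-cell: half-open intervals (a point on an interior grid line
  belongs to the cell to its east/south), with the far edges (xmax, ymin)
  closed so every in-extent point has a cell.
* Antimeridian-crossing extents are rejected, not wrapped.

## Friction preparation

Friction is strictly positive and finite on unmasked cells — a zero would
mean infinite speed and is treated as data corruption, not clamped. Values
above 10 min/m trigger a units warning (likely minutes per km) but are not
converted. User rasters are never resampled: preparation crops to the
sub-block of whole cells covering the area of interest, so every output
value equals an input value; users must supply data aligned to their
intended grid. Polygon masking is all-or-nothing by cell center (a center
on the polygon boundary counts as inside); fractional-coverage masking was
rejected because downstream cost paths cannot traverse a fraction of a
cell. Named surfaces (`walk2020`, `motor2020`) go through a pluggable fetch
adapter; with no adapter configured the request fails with an explicit
offline error rather than attempting network access. A disk-caching
wrapper keys on (name, snapped extent) and serves repeat requests
byte-identically.

## File formats

Rasters are single-band GeoTIFFs with an axis-aligned geotransform, read
and written through `tifffile` with the standard GeoTIFF tags
(ModelPixelScale, ModelTiepoint, GeoKeyDirectory with EPSG:4326 for
geographic grids) plus GDAL_NODATA and GDAL_METADATA. Multi-band, rotated
or CRS-less files are rejected with the defect named. Travel-time output
is float32 (minutes need < 7 significant digits); friction is written at
float64. GeoTIFF consumers handle IEEE ∞ inconsistently, so on disk both
infinite and masked cells carry the nodata sentinel (default −9999) while
GDAL_METADATA records the separate counts and the edge model, keeping the
distinction recoverable; in memory infinity stays a true +∞. Points are
headered CSV (configurable column names, '.' decimal, no locale
inference) or point GeoJSON; mask polygons are the first
Polygon/MultiPolygon feature of a GeoJSON file.

## Synthetic surfaces

`synth_friction` generates the test conditions: geographic 30-arc-second
cells with the south-west corner at (0°, 0°) — equatorial cells of the
global surface lattice — and base friction 0.012 min/m, a typical minimum
urban walking friction. Patterns: `uniform` (exactly the base value),
`gradient` (west→east linear ramp from base to 5× base), `random`
(per-cell log-uniform in [base, 5·base], seeded), and
`corridor_with_barrier` (uniform with the middle column fully masked,
splitting the grid into two components — the deterministic analogue of an
island with no station, used to test the +∞ contract). Synthetic surfaces
emulate the value range, grid geometry and masking structure of real
friction data but not its spatial autocorrelation or road-network
anisotropy, so passing tests demonstrate the correctness of the
computation, not the realism of any particular travel-time map.

## Numerical choices

* Source points on masked cells, or outside the extent, are hard errors by
  default — silently dropping them would quietly change every downstream
  value; `drop_bad` (CLI `--drop-bad-points`) downgrades to warn-and-drop,
  still erroring if nothing remains.
* Grid-consistency checks use a relative tolerance of 1e−9; grid equality
  after file round trips uses an absolute 1e−9 in degrees (~0.1 mm).
* Label ties: lowest source index, deterministic.
* A 1×1 grid or fully-disconnected graph degenerates gracefully: sources
  are 0, everything else +∞.

## Verification

The engine is checked against an independent oracle: tests enumerate every
8-neighbor edge explicitly with their own haversine and averaging
arithmetic and relax with vectorized Bellman–Ford until fixed point;
engine and oracle agree to 1e−9 relative on hundreds of random masked
grids up to 20×20 under both averagings and both distance modes. Closed
forms pin the scale: on uniform planar grids travel time follows the
octile formula `f·s·(√2·min(|Δr|,|Δc|) + ||Δr|−|Δc||)` exactly, and a
30-arc-second step at the equator costs `f × 926.63 m`-minutes. Property
tests cover multi-source decomposition (pointwise minimum of single-source
runs), monotonicity in sources and in friction, scale equivariance, snap
idempotence, and file round trips. Problem sizes in the suite (grids up to
~40×50) keep the full run near one second while exercising every code
path; the algorithms scale to the tens-of-megacell range in memory, and
out-of-core continental extents are out of scope.

## Known limitations

* No reprojection, rotated grids, or sub-cell interpolation; inputs must
  share a CRS.
* Friction is isotropic and time-invariant; no one-way or time-dependent
  costs, no path reconstruction.
* Connectivity is fixed at 8; 16-connectivity (knight's moves) would
  reduce octile distortion but is not implemented.
* Named-surface fetching is a seam, not a bundled downloader; reproducing
  the hosted surfaces' cell values depends on the remote files and is an
  integration concern, not covered by the offline test suite.
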