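# traveltime

Travel-time rasters from friction surfaces: given a resistance ("friction")
raster and a set of point locations, compute a raster whose every cell holds
the **minimum travel time in minutes to the nearest of the supplied
locations**.

This is the standard tool shape of accessibility mapping in public health
and spatial epidemiology — time to the nearest health facility, station,
defibrillator, or charger — but it applies to any set of coordinates and
any friction surface: the friction raster encodes the cost of crossing each
cell in **minutes per meter** (the reciprocal of speed), and the package
turns it into a least-cost travel-time surface, catchment labels, and
GeoTIFF outputs.

## The model

The raster is viewed as a weighted graph on its unmasked cells with
8-connectivity (queen's move). The cost of a step between adjacent cells
*a* and *b* is

```
cost(a,b) = d(a,b) · (f_a + f_b) / 2            (mean_friction, default)
cost(a,b) = d(a,b) / ((1/f_a + 1/f_b) / 2)      (mean_conductance)
```

where `f` is friction in min/m and `d(a,b)` is the distance between the
cell centers — great-circle (haversine, sphere of radius 6,371,008.8 m) on
geographic grids, so horizontal and diagonal step lengths shrink with
latitude, or Euclidean on projected grids. `mean_friction` averages the two
resistances; `mean_conductance` averages the two speeds, matching
transition-matrix ("conductance") implementations. Travel time to the
nearest source is then a multi-source shortest-path problem, solved by
Dijkstra's algorithm seeded at every source cell. Cells in components
containing no source (islands cut off by masked sea, areas behind a
barrier) get **+∞**: they are unreachable, not merely far. Masked cells are
nodata.

Friction preparation follows the conventions of the 2020 global walking and
motorised surfaces: requested extents are snapped to the global
30-arc-second lattice (1/120°, anchored at −180, −90) by moving each bound
to the nearest lattice line; user-supplied rasters are cropped, never
resampled; polygon masks remove cells whose center falls outside the
polygon.

## Worked example

Snapping the GADM bounding box of Singapore onto the global lattice
(`examples/snap_singapore_grid.py`):

```
requested extent : (103.6091, 104.0858, 1.1664, 1.4714)
snapped extent   : (103.608333, 104.083333, 1.166667, 1.475000)
dimensions       : 37 rows x 57 cols at 0.008333333 deg
```

Each bound moved to the nearest 1/120° line — at most half a cell — so the
grid aligns cell-for-cell with the hosted friction surfaces.

Computing walking time on a synthetic surface with a disconnected component
(`examples/disconnected_island.py`; the middle column is masked, the single
source sits west of it):

```
travel-time raster (minutes; nan = masked barrier, inf = unreachable):
[[33.4 38.  42.6  nan  inf  inf  inf]
 [22.2 26.8 31.5  nan  inf  inf  inf]
 [11.1 15.7 26.8  nan  inf  inf  inf]
 [ 0.  11.1 22.2  nan  inf  inf  inf]
 [11.1 15.7 26.8  nan  inf  inf  inf]
 [22.2 26.8 31.5  nan  inf  inf  inf]]

min value : 0
max value : inf
unreachable cells : 18
```

The source cell is exactly 0; one 30-arc-second step at the equator at
friction 0.012 min/m costs 0.012 × 926.63 ≈ 11.1 minutes; the east
component holds no source, so its travel time is infinite. See also
`examples/walking_time_synthetic_city.py` (multi-source catchments).

## Command line

The shell workflow mirrors the two preparation/computation steps
(`examples/cli_workflow.sh`):

```sh
traveltime prepare --friction user.tif --extent "103.6091,104.0858,1.1664,1.4714" \
    --mask land.geojson -o friction.tif
traveltime compute --friction friction.tif --points stations.csv \
    -o minutes.tif --labels catchments.tif --json
traveltime synth --pattern corridor_with_barrier --nrow 5 --ncol 5 -o fixture.tif
```

`prepare --surface walk2020|motor2020` addresses the named 2020 global
surfaces and requires a configured fetch adapter (a library-level seam;
without one it fails with an explicit offline error, exit code 3).
Validation errors exit 2. `compute --json` prints a machine-readable
summary line (min/max finite minutes, infinite-cell count) to stdout.

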