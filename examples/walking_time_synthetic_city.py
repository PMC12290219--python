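"""Walking time to the nearest of three stations on a synthetic surface.

Generates a 40x50 random walking-friction surface (log-uniform between
0.012 and 0.060 min/m, the plausible urban walking range), places three
"station" sources, and computes the travel-time raster: each cell holds
the minimum walking minutes to the nearest station over the 8-connected
least-cost graph with geodesic step lengths.
"""

import numpy as np

import traveltime as tt

surface = tt.synth_friction(40, 50, pattern="random", base_value=0.012, seed=11)
stations = [
    surface.grid.cell_center(tt.CellIndex(10, 10)),
    surface.grid.cell_center(tt.CellIndex(30, 25)),
    surface.grid.cell_center(tt.CellIndex(15, 42)),
]

result = tt.calculate_travel_time(surface, stations)
labels = tt.nearest_source_labels(surface, stations)

finite = result.finite_minutes()
print(f"grid              : {surface.grid.nrow} x {surface.grid.ncol} cells "
      f"(30 arc-second, ~926 m at the equator)")
print(f"stations          : {len(stations)}")
print(f"min travel time   : {finite.min():.1f} minutes (exactly 0 at each station)")
print(f"max travel time   : {finite.max():.1f} minutes")
print(f"mean travel time  : {finite.mean():.1f} minutes")
for i in range(len(stations)):
    n = int((labels == i).sum())
    print(f"catchment of station {i}: {n} cells "
          f"({100 * n / surface.grid.size:.0f}% of the grid)")
print()
print("The catchment of a station is the set of cells for which it is the")
print("nearest (minimum travel time) source — a health-district style allocation.")
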