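"""Snap an area of interest onto the global 30-arc-second friction lattice.

The 2020 global walking/motorised friction surfaces live on a fixed
1/120-degree grid anchored at (-180, -90).  Any requested bounding box
must first be moved onto that lattice; here we snap the GADM bounding box
of Singapore and print the resulting grid, which is the grid every
Singapore travel-time raster in this package's documentation uses.
"""

import traveltime as tt

requested = tt.Extent(103.6091, 104.0858, 1.1664, 1.4714)  # GADM Singapore bbox
grid = tt.snap_extent(requested, tt.RES_30_ARCSEC)

e = grid.extent
print(f"requested extent : {requested.as_tuple()}")
print(f"snapped extent   : ({e.xmin:.6f}, {e.xmax:.6f}, {e.ymin:.6f}, {e.ymax:.6f})")
print(f"dimensions       : {grid.nrow} rows x {grid.ncol} cols "
      f"at {grid.resolution_x:.9f} deg")
print()
print("Each bound moved to the nearest lattice line (at most half a cell),")
print("so the grid aligns cell-for-cell with the global friction surfaces.")
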