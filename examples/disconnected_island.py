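"""Travel time to areas disconnected from every source is infinite.

A friction surface masked by a land polygon can contain islands: filled
cells with no 8-connected path to the mainland.  With all sources on the
mainland those island cells get +infinity — they are unreachable, not
merely far.  Here the same situation is built deterministically with the
corridor_with_barrier fixture, whose fully masked middle column splits
the grid into two components.
"""

import numpy as np

import traveltime as tt

surface = tt.synth_friction(6, 7, pattern="corridor_with_barrier", base_value=0.012)
source = surface.grid.cell_center(tt.CellIndex(3, 0))  # west of the barrier

result = tt.calculate_travel_time(surface, [source])

print("travel-time raster (minutes; nan = masked barrier, inf = unreachable):")
with np.printoptions(precision=1, suppress=True):
    print(result.minutes)
print()
print(f"min value : {np.nanmin(result.minutes):g}")
print(f"max value : {np.nanmax(result.minutes):g}")
print(f"unreachable cells : {result.n_infinite} "
      "(the east component holds no source, so its travel time is infinite)")
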