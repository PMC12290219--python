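#!/usr/bin/env bash
# The two-step shell workflow: prepare a friction surface, then compute
# travel time over it for a set of points.  Uses synthetic fixtures so it
# runs fully offline.
set -euo pipefail
cd "$(mktemp -d)"

# 1. generate a deterministic friction surface and three source points
traveltime synth --pattern random --nrow 30 --ncol 30 --seed 7 \
    -o friction.tif --points-out stations.csv

# 2. (optional) crop it to a sub-extent — prepare never resamples
traveltime prepare --friction friction.tif \
    --extent "0.02,0.2,0.02,0.2" -o friction_crop.tif

# 3. travel time in minutes to the nearest station, plus catchment labels
traveltime compute --friction friction.tif --points stations.csv \
    -o minutes.tif --labels catchments.tif --json
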