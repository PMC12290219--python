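"""Independent brute-force oracle for travel-time computations.

Enumerates every 8-neighbor edge of a friction surface explicitly,
computes its cost from first principles (its own haversine, its own
averaging arithmetic), and relaxes with Bellman–Ford until a fixed
point.  Shares no code path with the engine under test.
"""

import math

import numpy as np

_R = 6_371_008.8  # meters, IUGG mean sphere


def _hav(lon1, lat1, lon2, lat2):
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * _R * math.asin(min(1.0, math.sqrt(a)))


def enumerate_edges(surface, averaging="mean_friction", distance_mode=None):
    """All undirected 8-neighbor edges among unmasked cells, with costs."""
    g = surface.grid
    if distance_mode is None:
        distance_mode = "geodesic" if g.crs_kind == "geographic" else "planar"
    nrow, ncol = g.nrow, g.ncol
    f = surface.values
    masked = surface.nodata_mask
    edges = []
    for r in range(nrow):
        for c in range(ncol):
            if masked[r, c]:
                continue
            for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
                r2, c2 = r + dr, c + dc
                if not (0 <= r2 < nrow and 0 <= c2 < ncol) or masked[r2, c2]:
                    continue
                if distance_mode == "planar":
                    d = math.hypot(dc * g.resolution_x, dr * g.resolution_y)
                else:
                    x1 = g.extent.xmin + (c + 0.5) * g.resolution_x
                    y1 = g.extent.ymax - (r + 0.5) * g.resolution_y
                    x2 = g.extent.xmin + (c2 + 0.5) * g.resolution_x
                    y2 = g.extent.ymax - (r2 + 0.5) * g.resolution_y
                    d = _hav(x1, y1, x2, y2)
                fa, fb = f[r, c], f[r2, c2]
                if averaging == "mean_friction":
                    w = d * (fa + fb) / 2.0
                else:
                    w = d / ((1.0 / fa + 1.0 / fb) / 2.0)
                edges.append((r * ncol + c, r2 * ncol + c2, w))
    return edges


def bellman_ford_minutes(surface, source_cells, averaging="mean_friction",
                         distance_mode=None):
    """Multi-source shortest-path minutes via Bellman–Ford relaxation.

    Returns an (nrow, ncol) array with 0 at sources, +inf where
    unreachable, NaN at masked cells.
    """
    g = surface.grid
    n = g.nrow * g.ncol
    edges = enumerate_edges(surface, averaging, distance_mode)
    if edges:
        i = np.array([e[0] for e in edges] + [e[1] for e in edges])
        j = np.array([e[1] for e in edges] + [e[0] for e in edges])
        w = np.array([e[2] for e in edges] * 2)
    else:
        i = j = np.zeros(0, dtype=int)
        w = np.zeros(0)
    dist = np.full(n, np.inf)
    for cell in source_cells:
        dist[cell.row * g.ncol + cell.col] = 0.0
    for _ in range(n):
        nxt = dist.copy()
        np.minimum.at(nxt, j, dist[i] + w)
        if np.array_equal(nxt, dist):
            break
        dist = nxt
    out = dist.reshape(g.nrow, g.ncol)
    out[surface.nodata_mask] = np.nan
    return out
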