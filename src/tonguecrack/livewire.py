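"""Live-wire annotation core: edge-attracted minimum-cost paths.

Crack ground truth is annotated by clicking a few anchor points; the tool
connects consecutive anchors with the cheapest 8-connected pixel path
through a cost field that is low on strong image edges ("magnetic"
behaviour), closes the polygon back to the first anchor, and fills the
enclosed region.  Only the path/rasterisation core lives here — no GUI.

Cost model: ``cost(p) = 1 - g(p)/g_max + eps`` with ``g`` the
central-difference gradient magnitude, ``g_max`` its image maximum (1 if
the image is constant) and ``eps = 0.01``, so costs lie in ``(0, 1+eps]``
and the strongest edge costs ``eps``.  A path pays the cost of every pixel
it enters (the start pixel is free); diagonal steps are weighted by
``sqrt(2)``.  Ties are broken deterministically by the fixed neighbour
scan order, so identical inputs always give identical paths.
"""

from __future__ import annotations

import heapq
import math

import numpy as np
from skimage.draw import polygon as _fill_polygon

__all__ = ["EPSILON", "cost_map", "min_cost_path", "polygon_mask", "AnchorPolygon"]

EPSILON = 0.01

# fixed scan order: lexicographic in (dr, dc); diagonals weighted sqrt(2)
_NEIGHBOURS = [
    (-1, -1, math.sqrt(2)),
    (-1, 0, 1.0),
    (-1, 1, math.sqrt(2)),
    (0, -1, 1.0),
    (0, 1, 1.0),
    (1, -1, math.sqrt(2)),
    (1, 0, 1.0),
    (1, 1, math.sqrt(2)),
]


def cost_map(gray: np.ndarray) -> np.ndarray:
    """Per-pixel traversal cost, low on strong edges (see module docs)."""
    gray = np.asarray(gray, dtype=np.float64)
    gy, gx = np.gradient(gray)
    mag = np.hypot(gy, gx)
    gmax = mag.max()
    if gmax == 0.0:
        return np.full(gray.shape, 1.0 + EPSILON)
    return 1.0 - mag / gmax + EPSILON


def _check_point(costs, p, name):
    r, c = int(p[0]), int(p[1])
    h, w = costs.shape
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"point {name}={p} lies outside the {h}x{w} image")
    return r, c


def min_cost_path(costs: np.ndarray, a, b):
    """Cheapest 8-connected path from ``a`` to ``b`` through ``costs``.

    Returns the path as a list of (row, col) tuples including both
    endpoints; the total cost is the sum of entered-pixel costs with
    diagonal steps weighted sqrt(2).  Dijkstra with a deterministic
    tie-break.
    """
    costs = np.asarray(costs, dtype=np.float64)
    a = _check_point(costs, a, "a")
    b = _check_point(costs, b, "b")
    if a == b:
        return [a]
    h, w = costs.shape
    dist = np.full((h, w), np.inf)
    prev = np.full((h, w, 2), -1, dtype=np.int32)
    done = np.zeros((h, w), dtype=bool)
    dist[a] = 0.0
    heap = [(0.0, a)]
    while heap:
        d, (r, c) = heapq.heappop(heap)
        if done[r, c]:
            continue
        done[r, c] = True
        if (r, c) == b:
            break
        for dr, dc, wgt in _NEIGHBOURS:
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w and not done[nr, nc]:
                nd = d + costs[nr, nc] * wgt
                if nd < dist[nr, nc]:
                    dist[nr, nc] = nd
                    prev[nr, nc] = (r, c)
                    heapq.heappush(heap, (nd, (nr, nc)))
    if not done[b]:
        raise RuntimeError("target unreachable (should not happen on a grid)")
    path = [b]
    while path[-1] != a:
        r, c = path[-1]
        path.append(tuple(int(v) for v in prev[r, c]))
    path.reverse()
    return path


def path_cost(costs: np.ndarray, path) -> float:
    """Total cost of a path under the entered-pixel convention."""
    costs = np.asarray(costs, dtype=np.float64)
    total = 0.0
    for (r0, c0), (r1, c1) in zip(path[:-1], path[1:]):
        step = math.sqrt(2) if (r0 != r1 and c0 != c1) else 1.0
        total += costs[r1, c1] * step
    return total


class AnchorPolygon:
    """Ordered anchor points plus the closed minimum-cost pixel chain
    through them (in anchor order, wrapping back to the first)."""

    def __init__(self, anchors, chain):
        self.anchors = [tuple(int(v) for v in a) for a in anchors]
        self.chain = chain

    def __len__(self):
        return len(self.chain)


def trace_polygon(gray: np.ndarray, anchors) -> AnchorPolygon:
    """Closed 8-connected chain visiting the anchors in order."""
    if len(anchors) < 3:
        raise ValueError(f"need at least 3 anchors, got {len(anchors)}")
    costs = cost_map(gray)
    pts = [tuple(int(v) for v in a) for a in anchors]
    chain = []
    for i, start in enumerate(pts):
        end = pts[(i + 1) % len(pts)]
        leg = min_cost_path(costs, start, end)
        chain.extend(leg if i == 0 else leg[1:])
    if len(chain) > 1 and chain[-1] == chain[0]:
        chain.pop()
    return AnchorPolygon(pts, chain)


def polygon_mask(gray: np.ndarray, anchors) -> np.ndarray:
    """Binary mask of the region enclosed by the live-wire polygon.

    The closed chain through the anchors is rasterised, the interior is
    filled with the even-odd scanline rule, and boundary pixels are
    included.  Degenerate (e.g. collinear) polygons reduce to the chain
    pixels themselves.
    """
    poly = trace_polygon(gray, anchors)
    rows = np.array([p[0] for p in poly.chain])
    cols = np.array([p[1] for p in poly.chain])
    mask = np.zeros(np.asarray(gray).shape[:2], dtype=np.uint8)
    rr, cc = _fill_polygon(rows, cols, shape=mask.shape)
    mask[rr, cc] = 1
    mask[rows, cols] = 1
    return mask
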