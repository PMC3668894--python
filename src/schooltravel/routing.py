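"""Deterministic shortest routes and mile-band classification on the road grid.

Coordinates are integer cell positions ``(x, y)`` with roads at every
multiple of ``cells_per_segment`` along each axis. A point is *on* the grid
iff at least one coordinate is such a multiple. Children keep the same route
every day, so route choice must be canonical: among equal-length paths we
always prefer travelling along the origin's horizontal road first, then
falling back to the other elementary path shapes in a fixed order.

Because a mid-segment point can only leave its road at an intersection, the
true network distance can exceed plain Manhattan distance when both endpoints
sit mid-segment on parallel roads with no cross-road between them; the router
handles that detour case exactly. Whenever either endpoint lies on an
intersection (e.g. the evenly-placed schools) the network distance equals the
Manhattan distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import METERS_PER_MILE

__all__ = [
    "DistanceBand",
    "BANDS",
    "Route",
    "band_of",
    "band_index",
    "network_distance_cells",
    "shortest_route",
    "route_mean_safety",
]


@dataclass(frozen=True)
class DistanceBand:
    """Half-open mile interval [lo_miles, hi_miles) used for reporting."""

    label: str
    lo_miles: float
    hi_miles: float

    def __contains__(self, distance_miles: float) -> bool:
        return self.lo_miles <= distance_miles < self.hi_miles


#: the survey reporting bands; they partition [0, inf)
BANDS: tuple[DistanceBand, ...] = (
    DistanceBand("<0.25", 0.0, 0.25),
    DistanceBand("0.25-0.5", 0.25, 0.5),
    DistanceBand("0.5-1", 0.5, 1.0),
    DistanceBand("1-2", 1.0, 2.0),
    DistanceBand(">=2", 2.0, float("inf")),
)

BAND_LABELS: tuple[str, ...] = tuple(b.label for b in BANDS)
_BAND_EDGES = np.array([b.lo_miles for b in BANDS[1:]])


def band_of(distance_miles: float) -> DistanceBand:
    """Classify a distance into its half-open mile band."""
    if distance_miles < 0:
        raise ValueError(f"distance must be >= 0, got {distance_miles}")
    return BANDS[int(np.searchsorted(_BAND_EDGES, distance_miles, side="right"))]


def band_index(distance_miles) -> np.ndarray:
    """Vectorised band index (0..4) for an array of distances in miles."""
    d = np.asarray(distance_miles)
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    return np.searchsorted(_BAND_EDGES, d, side="right")


@dataclass(frozen=True)
class Route:
    """An ordered walk along road cells from household to school, inclusive."""

    cells: np.ndarray  # cell ids along the route
    distance_m: float
    distance_miles: float

    def __len__(self) -> int:
        return len(self.cells)


def _span_with_connector(p, q, c):
    """Shortest along-axis travel from offset p to q for a path that must pass
    through a road line (multiple of c) on this axis; returns (length, line)."""
    lo, hi = (p, q) if p <= q else (q, p)
    first = -(-lo // c) * c  # smallest multiple of c >= lo
    if first <= hi:
        return hi - lo, first
    below = (lo // c) * c
    above = first
    len_below = (p - below) + (q - below)
    len_above = (above - p) + (above - q)
    if len_below <= len_above:
        return len_below, below
    return len_above, above


def network_distance_cells(ox, oy, dx, dy, cells_per_segment: int):
    """Network (along-roads) distance in cell steps between on-grid points.

    Vectorised over numpy arrays. Both endpoints must lie on roads; the
    result is the exact shortest-path length on the grid graph.
    """
    c = cells_per_segment
    ox, oy, dx, dy = (np.asarray(a, dtype=np.int64) for a in (ox, oy, dx, dy))
    adx = np.abs(ox - dx)
    ady = np.abs(oy - dy)
    manhattan = adx + ady

    o_on_h = oy % c == 0  # origin on a horizontal road
    o_on_v = ox % c == 0
    d_on_h = dy % c == 0
    d_on_v = dx % c == 0

    best = np.full(np.broadcast(ox, oy, dx, dy).shape, np.iinfo(np.int64).max)
    # L-paths achieve Manhattan distance outright
    feasible_L = (o_on_h & d_on_v) | (o_on_v & d_on_h)
    best = np.where(feasible_L, manhattan, best)
    # same-road direct paths
    same_v = o_on_v & d_on_v & (ox == dx)
    same_h = o_on_h & d_on_h & (oy == dy)
    best = np.where(same_v, ady, best)
    best = np.where(same_h, adx, best)
    # Z-paths between parallel roads may need a detour to reach a cross-road
    if np.any(o_on_v & d_on_v) or np.any(o_on_h & d_on_h):
        lo = np.minimum(oy, dy)
        hi = np.maximum(oy, dy)
        first = -(-lo // c) * c
        span_y = np.where(
            first <= hi,
            ady,
            np.minimum((oy - (lo // c) * c) + (dy - (lo // c) * c),
                       (first - oy) + (first - dy)),
        )
        best = np.where(o_on_v & d_on_v, np.minimum(best, adx + span_y), best)
        lo = np.minimum(ox, dx)
        hi = np.maximum(ox, dx)
        first = -(-lo // c) * c
        span_x = np.where(
            first <= hi,
            adx,
            np.minimum((ox - (lo // c) * c) + (dx - (lo // c) * c),
                       (first - ox) + (first - dx)),
        )
        best = np.where(o_on_h & d_on_h, np.minimum(best, ady + span_x), best)
    return best


def _leg(x0, y0, x1, y1):
    """Cell coordinates of a straight road leg, endpoint included, start excluded."""
    if x0 == x1 and y0 == y1:
        return np.empty((0, 2), dtype=np.int64)
    if x0 == x1:
        step = 1 if y1 > y0 else -1
        ys = np.arange(y0 + step, y1 + step, step, dtype=np.int64)
        return np.column_stack([np.full_like(ys, x0), ys])
    if y0 == y1:
        step = 1 if x1 > x0 else -1
        xs = np.arange(x0 + step, x1 + step, step, dtype=np.int64)
        return np.column_stack([xs, np.full_like(xs, y0)])
    raise ValueError("leg must be axis-aligned")


def shortest_route(grid, from_cell: int, to_cell: int) -> Route:
    """Canonical shortest route between two road cells of ``grid``.

    Tie-break among equal-length shortest paths, in order of preference:
    direct same-road path; origin's horizontal road first, then the target's
    vertical road; origin's vertical road first, then the target's horizontal
    road; Z-path via a horizontal cross-road (smallest feasible road line);
    Z-path via a vertical cross-road.
    """
    c = grid.config.cells_per_segment
    ox, oy = grid.cell_xy(from_cell)
    dx, dy = grid.cell_xy(to_cell)

    candidates: list[tuple[int, list[tuple[int, int]]]] = []
    o_on_h, o_on_v = oy % c == 0, ox % c == 0
    d_on_h, d_on_v = dy % c == 0, dx % c == 0
    if o_on_v and d_on_v and ox == dx:
        candidates.append((abs(dy - oy), [(ox, dy)]))
    if o_on_h and d_on_h and oy == dy:
        candidates.append((abs(dx - ox), [(dx, oy)]))
    if o_on_h and d_on_v:
        candidates.append((abs(dx - ox) + abs(dy - oy), [(dx, oy), (dx, dy)]))
    if o_on_v and d_on_h:
        candidates.append((abs(dx - ox) + abs(dy - oy), [(ox, dy), (dx, dy)]))
    if o_on_v and d_on_v:
        span, line = _span_with_connector(oy, dy, c)
        candidates.append((abs(dx - ox) + span, [(ox, line), (dx, line), (dx, dy)]))
    if o_on_h and d_on_h:
        span, line = _span_with_connector(ox, dx, c)
        candidates.append((abs(dx - ox) + span, [(line, oy), (line, dy), (dx, dy)]))
    if not candidates:
        raise ValueError("endpoints are not on the road grid")

    best_len = min(length for length, _ in candidates)
    waypoints = next(wp for length, wp in candidates if length == best_len)

    coords = [np.array([[ox, oy]], dtype=np.int64)]
    x, y = ox, oy
    for wx, wy in waypoints:
        coords.append(_leg(x, y, wx, wy))
        x, y = wx, wy
    xy = np.concatenate(coords)
    cells = grid.ids_at(xy[:, 0], xy[:, 1])
    distance_m = (len(cells) - 1) * grid.config.cell_size_m
    return Route(cells=cells, distance_m=distance_m,
                 distance_miles=distance_m / METERS_PER_MILE)


def route_mean_safety(grid, route: Route) -> float:
    """Mean traffic safety over every cell of the route, endpoints included."""
    if len(route) == 0:
        raise ValueError("route must contain at least one cell")
    return float(grid.S[route.cells].mean())
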