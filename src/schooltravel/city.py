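"""Construction of the synthetic grid city: roads, schools, households.

The city is a square of ``city_size_m`` metres with a uniform grid of roads
discretised into 20 m road cells. Households and schools occupy distinct road
cells. Schools are placed according to a :class:`~schooltravel.config.ScenarioSpec`
(even zone centres, random citywide, or random within zones) and each child is
assigned a school by the scenario's catchment rule, after which the child's
fixed walking route and network distance are computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .config import (
    METERS_PER_MILE,
    CityConfig,
    ConfigurationError,
    InterventionSpec,
    ScenarioSpec,
)
from . import routing
from .routing import Route, network_distance_cells, shortest_route


def _cell_safety_scalar(w: float) -> float:
    # local copy to avoid a circular import with dynamics
    return min(max(1.0 - w ** -0.6, 0.0), 1.0)


@dataclass
class RoadGrid:
    """Road cells with per-cell walker count ``W``, safety ``S`` and boost.

    Cells are indexed by a dense integer id; ``xs``/``ys`` give the integer
    cell coordinates of each id and ``_id_lookup`` maps coordinates back to
    ids (-1 off-road). Intersection cells are shared between their horizontal
    and vertical road, so they appear exactly once.
    """

    config: CityConfig
    xs: np.ndarray
    ys: np.ndarray
    _id_lookup: np.ndarray
    W: np.ndarray = field(default=None)  # walkers per cell per day (real-valued)
    S: np.ndarray = field(default=None)  # traffic safety in [0, 1]
    boost: np.ndarray = field(default=None)  # intervention increment

    def __post_init__(self) -> None:
        n = len(self.xs)
        bg = self.config.background_walkers_per_cell
        if self.W is None:
            self.W = np.full(n, bg, dtype=float)
        if self.S is None:
            self.S = np.full(n, _cell_safety_scalar(bg), dtype=float)
        if self.boost is None:
            self.boost = np.zeros(n, dtype=float)

    @property
    def n_cells(self) -> int:
        return len(self.xs)

    def cell_xy(self, cell_id: int) -> tuple[int, int]:
        return int(self.xs[cell_id]), int(self.ys[cell_id])

    def ids_at(self, xs, ys) -> np.ndarray:
        """Cell ids at integer coordinates; raises if any is off-road."""
        xs = np.asarray(xs, dtype=np.int64)
        ys = np.asarray(ys, dtype=np.int64)
        p = self.config.positions_per_road
        if np.any((xs < 0) | (xs >= p) | (ys < 0) | (ys >= p)):
            raise KeyError("coordinates outside the city")
        ids = self._id_lookup[xs, ys]
        if np.any(ids < 0):
            raise KeyError("coordinates not on a road")
        return ids

    def id_at(self, x: int, y: int) -> int:
        return int(self.ids_at([x], [y])[0])

    def meters_xy(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell coordinates in metres."""
        s = self.config.cell_size_m
        return self.xs * s, self.ys * s


@dataclass
class Schools:
    """Column-oriented table of schools (one row per school, id = row)."""

    cell: np.ndarray        # road-cell id
    x: np.ndarray           # cell coordinates
    y: np.ndarray
    enrolment: np.ndarray   # N, children enrolled
    walkers_today: np.ndarray      # N_w'
    walkers_yesterday: np.ndarray  # N_w
    zone: np.ndarray        # flat zone index, -1 if not zone-based

    @classmethod
    def from_cells(cls, grid: RoadGrid, cells: np.ndarray,
                   zones: Optional[np.ndarray] = None) -> "Schools":
        cells = np.asarray(cells, dtype=np.int64)
        n = len(cells)
        if zones is None:
            zones = np.full(n, -1, dtype=np.int64)
        return cls(
            cell=cells,
            x=grid.xs[cells].astype(np.int64),
            y=grid.ys[cells].astype(np.int64),
            enrolment=np.zeros(n, dtype=np.int64),
            walkers_today=np.zeros(n, dtype=np.int64),
            walkers_yesterday=np.zeros(n, dtype=np.int64),
            zone=np.asarray(zones, dtype=np.int64),
        )

    def __len__(self) -> int:
        return len(self.cell)


@dataclass
class Households:
    """Column-oriented table of households, one child each (id = row).

    ``concern`` is the traffic-safety threshold C_t (fixed after
    initialisation); ``attitude`` is the child's walking attitude A_w,
    updated daily by the school social-norm feedback.
    """

    cell: np.ndarray
    x: np.ndarray
    y: np.ndarray
    concern: np.ndarray
    attitude: np.ndarray
    school_id: np.ndarray
    distance_miles: np.ndarray
    routes: list[Route] = field(default_factory=list)
    # flattened route representation for vectorised daily updates
    route_flat: np.ndarray = field(default=None)
    route_offsets: np.ndarray = field(default=None)
    route_lens: np.ndarray = field(default=None)

    def __len__(self) -> int:
        return len(self.cell)


def build_grid(config: CityConfig) -> RoadGrid:
    """Construct the road grid with safety initialised from background walkers."""
    p = config.positions_per_road
    c = config.cells_per_segment
    coords_x, coords_y = np.meshgrid(np.arange(p), np.arange(p), indexing="ij")
    on_road = (coords_x % c == 0) | (coords_y % c == 0)
    xs = coords_x[on_road].astype(np.int64)
    ys = coords_y[on_road].astype(np.int64)
    lookup = np.full((p, p), -1, dtype=np.int64)
    lookup[xs, ys] = np.arange(len(xs))
    return RoadGrid(config=config, xs=xs, ys=ys, _id_lookup=lookup)


def zone_of(x_cells, y_cells, layout: tuple[int, int], config: CityConfig) -> np.ndarray:
    """Flat zone index (zx * ny + zy) of cells; boundary cells join the
    lower-indexed zone."""
    nx, ny = layout
    span = config.positions_per_road - 1  # city width in cell steps
    x = np.asarray(x_cells, dtype=np.int64)
    y = np.asarray(y_cells, dtype=np.int64)
    zx = x * nx // span
    zy = y * ny // span
    zx = np.where((x * nx % span == 0) & (zx > 0), zx - 1, zx)
    zy = np.where((y * ny % span == 0) & (zy > 0), zy - 1, zy)
    zx = np.minimum(zx, nx - 1)
    zy = np.minimum(zy, ny - 1)
    return zx * ny + zy


def _school_zones(spec: ScenarioSpec) -> list[int]:
    """Flat zone indices that receive a school, in school-id order."""
    nx, ny = spec.zone_layout
    zones = []
    for zx in range(nx):
        for zy in range(ny):
            if (nx, ny) == (3, 3) and (zx, zy) == (1, 1):
                continue  # centre zone of the 3x3 layout has no school
            zones.append(zx * ny + zy)
    return zones


def zone_centers_m(spec: ScenarioSpec, config: CityConfig) -> np.ndarray:
    """Geometric centres (metres) of the school zones, in school-id order."""
    nx, ny = spec.zone_layout
    w = config.city_size_m / nx
    h = config.city_size_m / ny
    centers = []
    for z in _school_zones(spec):
        zx, zy = divmod(z, ny)
        centers.append(((zx + 0.5) * w, (zy + 0.5) * h))
    return np.array(centers)


def _snap_to_road(grid: RoadGrid, x_m: float, y_m: float) -> int:
    """Road cell nearest (Euclidean) to a point in metres; ties go to the
    lexicographically smallest (x, y) cell coordinate."""
    mx, my = grid.meters_xy()
    d2 = (mx - x_m) ** 2 + (my - y_m) ** 2
    best = d2.min()
    tied = np.flatnonzero(d2 == best)
    order = np.lexsort((grid.ys[tied], grid.xs[tied]))
    return int(tied[order[0]])


def place_schools(grid: RoadGrid, spec: ScenarioSpec,
                  rng: np.random.Generator) -> Schools:
    """Place schools on road cells according to the scenario's placement rule."""
    config = grid.config
    if spec.placement_rule == "even_zone_centers":
        centers = zone_centers_m(spec, config)
        cells = np.array([_snap_to_road(grid, cx, cy) for cx, cy in centers])
        zones = np.array(_school_zones(spec))
    elif spec.placement_rule == "random_citywide":
        cells = rng.choice(grid.n_cells, size=spec.n_schools, replace=False)
        zones = np.full(spec.n_schools, -1)
    elif spec.placement_rule == "random_within_zone":
        zone_ids = zone_of(grid.xs, grid.ys, spec.zone_layout, config)
        zones = np.array(_school_zones(spec))
        cells = np.array([
            rng.choice(np.flatnonzero(zone_ids == z)) for z in zones
        ])
    else:  # pragma: no cover - guarded by ScenarioSpec validation
        raise ConfigurationError(f"unknown placement rule {spec.placement_rule!r}")
    return Schools.from_cells(grid, cells, zones)


def place_households(grid: RoadGrid, spec: ScenarioSpec, rng: np.random.Generator,
                     schools: Optional[Schools] = None) -> Households:
    """Scatter households uniformly on road cells not occupied by a school.

    Safety concern C_t and walking attitude A_w are independent Uniform(0,1)
    draws per household.
    """
    occupied = np.zeros(grid.n_cells, dtype=bool)
    if schools is not None:
        occupied[schools.cell] = True
    free = np.flatnonzero(~occupied)
    if spec.n_households > len(free):
        raise ConfigurationError(
            f"{spec.n_households} households cannot fit on {len(free)} free road cells"
        )
    cells = rng.choice(free, size=spec.n_households, replace=False)
    concern = rng.uniform(0.0, 1.0, size=spec.n_households)
    attitude = rng.uniform(0.0, 1.0, size=spec.n_households)
    n = spec.n_households
    return Households(
        cell=cells,
        x=grid.xs[cells].astype(np.int64),
        y=grid.ys[cells].astype(np.int64),
        concern=concern,
        attitude=attitude,
        school_id=np.full(n, -1, dtype=np.int64),
        distance_miles=np.zeros(n, dtype=float),
    )


def assign_schools(households: Households, schools: Schools, spec: ScenarioSpec,
                   grid: RoadGrid) -> Households:
    """Assign each child a school, compute the fixed route, update enrolments."""
    config = grid.config
    c = config.cells_per_segment
    n_hh = len(households)

    if spec.catchment_rule == "nearest_school":
        dists = np.empty((n_hh, len(schools)), dtype=np.int64)
        for s in range(len(schools)):
            dists[:, s] = network_distance_cells(
                households.x, households.y, schools.x[s], schools.y[s], c
            )
        school_id = np.argmin(dists, axis=1)  # ties -> lowest school id
    elif spec.catchment_rule == "own_zone":
        if spec.zone_layout is None:
            raise ConfigurationError("own_zone catchment requires a zone layout")
        hh_zone = zone_of(households.x, households.y, spec.zone_layout, config)
        zone_to_school = {int(z): s for s, z in enumerate(schools.zone)}
        missing = set(np.unique(hh_zone)) - set(zone_to_school)
        if missing:
            raise ConfigurationError(
                f"own_zone catchment: zones {sorted(missing)} have no school"
            )
        school_id = np.array([zone_to_school[int(z)] for z in hh_zone])
    else:  # pragma: no cover - guarded by ScenarioSpec validation
        raise ConfigurationError(f"unknown catchment rule {spec.catchment_rule!r}")

    households.school_id = school_id.astype(np.int64)
    routes = [
        shortest_route(grid, int(households.cell[i]), int(schools.cell[school_id[i]]))
        for i in range(n_hh)
    ]
    households.routes = routes
    households.distance_miles = np.array([r.distance_miles for r in routes])
    households.route_lens = np.array([len(r) for r in routes], dtype=np.int64)
    households.route_offsets = np.concatenate(
        [[0], np.cumsum(households.route_lens)[:-1]]
    )
    households.route_flat = np.concatenate([r.cells for r in routes])
    schools.enrolment = np.bincount(school_id, minlength=len(schools)).astype(np.int64)
    return households


@dataclass
class City:
    """A fully realised city: grid, schools, households, routes, boosts."""

    config: CityConfig
    scenario: ScenarioSpec
    grid: RoadGrid
    schools: Schools
    households: Households
    intervention: Optional[InterventionSpec] = None

    @property
    def n_children(self) -> int:
        return len(self.households)


def build_city(config: CityConfig, scenario: Optional[ScenarioSpec] = None,
               intervention: Optional[InterventionSpec] = None) -> City:
    """Build a seeded city ready for simulation.

    The scenario defaults to the baseline layout (evenly placed schools,
    nearest-school catchment) with the config's school and household counts.
    All randomness comes from ``config.seed``.
    """
    if scenario is None:
        scenario = ScenarioSpec(n_schools=config.n_schools,
                                n_households=config.n_households)
    rng = np.random.default_rng(config.seed)
    grid = build_grid(config)
    schools = place_schools(grid, scenario, rng)
    households = place_households(grid, scenario, rng, schools)
    assign_schools(households, schools, scenario, grid)
    if intervention is not None:
        from .interventions import boost_field
        grid.boost = boost_field(grid, schools, intervention)
    return City(config=config, scenario=scenario, grid=grid,
                schools=schools, households=households, intervention=intervention)


def dump_city(city: City, path: str | Path, include_routes: bool = False) -> None:
    """Write a JSON snapshot of the city for inspection or fixtures."""
    s = city.config.cell_size_m
    out = {
        "config": {
            **{k: getattr(city.config, k) for k in CityConfig.__dataclass_fields__},
        },
        "scenario": {
            "placement_rule": city.scenario.placement_rule,
            "catchment_rule": city.scenario.catchment_rule,
            "n_schools": city.scenario.n_schools,
            "n_households": city.scenario.n_households,
            "zone_layout": list(city.scenario.zone_layout)
            if city.scenario.zone_layout else None,
        },
        "schools": [
            {
                "id": i,
                "x_m": float(city.schools.x[i] * s),
                "y_m": float(city.schools.y[i] * s),
                "enrolment": int(city.schools.enrolment[i]),
            }
            for i in range(len(city.schools))
        ],
        "households": [
            {
                "id": i,
                "x_m": float(city.households.x[i] * s),
                "y_m": float(city.households.y[i] * s),
                "concern": float(city.households.concern[i]),
                "attitude": float(city.households.attitude[i]),
                "school_id": int(city.households.school_id[i]),
                "distance_miles": float(city.households.distance_miles[i]),
            }
            for i in range(len(city.households))
        ],
    }
    if include_routes:
        for i, rec in enumerate(out["households"]):
            route = city.households.routes[i]
            rec["route_xy_m"] = [
                [float(city.grid.xs[cid] * s), float(city.grid.ys[cid] * s)]
                for cid in route.cells
            ]
    Path(path).write_text(json.dumps(out, indent=1))
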