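"""Configuration objects for the grid-city school-travel model.

The model lives in a synthetic square city whose road network is a uniform
grid. All spatial quantities are expressed in integer *cell units* internally
(one cell = ``cell_size_m`` metres on the ground); distances handed to the
behavioural model are converted to miles, the unit in which the distance-decay
parameter ``beta`` and the reporting bands are defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional

import yaml

#: metres per statute mile, used for every distance conversion in the package
METERS_PER_MILE = 1609.34

PLACEMENT_RULES = ("even_zone_centers", "random_citywide", "random_within_zone")
CATCHMENT_RULES = ("nearest_school", "own_zone")

#: canonical zone partitions (nx columns, ny rows) keyed by school count;
#: the 8-school layout is a 3x3 partition whose centre zone holds no school
ZONE_LAYOUTS = {2: (2, 1), 4: (2, 2), 6: (2, 3), 8: (3, 3)}


class ConfigurationError(ValueError):
    """A configuration field violates a model invariant."""


@dataclass(frozen=True)
class CityConfig:
    """Geometry, population and behavioural parameters of the synthetic city.

    Defaults describe an 8 km x 8 km city with 41 vertical and 41 horizontal
    roads. Each road is divided by intersections into 40 segments of 10 cells,
    so one segment spans 200 m and one cell spans 20 m. Roads therefore sit
    every ``cells_per_segment`` cell positions and a road runs over
    ``segments_per_road * cells_per_segment + 1`` positions end to end.
    """

    city_size_m: float = 8000.0
    n_roads_per_axis: int = 41
    segments_per_road: int = 40
    cells_per_segment: int = 10
    cell_size_m: float = 20.0
    n_schools: int = 4
    n_households: int = 3000
    background_walkers_per_cell: float = 1.5
    beta: float = 1.6
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_roads_per_axis": self.n_roads_per_axis,
            "segments_per_road": self.segments_per_road,
            "cells_per_segment": self.cells_per_segment,
            "n_schools": self.n_schools,
            "n_households": self.n_households,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        if self.city_size_m <= 0 or self.cell_size_m <= 0:
            raise ConfigurationError("city_size_m and cell_size_m must be positive")
        if self.background_walkers_per_cell <= 0:
            raise ConfigurationError(
                f"background_walkers_per_cell must be > 0, got {self.background_walkers_per_cell}"
            )
        if self.beta <= 0:
            raise ConfigurationError(f"beta must be > 0, got {self.beta}")
        span = self.segments_per_road * self.cells_per_segment * self.cell_size_m
        if span > self.city_size_m:
            raise ConfigurationError(
                "segments_per_road * cells_per_segment * cell_size_m "
                f"({span}) exceeds city_size_m ({self.city_size_m})"
            )
        if self.n_roads_per_axis != self.segments_per_road + 1:
            raise ConfigurationError(
                "n_roads_per_axis must equal segments_per_road + 1 so that roads "
                f"coincide with segment boundaries; got {self.n_roads_per_axis} "
                f"roads and {self.segments_per_road} segments"
            )

    @property
    def positions_per_road(self) -> int:
        """Cell positions a road spans, both endpoints included."""
        return self.segments_per_road * self.cells_per_segment + 1

    @property
    def n_road_cells(self) -> int:
        """Unique road cells (intersections counted once)."""
        r, p = self.n_roads_per_axis, self.positions_per_road
        return 2 * r * p - r * r

    def with_seed(self, seed: int) -> "CityConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class ScenarioSpec:
    """How schools are placed and which school each child attends.

    ``placement_rule``:
      * ``even_zone_centers`` — one school per zone, snapped to the road cell
        nearest the zone's geometric centre (the evenly-distributed layouts);
      * ``random_citywide`` — schools on distinct road cells drawn uniformly
        over the whole city;
      * ``random_within_zone`` — one school per zone on a road cell drawn
        uniformly within that zone.

    ``catchment_rule``:
      * ``nearest_school`` — each child attends the school at minimal network
        distance (ties broken by lowest school id);
      * ``own_zone`` — each child attends the school of its household's zone.
    """

    placement_rule: str = "even_zone_centers"
    catchment_rule: str = "nearest_school"
    n_schools: int = 4
    n_households: int = 3000
    zone_layout: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.placement_rule not in PLACEMENT_RULES:
            raise ConfigurationError(
                f"unknown placement_rule {self.placement_rule!r}; expected one of {PLACEMENT_RULES}"
            )
        if self.catchment_rule not in CATCHMENT_RULES:
            raise ConfigurationError(
                f"unknown catchment_rule {self.catchment_rule!r}; expected one of {CATCHMENT_RULES}"
            )
        if self.n_schools <= 0 or self.n_households <= 0:
            raise ConfigurationError("n_schools and n_households must be positive")
        layout = self.zone_layout
        if layout is None:
            if self.placement_rule != "random_citywide":
                if self.n_schools not in ZONE_LAYOUTS:
                    raise ConfigurationError(
                        f"no canonical zone layout for {self.n_schools} schools; "
                        "provide zone_layout explicitly"
                    )
                layout = ZONE_LAYOUTS[self.n_schools]
            object.__setattr__(self, "zone_layout", layout)
        if layout is not None:
            nx, ny = layout
            n_zones = nx * ny
            if nx == 3 and ny == 3:
                n_zones -= 1  # centre zone of the 3x3 layout holds no school
            if self.placement_rule != "random_citywide" and n_zones != self.n_schools:
                raise ConfigurationError(
                    f"zone_layout {layout} provides {n_zones} school zones "
                    f"but n_schools = {self.n_schools}"
                )

    @property
    def uses_zones(self) -> bool:
        return self.zone_layout is not None


@dataclass(frozen=True)
class InterventionSpec:
    """A radius-graded traffic-safety boost around every school.

    The safety of every road cell within ``radius_miles`` (Euclidean) of a
    school is raised by ``a * (0.5 / radius_miles)**2``, so the product of
    boost intensity and targeted area is the same for every radius: the levels
    studied are the full boost ``a`` within 0.5 miles, ``~a/2`` within
    0.71 miles and ``a/4`` within 1 mile.
    """

    radius_miles: float = 0.5
    boost_a: float = 0.1

    def __post_init__(self) -> None:
        if self.radius_miles <= 0:
            raise ConfigurationError(f"radius_miles must be > 0, got {self.radius_miles}")
        if not 0.0 <= self.applied_boost <= 1.0:
            raise ConfigurationError(
                f"applied boost {self.applied_boost:.4f} outside [0, 1]; "
                "reduce boost_a or enlarge radius_miles"
            )

    @property
    def applied_boost(self) -> float:
        """Per-cell safety increment after the intensity-area rescaling."""
        return self.boost_a * (0.5 / self.radius_miles) ** 2


def load_config(path: str | Path) -> tuple[CityConfig, ScenarioSpec, Optional[InterventionSpec]]:
    """Read a YAML/JSON config file mirroring the dataclass field names.

    Recognised top-level keys: the ``CityConfig`` fields, a ``scenario``
    block (``ScenarioSpec`` fields) and an optional ``intervention`` block
    (``InterventionSpec`` fields).
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    scenario_raw = dict(raw.pop("scenario", {}) or {})
    intervention_raw = raw.pop("intervention", None)
    known = set(CityConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    config = CityConfig(**raw)
    scenario_raw.setdefault("n_schools", config.n_schools)
    scenario_raw.setdefault("n_households", config.n_households)
    if scenario_raw.get("zone_layout") is not None:
        scenario_raw["zone_layout"] = tuple(scenario_raw["zone_layout"])
    scenario = ScenarioSpec(**scenario_raw)
    intervention = InterventionSpec(**intervention_raw) if intervention_raw else None
    return config, scenario, intervention


def config_to_dict(config: CityConfig, scenario: ScenarioSpec,
                   intervention: Optional[InterventionSpec] = None) -> dict:
    out = asdict(config)
    out["scenario"] = asdict(scenario)
    if scenario.zone_layout is not None:
        out["scenario"]["zone_layout"] = list(scenario.zone_layout)
    if intervention is not None:
        out["intervention"] = asdict(intervention)
    return out
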