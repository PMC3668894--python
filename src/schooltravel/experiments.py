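"""Reproducible experiment suites: scenario contrasts, density grids, safety
interventions and calibration, with seeded replicates and CSV/JSON reporting.

Scenario comparisons are replicate-paired: scenario ``k``'s replicate ``i``
uses the same seed as every other scenario's replicate ``i``, so household
positions and attributes are shared wherever the scenario definition allows
and contrasts reflect policy, not sampling noise.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import CityConfig, ScenarioSpec, InterventionSpec, config_to_dict
from .city import build_city
from .dynamics import ReplicateSummary, run_replicates
from .calibration import (
    CalibrationTarget, calibrate, nhts_reference,
    DEFAULT_BETA_GRID, DEFAULT_BG_GRID,
)
from .interventions import intervention_experiment
from .routing import BAND_LABELS

__all__ = [
    "SCENARIOS",
    "scenario_spec",
    "run_scenario",
    "run_table2",
    "run_table3",
    "run_interventions",
    "run_calibration",
    "write_outputs",
]

#: the four school-location / catchment policies contrasted in the scenario suite
SCENARIOS: dict[str, dict] = {
    "B": dict(placement_rule="even_zone_centers", catchment_rule="nearest_school"),
    "S1": dict(placement_rule="random_citywide", catchment_rule="nearest_school"),
    "S2": dict(placement_rule="random_within_zone", catchment_rule="own_zone"),
    "S3": dict(placement_rule="random_within_zone", catchment_rule="nearest_school"),
}


def scenario_spec(name: str, config: CityConfig) -> ScenarioSpec:
    """The named policy scenario at the config's school/household counts."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; expected one of {list(SCENARIOS)}")
    return ScenarioSpec(n_schools=config.n_schools,
                        n_households=config.n_households, **SCENARIOS[name])


def config_hash(config: CityConfig, scenario: Optional[ScenarioSpec] = None,
                intervention: Optional[InterventionSpec] = None) -> str:
    """Short provenance hash of the full configuration."""
    payload = config_to_dict(
        config,
        scenario or ScenarioSpec(n_schools=config.n_schools,
                                 n_households=config.n_households),
        intervention,
    )
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_scenario(config: CityConfig, scenario: ScenarioSpec,
                 n_reps: int = 20, base_seed: int = 0,
                 intervention: Optional[InterventionSpec] = None,
                 max_days: int = 100) -> ReplicateSummary:
    """Run one scenario over seeded replicates."""
    return run_replicates(
        lambda seed: build_city(config.with_seed(seed), scenario, intervention),
        n_reps=n_reps, base_seed=base_seed, max_days=max_days,
    )


def _summary_row(name: str, config: CityConfig, scenario: ScenarioSpec,
                 summary: ReplicateSummary, base_seed: int) -> dict:
    row = {
        "scenario": name,
        "n_schools": scenario.n_schools,
        "n_households": scenario.n_households,
        "percent_walking": summary.mean_percent_walking,
        "percent_walking_min": summary.min_percent_walking,
        "percent_walking_max": summary.max_percent_walking,
    }
    for label in BAND_LABELS:
        row[f"pop_share[{label}]"] = summary.mean_band_population_shares[label]
    for label in BAND_LABELS:
        row[f"walk_rate[{label}]"] = summary.mean_band_walk_rates[label]
    row["n_reps"] = summary.n_reps
    row["base_seed"] = base_seed
    row["config_hash"] = config_hash(config, scenario)
    return row


def run_table2(n_reps: int = 20, base_seed: int = 0,
               config: Optional[CityConfig] = None,
               max_days: int = 100) -> pd.DataFrame:
    """The four-scenario contrast: mean percent walking and the distance
    distribution of children, one row per scenario (B, S1, S2, S3)."""
    if config is None:
        config = CityConfig()
    rows = []
    for name in SCENARIOS:
        spec = scenario_spec(name, config)
        summary = run_scenario(config, spec, n_reps=n_reps, base_seed=base_seed,
                               max_days=max_days)
        rows.append(_summary_row(name, config, spec, summary, base_seed))
    return pd.DataFrame(rows)


def run_table3(school_counts: Sequence[int] = (2, 4, 6, 8),
               household_counts: Sequence[int] = (1500, 3000, 4500, 6000),
               n_reps: int = 20, base_seed: int = 0,
               config: Optional[CityConfig] = None,
               max_days: int = 100) -> pd.DataFrame:
    """School-size x population-density grid of mean percent walking.

    Schools are evenly placed (zone centres) with nearest-school catchment.
    Returns a DataFrame indexed by n_households (descending, as printed) with
    one column per school count.
    """
    if config is None:
        config = CityConfig()
    grid = {}
    for n_schools in school_counts:
        col = {}
        for n_households in household_counts:
            cfg = CityConfig(
                **{**{k: getattr(config, k) for k in CityConfig.__dataclass_fields__},
                   "n_schools": n_schools, "n_households": n_households}
            )
            spec = ScenarioSpec(n_schools=n_schools, n_households=n_households)
            summary = run_scenario(cfg, spec, n_reps=n_reps, base_seed=base_seed,
                                   max_days=max_days)
            col[n_households] = summary.mean_percent_walking
        grid[n_schools] = col
    table = pd.DataFrame(grid)
    table.index.name = "n_households"
    table.columns.name = "n_schools"
    return table.sort_index(ascending=False)


def run_interventions(n_reps: int = 20, base_seed: int = 0,
                      a_levels: Sequence[float] = (0.1, 0.2, 0.3),
                      radii: Sequence[float] = (0.5, 0.71, 1.0),
                      config: Optional[CityConfig] = None,
                      max_days: int = 100) -> pd.DataFrame:
    """Safety-intervention strategy comparison on the baseline scenario."""
    if config is None:
        config = CityConfig()
    table = intervention_experiment(config, a_levels=a_levels, radii=radii,
                                    n_reps=n_reps, base_seed=base_seed,
                                    max_days=max_days)
    table["base_seed"] = base_seed
    table["n_reps"] = n_reps
    return table


def run_calibration(n_reps: int = 20, base_seed: int = 0,
                    target: Optional[CalibrationTarget] = None,
                    beta_grid: Sequence[float] = DEFAULT_BETA_GRID,
                    bg_grid: Sequence[float] = DEFAULT_BG_GRID,
                    config: Optional[CityConfig] = None,
                    max_days: int = 100):
    """Grid-search calibration against the NHTS middle-school column."""
    if target is None:
        target = nhts_reference("middle")
    return calibrate(target, beta_grid=beta_grid, bg_grid=bg_grid,
                     n_reps=n_reps, base_seed=base_seed, config=config,
                     max_days=max_days)


def write_outputs(frame: pd.DataFrame, out_dir: str | Path, stem: str,
                  keep_index: bool = False) -> tuple[Path, Path]:
    """Write a result table as ``<stem>.csv`` and ``<stem>.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}.csv"
    json_path = out_dir / f"{stem}.json"
    frame.to_csv(csv_path, index=keep_index)
    if keep_index:
        json_path.write_text(frame.to_json(orient="index", indent=1))
    else:
        json_path.write_text(frame.to_json(orient="records", indent=1))
    return csv_path, json_path
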