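"""The daily simulation step, convergence detection and replicate runner.

Each simulated day a child walks to school iff both behavioural conditions
hold:

* the mean traffic safety along the fixed walking route exceeds the
  household's safety concern, ``S_t > C_t``;
* attitude plus distance-decay propensity exceed one,
  ``A_w + exp(-beta * d) > 1``.

Safety per road cell is the safety-in-numbers law ``S = 1 - W**-0.6`` where
``W`` is yesterday's walker count on the cell (background walkers plus one
count per walking child whose route passes the cell), plus any intervention
boost, clamped to [0, 1]. After travelling, every child's attitude is
rescaled by the school social-norm ratio
``(0.9 + 0.1 N_w'/N) / (0.9 + 0.1 N_w/N)`` and clamped to [0, 1].

The run stops on the first day that completes a stretch of three equal daily
walker counts (the count has "remained constant" for two consecutive days),
or at ``max_days`` with a convergence-failure flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .city import City
from .routing import BAND_LABELS, band_index

logger = logging.getLogger(__name__)

__all__ = [
    "DayState",
    "RunResult",
    "ReplicateSummary",
    "prob_walk_given_distance",
    "cell_safety",
    "decide_mode",
    "update_attitude",
    "step_day",
    "run_to_convergence",
    "run_replicates",
]

SAFETY_EXPONENT = -0.6
NORM_BASE = 0.9
NORM_WEIGHT = 0.1


def prob_walk_given_distance(d_miles, beta: float):
    """Distance-decay walking propensity ``P_d = exp(-beta * d)``."""
    d = np.asarray(d_miles, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    if beta <= 0:
        raise ValueError(f"beta must be > 0, got {beta}")
    out = np.exp(-beta * d)
    return float(out) if np.isscalar(d_miles) else out


def cell_safety(W):
    """Safety-in-numbers: ``S = 1 - W**-0.6`` clamped to [0, 1].

    ``W**-0.6`` estimates the per-pedestrian risk of being struck given ``W``
    walkers, so safety rises (with diminishing returns) as walkers accumulate.
    """
    w = np.asarray(W, dtype=float)
    if np.any(w <= 0):
        raise ValueError("walker count W must be > 0")
    out = np.clip(1.0 - w ** SAFETY_EXPONENT, 0.0, 1.0)
    return float(out) if np.isscalar(W) else out


def decide_mode(route_safety: float, concern: float, attitude: float,
                p_distance: float) -> bool:
    """True if the child walks: ``S_t > C_t`` and ``A_w + P_d > 1`` (strict)."""
    return route_safety > concern and attitude + p_distance > 1.0


def update_attitude(attitude, N, N_w, N_w_prime):
    """School social-norm update of walking attitude, clamped to [0, 1].

    If more enrolled children walked today (``N_w'``) than yesterday
    (``N_w``), attitudes of everyone at the school rise, and vice versa.
    """
    N = np.asarray(N, dtype=float)
    if np.any(N <= 0):
        raise ValueError("school enrolment N must be > 0")
    ratio = (NORM_BASE + NORM_WEIGHT * np.asarray(N_w_prime) / N) / (
        NORM_BASE + NORM_WEIGHT * np.asarray(N_w) / N
    )
    out = np.clip(np.asarray(attitude, dtype=float) * ratio, 0.0, 1.0)
    return float(out) if np.isscalar(attitude) else out


@dataclass
class DayState:
    """State after a completed simulation day."""

    day: int
    walkers_by_cell: np.ndarray       # W per cell, background included
    walking: np.ndarray               # bool per household
    n_walking: int
    school_walkers_today: np.ndarray      # N_w' per school
    school_walkers_yesterday: np.ndarray  # N_w per school

    @property
    def walking_children(self) -> np.ndarray:
        return np.flatnonzero(self.walking)


def step_day(state: Optional[DayState], city: City) -> DayState:
    """Advance the city by one day; ``state=None`` starts day 1.

    Sub-steps, in order: (a) refresh every cell's safety from yesterday's
    walker counts plus the intervention boost; (b) every child picks a mode;
    (c) walker counts accumulate along the walking children's routes;
    (d) school walker tallies roll over; (e) attitudes update from the school
    social norm.
    """
    grid = city.grid
    hh = city.households
    schools = city.schools
    bg = city.config.background_walkers_per_cell

    if state is None:
        prev_W = np.full(grid.n_cells, bg, dtype=float)
        prev_today = np.zeros(len(schools), dtype=np.int64)
        day = 1
    else:
        prev_W = state.walkers_by_cell
        prev_today = state.school_walkers_today
        day = state.day + 1

    # (a) safety field from yesterday's walkers, plus boost, clamped
    grid.W = prev_W
    grid.S = np.clip(cell_safety(prev_W) + grid.boost, 0.0, 1.0)

    # (b) mode choice: route-mean safety vs concern; attitude + distance decay
    cell_S = grid.S[hh.route_flat]
    route_sums = np.add.reduceat(cell_S, hh.route_offsets)
    route_safety = route_sums / hh.route_lens
    p_d = np.exp(-city.config.beta * hh.distance_miles)
    walking = (route_safety > hh.concern) & (hh.attitude + p_d > 1.0)
    n_walking = int(walking.sum())

    # (c) walker counts: background plus one per walking child per route cell
    counts = np.bincount(
        hh.route_flat[np.repeat(walking, hh.route_lens)], minlength=grid.n_cells
    )
    new_W = bg + counts.astype(float)

    # (d) school tallies roll over
    walkers_yesterday = prev_today
    walkers_today = np.bincount(
        hh.school_id[walking], minlength=len(schools)
    ).astype(np.int64)
    schools.walkers_yesterday = walkers_yesterday
    schools.walkers_today = walkers_today

    # (e) social-norm attitude update per school (empty schools unchanged)
    enrolled = schools.enrolment > 0
    ratio = np.ones(len(schools), dtype=float)
    ratio[enrolled] = (
        NORM_BASE + NORM_WEIGHT * walkers_today[enrolled] / schools.enrolment[enrolled]
    ) / (
        NORM_BASE + NORM_WEIGHT * walkers_yesterday[enrolled] / schools.enrolment[enrolled]
    )
    hh.attitude = np.clip(hh.attitude * ratio[hh.school_id], 0.0, 1.0)

    return DayState(
        day=day,
        walkers_by_cell=new_W,
        walking=walking,
        n_walking=n_walking,
        school_walkers_today=walkers_today,
        school_walkers_yesterday=walkers_yesterday,
    )


@dataclass
class RunResult:
    """Steady-state summary of a single simulated city."""

    seed: int
    n_households: int
    steady_n_walking: int
    percent_walking: float
    days_to_converge: int
    converged: bool
    band_walk_rates: dict[str, float]          # % walking within each mile band
    band_population_shares: dict[str, float]   # % of children per mile band
    n_walking_history: list[int] = field(default_factory=list)

    def to_row(self) -> dict:
        row = {
            "seed": self.seed,
            "n_households": self.n_households,
            "percent_walking": self.percent_walking,
            "days_to_converge": self.days_to_converge,
            "converged": self.converged,
        }
        for label in BAND_LABELS:
            row[f"walk_rate[{label}]"] = self.band_walk_rates[label]
        for label in BAND_LABELS:
            row[f"pop_share[{label}]"] = self.band_population_shares[label]
        return row


def _band_stats(city: City, walking: np.ndarray) -> tuple[dict, dict]:
    idx = band_index(city.households.distance_miles)
    n = len(city.households)
    rates, shares = {}, {}
    for b, label in enumerate(BAND_LABELS):
        in_band = idx == b
        n_band = int(in_band.sum())
        shares[label] = 100.0 * n_band / n
        rates[label] = (
            100.0 * float(walking[in_band].sum()) / n_band if n_band else float("nan")
        )
    return rates, shares


def run_to_convergence(city: City, max_days: int = 100) -> RunResult:
    """Simulate daily until the walking count has stayed constant for two
    consecutive days (three equal values), or ``max_days`` is reached."""
    if max_days < 2:
        raise ValueError("max_days must be >= 2")
    state: Optional[DayState] = None
    history: list[int] = []
    converged = False
    for _ in range(max_days):
        state = step_day(state, city)
        history.append(state.n_walking)
        logger.debug("day %d: %d children walking", state.day, state.n_walking)
        if len(history) >= 3 and history[-1] == history[-2] == history[-3]:
            converged = True
            break
    rates, shares = _band_stats(city, state.walking)
    return RunResult(
        seed=city.config.seed,
        n_households=len(city.households),
        steady_n_walking=state.n_walking,
        percent_walking=100.0 * state.n_walking / len(city.households),
        days_to_converge=state.day,
        converged=converged,
        band_walk_rates=rates,
        band_population_shares=shares,
        n_walking_history=history,
    )


@dataclass
class ReplicateSummary:
    """Aggregate over independent replicates of one scenario."""

    results: list[RunResult]
    mean_percent_walking: float
    min_percent_walking: float
    max_percent_walking: float
    mean_band_walk_rates: dict[str, float]
    band_walk_rate_ranges: dict[str, tuple[float, float]]
    mean_band_population_shares: dict[str, float]

    @property
    def n_reps(self) -> int:
        return len(self.results)


def run_replicates(city_factory: Callable[[int], City], n_reps: int,
                   base_seed: int, max_days: int = 100) -> ReplicateSummary:
    """Run ``n_reps`` independent cities seeded ``base_seed + i`` and aggregate.

    ``city_factory`` maps a seed to a fully built :class:`City`; per-band
    means ignore replicates whose band is empty.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    results = [
        run_to_convergence(city_factory(base_seed + i), max_days=max_days)
        for i in range(n_reps)
    ]
    pct = np.array([r.percent_walking for r in results])
    mean_rates, rate_ranges, mean_shares = {}, {}, {}
    for label in BAND_LABELS:
        vals = np.array([r.band_walk_rates[label] for r in results])
        vals = vals[~np.isnan(vals)]
        mean_rates[label] = float(vals.mean()) if len(vals) else float("nan")
        rate_ranges[label] = (
            (float(vals.min()), float(vals.max())) if len(vals) else (float("nan"),) * 2
        )
        mean_shares[label] = float(
            np.mean([r.band_population_shares[label] for r in results])
        )
    return ReplicateSummary(
        results=results,
        mean_percent_walking=float(pct.mean()),
        min_percent_walking=float(pct.min()),
        max_percent_walking=float(pct.max()),
        mean_band_walk_rates=mean_rates,
        band_walk_rate_ranges=rate_ranges,
        mean_band_population_shares=mean_shares,
    )
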