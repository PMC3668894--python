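"""Independent brute-force reimplementation of the daily step.

Pure-Python dict/loop version of the simulation day, used as an oracle
against the vectorised implementation. Deliberately naive: no caching, no
numpy accumulation, everything recomputed per day.
"""

from __future__ import annotations

import math


def clamp01(v: float) -> float:
    return min(max(v, 0.0), 1.0)


def naive_run(city, n_days: int):
    """Simulate ``n_days`` with plain loops; returns per-day records.

    Each record holds the walking household ids, per-cell walker counts,
    per-school walker tallies and the post-update attitudes.
    """
    config = city.config
    bg = config.background_walkers_per_cell
    hh = city.households
    n_hh = len(hh)
    n_schools = len(city.schools)
    enrolment = [0] * n_schools
    for i in range(n_hh):
        enrolment[int(hh.school_id[i])] += 1

    attitudes = [float(a) for a in hh.attitude]
    concerns = [float(c) for c in hh.concern]
    routes = [[int(c) for c in r.cells] for r in hh.routes]
    distances = [float(d) for d in hh.distance_miles]
    boost = [float(b) for b in city.grid.boost]

    W = {c: bg for c in range(city.grid.n_cells)}
    walkers_today = [0] * n_schools
    days = []
    for _ in range(n_days):
        S = {c: clamp01(clamp01(1.0 - W[c] ** -0.6) + boost[c]) for c in W}
        walking = []
        for i in range(n_hh):
            route_safety = sum(S[c] for c in routes[i]) / len(routes[i])
            p_d = math.exp(-config.beta * distances[i])
            if route_safety > concerns[i] and attitudes[i] + p_d > 1.0:
                walking.append(i)
        new_W = {c: bg for c in W}
        for i in walking:
            for c in routes[i]:
                new_W[c] += 1
        walkers_yesterday = walkers_today
        walkers_today = [0] * n_schools
        for i in walking:
            walkers_today[int(hh.school_id[i])] += 1
        new_attitudes = []
        for i in range(n_hh):
            s = int(hh.school_id[i])
            ratio = (0.9 + 0.1 * walkers_today[s] / enrolment[s]) / (
                0.9 + 0.1 * walkers_yesterday[s] / enrolment[s]
            )
            new_attitudes.append(clamp01(attitudes[i] * ratio))
        attitudes = new_attitudes
        W = new_W
        days.append({
            "walking": walking,
            "n_walking": len(walking),
            "W": dict(W),
            "school_walkers_today": list(walkers_today),
            "school_walkers_yesterday": list(walkers_yesterday),
            "attitudes": list(attitudes),
        })
    return days
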