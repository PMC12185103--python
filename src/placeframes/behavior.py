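"""End-point measures of active place avoidance behavior.

Three measures summarise each 10-min trial: the distance walked
(locomotion), the time to first enter the shock zone (between-session
avoidance memory) and the number of entrances into the zone (place
learning). A savings index compares first-5-minute entrance counts
between the first trials of the two conflict days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import PositionSeries, SectorSpec, in_sector

#: Tracking resolution, cm; steps shorter than this are tracker jitter.
MIN_STEP_CM = 0.32
#: Minimum continuous time outside the zone before a new entrance counts, s.
REFRACTORY_S = 1.5


@dataclass(frozen=True)
class BehaviorResult:
    """Endpoint measures for one trial (optionally a sub-window of it)."""

    distance_m: float
    time_to_first_entry_s: float
    first_entry_censored: bool
    n_entrances: int
    session_length_s: float


def _windowed(series: PositionSeries, window: tuple[float, float] | None) -> PositionSeries:
    if window is None:
        return series
    return series.window(window[0], window[1])


def path_length(series: PositionSeries, min_step: float = MIN_STEP_CM,
                window: tuple[float, float] | None = None) -> float:
    """Distance walked in metres; steps below ``min_step`` cm are ignored."""
    series = _windowed(series, window)
    if len(series) < 2:
        raise ValueError("path length needs at least two samples")
    steps = np.hypot(np.diff(series.x), np.diff(series.y))
    return float(steps[steps >= min_step].sum()) / 100.0


def entrances(series: PositionSeries, zone: SectorSpec,
              refractory: float = REFRACTORY_S,
              window: tuple[float, float] | None = None) -> tuple[int, np.ndarray]:
    """Count zone entrances and return their timestamps.

    An entrance is an outside-to-inside transition preceded by at least
    ``refractory`` seconds continuously outside the zone, suppressing
    boundary chatter. The pre-session state counts as outside, so a
    trial that starts inside the zone registers an entrance at its first
    sample.
    """
    if zone.frame != "room":
        raise ValueError("the shock zone is defined in the room frame")
    series = _windowed(series, window)
    inside = np.asarray(in_sector(series.x, series.y, zone), dtype=bool).reshape(-1)
    t = series.t
    entry_times = []
    outside_since = -np.inf  # pre-session treated as continuously outside
    was_inside = False
    for i in range(len(series)):
        if inside[i]:
            if not was_inside and (t[i] - outside_since) >= refractory:
                entry_times.append(t[i])
            was_inside = True
        else:
            if was_inside:
                outside_since = t[i]
            was_inside = False
    return len(entry_times), np.asarray(entry_times)


def time_to_first_entry(series: PositionSeries, zone: SectorSpec,
                        window: tuple[float, float] | None = None) -> tuple[float, bool]:
    """Latency to the first sample inside the zone, from session start.

    Returns ``(latency_s, censored)``; a trial with no entry reports the
    session length with the censored flag set, so averages stay finite.
    """
    if zone.frame != "room":
        raise ValueError("the shock zone is defined in the room frame")
    series = _windowed(series, window)
    inside = np.asarray(in_sector(series.x, series.y, zone), dtype=bool).reshape(-1)
    hits = np.flatnonzero(inside)
    length = series.duration
    if hits.size == 0:
        return float(length), True
    return float(series.t[hits[0]] - series.t[0]), False


def savings_index(entrances_c1: int, entrances_c9: int) -> float:
    """Percent reduction in entrances from conflict trial 1 to trial 9.

    100 * (entrances_c1 - entrances_c9) / entrances_c1. Positive values
    mean improvement (savings); 100 iff trial 9 has no entrances; the
    index is unbounded below when performance worsens.
    """
    if entrances_c1 < 0 or entrances_c9 < 0:
        raise ValueError("entrance counts must be non-negative")
    if entrances_c1 == 0:
        raise ValueError(
            "savings index undefined: no entrances on the first conflict trial "
            "(division by zero)"
        )
    return 100.0 * (entrances_c1 - entrances_c9) / entrances_c1


def behavior_endpoints(series: PositionSeries, zone: SectorSpec | None,
                       min_step: float = MIN_STEP_CM,
                       refractory: float = REFRACTORY_S,
                       window: tuple[float, float] | None = None) -> BehaviorResult:
    """All endpoint measures for one trial; zone may be None (pretraining)."""
    sub = _windowed(series, window)
    dist = path_length(sub, min_step=min_step)
    if zone is None:
        return BehaviorResult(dist, float(sub.duration), True, 0, float(sub.duration))
    n, _ = entrances(sub, zone, refractory=refractory)
    latency, censored = time_to_first_entry(sub, zone)
    return BehaviorResult(dist, latency, censored, n, float(sub.duration))
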