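"""Weekly movement-pattern classification and templated summaries.

Each calendar week of a bird's record is assigned one of six patterns,
mirroring the categories used when narrating raptor dispersal: staying
within a home range, establishing a new home range, travelling between
known home ranges, a round trip out and back, exploring outside known
ranges, or no data. "Known home ranges" are the cumulative weekly isopleth
polygons computed from settlement fixes up to the *previous* week, so the
classification only uses information available at the time.

The decision cascade (first match wins):

1. no fixes -> ``no_data``
2. no excursion-labelled fixes and >= 80 % of fixes inside known polygons
   -> ``within_home_range``
3. excursion fixes present and first and last fix in the *same* known
   polygon -> ``round_trip``
4. first and last fix in *different* known polygons
   -> ``travel_between_home_ranges``
5. the trailing >= 5 fixes all outside known polygons, within a 5 km
   radius disc, spanning >= 3 days -> ``new_home_range``
6. otherwise -> ``exploring_outside``

The thresholds in steps 2 and 5 are operational choices (configurable via
:class:`BehaviorConfig`), not field-measured constants.

Weekly distance is the great-circle chain over the week's steps — a lower
bound on the true path length, which is all a handful of fixes per day can
support.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta

import numpy as np
import pandas as pd

from . import geometry

PATTERNS = (
    "within_home_range",
    "new_home_range",
    "travel_between_home_ranges",
    "round_trip",
    "exploring_outside",
    "no_data",
)


@dataclass
class BehaviorConfig:
    """Thresholds of the weekly pattern cascade."""

    inside_fraction: float = 0.80
    inside_buffer_km: float = 5.0
    new_range_min_fixes: int = 5
    new_range_radius_km: float = 5.0
    new_range_min_days: float = 3.0
    week_anchor: int = 0  # 0 = Monday


@dataclass
class WeekSummary:
    """One bird-week: window, fix count, distance, pattern, range ids."""

    bird_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    n_fixes: int
    distance_km: float
    pattern: str
    start_range_id: int | None = None
    end_range_id: int | None = None

    @property
    def distance_miles(self) -> float:
        return self.distance_km * geometry.MILES_PER_KM


def assign_weeks(times: pd.DatetimeIndex, anchor: int = 0):
    """Partition a time range into calendar weeks anchored on a weekday.

    Returns a list of (start, end) pairs, midnight-to-midnight UTC, with
    ``end`` exclusive; every fix falls in exactly one window and the
    windows tile the record from the first fix's week to the last's.
    """
    if len(times) == 0:
        return []
    first = times[0].normalize()
    start = first - timedelta(days=(first.weekday() - anchor) % 7)
    windows = []
    while start <= times[-1]:
        end = start + timedelta(days=7)
        windows.append((start, end))
        start = end
    return windows


def _poly_ids(home_range):
    """Stable ids for a home range's polygon parts (sorted by centroid)."""
    if home_range is None:
        return []
    parts = home_range.polygon_list
    order = sorted(range(len(parts)), key=lambda i: (parts[i].centroid.x, parts[i].centroid.y))
    return [(rank, parts[i]) for rank, i in enumerate(order)]


def _locate(parts, x, y, buffer_km=0.0):
    """Id of the nearest polygon part within ``buffer_km`` of (x, y), else None.

    A fix a couple of kilometres outside the isopleth contour is still
    "in" that range for behavioural purposes: the contour is an estimate
    and weekly fixes are few and noisy.
    """
    from shapely.geometry import Point

    best = None
    pt = Point(float(x), float(y))
    for pid, poly in parts:
        d = poly.distance(pt)
        if d <= buffer_km and (best is None or d < best[1]):
            best = (pid, d)
    return best[0] if best else None


def classify_week(
    bird_id,
    window,
    xy,
    times,
    labels,
    known_range,
    distance_km,
    cfg: BehaviorConfig | None = None,
) -> WeekSummary:
    """Classify one week of fixes against the known home ranges.

    Parameters
    ----------
    window : (start, end) timestamps of the week.
    xy : (n, 2) projected coordinates of the week's fixes, km.
    times : DatetimeIndex of the week's fixes.
    labels : excursion/settlement labels of the week's fixes.
    known_range : HomeRange (cumulative, up to the previous week) or None.
    distance_km : distance flown this week (precomputed step chain).
    """
    cfg = cfg or BehaviorConfig()
    start, end = window
    n = len(times)
    if n == 0:
        return WeekSummary(bird_id, start, end, 0, 0.0, "no_data")

    labels = np.asarray(labels)
    xy = np.atleast_2d(np.asarray(xy, float))
    parts = _poly_ids(known_range)
    inside_any = np.zeros(n, dtype=bool)
    if parts:
        from shapely.geometry import Point

        for i in range(n):
            pt = Point(xy[i, 0], xy[i, 1])
            inside_any[i] = any(
                poly.distance(pt) <= cfg.inside_buffer_km for _, poly in parts
            )

    has_excursion = bool(np.any(labels == "excursion"))
    first_id = _locate(parts, xy[0, 0], xy[0, 1], cfg.inside_buffer_km)
    last_id = _locate(parts, xy[-1, 0], xy[-1, 1], cfg.inside_buffer_km)

    summary = WeekSummary(
        bird_id,
        start,
        end,
        n,
        float(distance_km),
        "exploring_outside",
        start_range_id=first_id,
        end_range_id=last_id,
    )

    if not has_excursion and inside_any.mean() >= cfg.inside_fraction and parts:
        summary.pattern = "within_home_range"
        return summary
    if has_excursion and first_id is not None and first_id == last_id:
        summary.pattern = "round_trip"
        return summary
    if first_id is not None and last_id is not None and first_id != last_id:
        summary.pattern = "travel_between_home_ranges"
        return summary
    # A new home range shows as a trailing block of >= new_range_min_fixes
    # fixes outside every known polygon that sit together in a small disc
    # for several days. The trailing outside run may begin with the travel
    # that got the bird there, so every sufficiently long suffix of the run
    # is tested, not just the full run.
    outside = ~inside_any
    run = 0
    while run < n and outside[n - 1 - run]:
        run += 1
    for k in range(run, cfg.new_range_min_fixes - 1, -1):
        tail = xy[n - k :]
        centroid = tail.mean(axis=0)
        radius = float(np.max(np.hypot(*(tail - centroid).T)))
        if radius > cfg.new_range_radius_km:
            continue
        span_days = (times[-1] - times[n - k]).total_seconds() / 86400.0
        if span_days >= cfg.new_range_min_days:
            summary.pattern = "new_home_range"
            return summary
    return summary


_TEMPLATES = {
    "within_home_range": (
        "This week, {bird} flew around {miles} miles and was actively exploring "
        "mainly within {pos} home range."
    ),
    "new_home_range": (
        "This week, {bird} flew around {miles} miles and was exploring "
        "{pos} newly established home range."
    ),
    "travel_between_home_ranges": (
        "This week, {bird} flew around {miles} miles and moved between "
        "{pos} known home ranges."
    ),
    "round_trip": (
        "This week, {bird} flew around {miles} miles and made a journey "
        "outside {pos} home range and back."
    ),
    "exploring_outside": (
        "This week, {bird} flew around {miles} miles and was exploring "
        "areas outside {pos} known home ranges."
    ),
    "no_data": "From {bird}, no transmissions were received this week.",
}


def render_summary(ws: WeekSummary, possessive: str = "its") -> str:
    """One deterministic template sentence for a classified week.

    A pure function of the :class:`WeekSummary`: the same summary always
    renders to byte-identical text. Miles are rounded half-up to the
    nearest whole mile.
    """
    miles = int(np.floor(ws.distance_miles + 0.5))
    return _TEMPLATES[ws.pattern].format(bird=ws.bird_id, miles=miles, pos=possessive)


def weekly_distances(traj, windows):
    """Distance flown per window, chaining great-circle steps.

    A step between consecutive fixes is assigned to the window containing
    its *later* fix, so boundary-crossing segments count toward the week in
    which they were completed.
    """
    steps = geometry.step_distances_km(traj.lat, traj.lon)  # step i: fix i -> i+1
    out = []
    for start, end in windows:
        if len(steps) == 0:
            out.append(0.0)
            continue
        later = traj.times[1:]
        mask = (later >= start) & (later < end)
        out.append(float(steps[np.asarray(mask)].sum()))
    return out
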