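"""Per-day time-away, distance and per-cat summary metrics.

Interval attribution: the time between two fixes belongs wholly to their
shared home/away state; when the endpoint states differ the interval is
split 50/50. Intervals are cut at local midnight so each second lands in
exactly one calendar day. Distance segments are assigned to the calendar
day of the destination fix.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, time as dtime, timedelta, timezone
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

from catmove.errors import InsufficientDataError, ValidationError
from catmove.tracks_io import DEFAULT_TIMEZONE, Trajectory, geodesic_m

HOME = "HOME"
AWAY = "AWAY"

DEFAULT_HOME_RADIUS_M = 50.0


def classify_home_away(traj: Trajectory, radius: float = DEFAULT_HOME_RADIUS_M) -> np.ndarray:
    """Per-fix state: HOME iff within ``radius`` meters of the home anchor
    (boundary inclusive), else AWAY."""
    d = geodesic_m(traj.latlon, np.asarray(traj.home, dtype=float))
    return np.where(d <= radius, HOME, AWAY)


def _local_date(epoch_s: float, tz: ZoneInfo) -> date:
    return datetime.fromtimestamp(epoch_s, tz).date()


def _next_midnight(epoch_s: float, tz: ZoneInfo) -> float:
    """Epoch seconds of the first local midnight strictly after ``epoch_s``."""
    local = datetime.fromtimestamp(epoch_s, tz)
    nxt = datetime.combine(local.date() + timedelta(days=1), dtime(0, 0), tzinfo=tz)
    return nxt.timestamp()


def _split_interval_by_day(t0: float, t1: float, tz: ZoneInfo):
    """Yield (day, seconds) pieces of [t0, t1) cut at local midnights."""
    t = t0
    while t < t1:
        cut = min(_next_midnight(t, tz), t1)
        yield _local_date(t, tz), cut - t
        t = cut


def time_away_per_day(
    traj: Trajectory,
    radius: float = DEFAULT_HOME_RADIUS_M,
    tz: str = DEFAULT_TIMEZONE,
) -> pd.DataFrame:
    """Seconds of tracked and away time per local calendar day.

    Returns a DataFrame with columns ``date, tracked_s, away_s, home_s``.
    Conservation holds exactly: away_s + home_s == tracked_s per day.
    """
    zone = ZoneInfo(tz)
    states = classify_home_away(traj, radius)
    times = traj.times_s
    acc: dict[date, list[float]] = {}
    for i in range(len(times) - 1):
        t0, t1 = times[i], times[i + 1]
        if t1 <= t0:
            continue
        if states[i] == states[i + 1]:
            frac_away = 1.0 if states[i] == AWAY else 0.0
        else:
            frac_away = 0.5
        for day, secs in _split_interval_by_day(t0, t1, zone):
            slot = acc.setdefault(day, [0.0, 0.0])
            slot[0] += secs
            slot[1] += secs * frac_away
    rows = [
        {"date": d, "tracked_s": v[0], "away_s": v[1], "home_s": v[0] - v[1]}
        for d, v in sorted(acc.items())
    ]
    return pd.DataFrame(rows, columns=["date", "tracked_s", "away_s", "home_s"])


def daily_distance(traj: Trajectory, tz: str = DEFAULT_TIMEZONE) -> pd.DataFrame:
    """Meters moved per local calendar day (segments keyed by destination fix)."""
    zone = ZoneInfo(tz)
    ll = traj.latlon
    times = traj.times_s
    seg = geodesic_m(ll[:-1], ll[1:]) if len(traj) > 1 else np.array([])
    acc: dict[date, float] = {}
    # every day with a fix appears, even if no segment lands in it
    for t in times:
        acc.setdefault(_local_date(t, zone), 0.0)
    for i, d in enumerate(seg):
        day = _local_date(times[i + 1], zone)
        acc[day] = acc.get(day, 0.0) + float(d)
    rows = [{"date": d, "distance_m": v} for d, v in sorted(acc.items())]
    return pd.DataFrame(rows, columns=["date", "distance_m"])


def trim_first_last_days(metrics: pd.DataFrame) -> pd.DataFrame:
    """Drop the records of the first and last calendar days.

    Requires at least 3 distinct days so at least one interior day survives.
    """
    if "date" not in metrics.columns:
        raise ValidationError("per-day records need a 'date' column")
    days = sorted(metrics["date"].unique())
    if len(days) < 3:
        raise InsufficientDataError(f"need >= 3 tracked days to trim, got {len(days)}")
    keep = metrics[~metrics["date"].isin([days[0], days[-1]])]
    return keep.reset_index(drop=True)


def flag_interrupted(traj: Trajectory, tz: str = DEFAULT_TIMEZONE) -> bool:
    """True iff some interior calendar day between the first and last tracked
    days contains zero fixes."""
    zone = ZoneInfo(tz)
    days = {_local_date(t, zone) for t in traj.times_s}
    first, last = min(days), max(days)
    d = first + timedelta(days=1)
    while d < last:
        if d not in days:
            return True
        d += timedelta(days=1)
    return False


def boundary_adjust(y, n: int):
    """Map proportions from [0,1] into (0,1): (y*(n-1) + 0.5) / n."""
    if n < 1:
        raise ValidationError("cohort size must be >= 1")
    return (np.asarray(y, dtype=float) * (n - 1) + 0.5) / n


def percent_time_away(metrics: pd.DataFrame, n_cohort: int | None = None) -> float:
    """Overall fraction of tracked time spent away: sum(away) / sum(tracked).

    When ``n_cohort`` is given, the raw fraction is boundary-adjusted into
    (0, 1) so it can enter a beta-likelihood model.
    """
    tracked = float(metrics["tracked_s"].sum())
    if tracked <= 0:
        raise ValidationError("no tracked time: cannot form a proportion")
    frac = float(metrics["away_s"].sum()) / tracked
    if n_cohort is not None:
        frac = float(boundary_adjust(frac, n_cohort))
    return frac


@dataclass
class CatSummary:
    cat_id: str
    mean_away_h_per_day: float
    frac_away: float
    total_days: int
    interrupted: bool


def daily_metrics(
    traj: Trajectory,
    radius: float = DEFAULT_HOME_RADIUS_M,
    tz: str = DEFAULT_TIMEZONE,
    rainfall: pd.DataFrame | None = None,
    municipality: str | None = None,
) -> pd.DataFrame:
    """Combined per-day table: cat_id, date, tracked_s, away_s, distance_m
    (+ rainfall_mm when a rainfall table and municipality are supplied)."""
    away = time_away_per_day(traj, radius=radius, tz=tz)
    dist = daily_distance(traj, tz=tz)
    df = away.merge(dist, on="date", how="outer").sort_values("date")
    df[["tracked_s", "away_s", "home_s", "distance_m"]] = df[
        ["tracked_s", "away_s", "home_s", "distance_m"]
    ].fillna(0.0)
    df.insert(0, "cat_id", traj.cat_id)
    if rainfall is not None and municipality is not None:
        r = rainfall[rainfall["municipality"] == municipality][["date", "rainfall_mm"]]
        df = df.merge(r, on="date", how="left")
    return df.reset_index(drop=True)


def summarize_cat(
    traj: Trajectory,
    metrics: pd.DataFrame,
    n_cohort: int | None = None,
    tz: str = DEFAULT_TIMEZONE,
) -> CatSummary:
    """Per-cat aggregate over the (already trimmed) per-day records.

    Hours away per day are normalized by tracked time (24 * away/tracked) so
    device gaps do not deflate the outcome.
    """
    frac_raw = percent_time_away(metrics)
    frac = percent_time_away(metrics, n_cohort) if n_cohort else frac_raw
    return CatSummary(
        cat_id=traj.cat_id,
        mean_away_h_per_day=24.0 * frac_raw,
        frac_away=frac,
        total_days=int(metrics["date"].nunique()),
        interrupted=flag_interrupted(traj, tz=tz),
    )
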