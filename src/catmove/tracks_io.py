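"""Reading, validating, anchoring and cleaning GPS trajectories.

Coordinates are WGS84 degrees; all timestamps are normalized to UTC.
Distances use the haversine formula on a sphere of radius 6,371,000 m —
the ~13 m device location error dwarfs ellipsoidal corrections.
"""

from __future__ import annotations

import csv as _csv
import math
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from catmove.errors import (
    DegenerateTrajectoryError,
    FormatError,
    InsufficientDataError,
    ProjectionError,
    ValidationError,
)

EARTH_RADIUS_M = 6_371_000.0

#: Mean device location error (meters); used when a fix carries no per-fix SD.
DEFAULT_LOC_ERR_SD = 13.1

#: Local timezone in which calendar-day boundaries are applied downstream.
DEFAULT_TIMEZONE = "Europe/Copenhagen"

# Closed category sets for the per-animal covariate table.
SEX_LEVELS = ["intact male", "neutered male", "intact female", "neutered female"]
AGE_LEVELS = ["1-3", "4-7", "8-16"]
BREED_LEVELS = ["domestic shorthair", "purebred", "mixed/unknown"]
FOOD_LEVELS = ["ad libitum", "restricted"]
LAND_USE_LEVELS = ["rural", "suburban/cottage", "urban/industry"]
YES_NO_LEVELS = ["yes", "no"]

CAT_RECORD_LEVELS = {
    "sex": SEX_LEVELS,
    "age_group": AGE_LEVELS,
    "breed": BREED_LEVELS,
    "food_access": FOOD_LEVELS,
    "land_use": LAND_USE_LEVELS,
    "busy_road": YES_NO_LEVELS,
    "nature_access": YES_NO_LEVELS,
}


@dataclass(frozen=True)
class Fix:
    """One GPS observation."""

    time: datetime
    lat: float
    lon: float
    loc_err_sd: float | None = None

    def __post_init__(self) -> None:
        if self.time.tzinfo is None:
            object.__setattr__(self, "time", self.time.replace(tzinfo=timezone.utc))
        else:
            object.__setattr__(self, "time", self.time.astimezone(timezone.utc))
        if not (-90.0 <= self.lat <= 90.0):
            raise ValidationError(f"latitude out of range: {self.lat!r}")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValidationError(f"longitude out of range: {self.lon!r}")
        if self.loc_err_sd is not None and not self.loc_err_sd > 0:
            raise ValidationError(f"loc_err_sd must be > 0, got {self.loc_err_sd!r}")

    @property
    def epoch_s(self) -> float:
        return self.time.timestamp()


@dataclass
class Trajectory:
    """Time-ordered fixes for one animal with a home anchor.

    ``home`` defaults to the coordinates of the first fix, mirroring the
    convention that the first recorded coordinate is the home address.
    """

    cat_id: str
    fixes: list[Fix]
    home: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if len(self.fixes) < 2:
            raise InsufficientDataError(
                f"trajectory {self.cat_id!r} has {len(self.fixes)} fixes; need >= 2"
            )
        self.fixes = sorted(self.fixes, key=lambda f: f.time)
        if self.home is None:
            self.home = (self.fixes[0].lat, self.fixes[0].lon)
        if not (math.isfinite(self.home[0]) and math.isfinite(self.home[1])):
            raise ValidationError(f"non-finite home anchor: {self.home!r}")

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def times_s(self) -> np.ndarray:
        """POSIX epoch seconds, float64."""
        return np.array([f.epoch_s for f in self.fixes])

    @property
    def latlon(self) -> np.ndarray:
        """(n, 2) array of (lat, lon) degrees."""
        return np.array([(f.lat, f.lon) for f in self.fixes])

    @property
    def loc_err_sd(self) -> np.ndarray:
        return np.array(
            [f.loc_err_sd if f.loc_err_sd is not None else DEFAULT_LOC_ERR_SD for f in self.fixes]
        )

    def segment_speeds(self) -> np.ndarray:
        """Speed (m/s) of each consecutive-fix segment; length n-1."""
        ll = self.latlon
        dt = np.diff(self.times_s)
        d = geodesic_m(ll[:-1], ll[1:])
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(dt > 0, d / dt, np.inf)


def geodesic_m(a, b) -> np.ndarray | float:
    """Great-circle (haversine) distance in meters between (lat, lon) points.

    Accepts single pairs or (n, 2) arrays; broadcasts elementwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    lat1, lon1 = np.radians(a[..., 0]), np.radians(a[..., 1])
    lat2, lon2 = np.radians(b[..., 0]), np.radians(b[..., 1])
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def _parse_time(value: str) -> datetime:
    ts = pd.Timestamp(value)
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    return ts.to_pydatetime().astimezone(timezone.utc)


_GPX_NS = "{http://www.topografix.com/GPX/1/1}"


def _read_gpx(path: Path) -> list[Fix]:
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise FormatError(f"{path}: not well-formed GPX: {exc}") from exc
    fixes: list[Fix] = []
    root = tree.getroot()
    # Accept both namespaced (GPX 1.0/1.1) and bare trackpoint elements.
    points = [el for el in root.iter() if el.tag.endswith("trkpt")]
    for i, el in enumerate(points):
        try:
            lat = float(el.attrib["lat"])
            lon = float(el.attrib["lon"])
        except (KeyError, ValueError) as exc:
            raise FormatError(f"{path}: trackpoint {i} lacks valid lat/lon") from exc
        t_el = next((c for c in el if c.tag.endswith("time")), None)
        if t_el is None or t_el.text is None:
            raise FormatError(f"{path}: trackpoint {i} has no <time> element")
        try:
            t = _parse_time(t_el.text.strip())
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: trackpoint {i}: bad timestamp {t_el.text!r}") from exc
        fixes.append(Fix(time=t, lat=lat, lon=lon))
    return fixes


def _read_csv_track(path: Path) -> list[Fix]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = _csv.DictReader(fh)
        if reader.fieldnames is None or not {"time", "lat", "lon"} <= set(reader.fieldnames):
            raise FormatError(f"{path}: CSV track needs header time,lat,lon[,loc_err_sd]")
        fixes: list[Fix] = []
        for i, row in enumerate(reader, start=2):  # header is line 1
            try:
                t = _parse_time(row["time"])
            except (ValueError, TypeError) as exc:
                raise FormatError(f"{path}: line {i}: bad timestamp {row['time']!r}") from exc
            try:
                lat = float(row["lat"])
                lon = float(row["lon"])
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}: line {i}: bad coordinates") from exc
            sd = row.get("loc_err_sd")
            sd_val = float(sd) if sd not in (None, "") else None
            fixes.append(Fix(time=t, lat=lat, lon=lon, loc_err_sd=sd_val))
    return fixes


def read_track(path: str | Path, format: str | None = None, cat_id: str | None = None) -> Trajectory:
    """Read a GPX or CSV track file into a time-sorted :class:`Trajectory`.

    ``format`` is inferred from the file extension when not given. The home
    anchor is set to the first (earliest) fix; use :func:`anchor_home` to
    override it.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "gpx":
        fixes = _read_gpx(path)
    elif format == "csv":
        fixes = _read_csv_track(path)
    else:
        raise FormatError(f"unknown track format {format!r} (expected gpx or csv)")
    if len(fixes) < 2:
        raise InsufficientDataError(f"{path}: only {len(fixes)} fixes; need >= 2")
    return Trajectory(cat_id=cat_id or path.stem, fixes=fixes)


def write_track_csv(traj: Trajectory, path: str | Path) -> None:
    """Write the CSV track dialect: ``time,lat,lon[,loc_err_sd]``."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        has_sd = any(f.loc_err_sd is not None for f in traj.fixes)
        cols = ["time", "lat", "lon"] + (["loc_err_sd"] if has_sd else [])
        w = _csv.writer(fh)
        w.writerow(cols)
        for f in traj.fixes:
            row = [f.time.strftime("%Y-%m-%dT%H:%M:%SZ"), repr(f.lat), repr(f.lon)]
            if has_sd:
                row.append("" if f.loc_err_sd is None else repr(f.loc_err_sd))
            w.writerow(row)


def anchor_home(traj: Trajectory, home: tuple[float, float] | None = None) -> Trajectory:
    """Return a trajectory with its home anchor set.

    With no ``home`` the first fix's coordinates are used; otherwise the
    supplied (lat, lon) wins regardless of where the first fix is.
    """
    if home is not None:
        lat, lon = float(home[0]), float(home[1])
        if not (math.isfinite(lat) and math.isfinite(lon)):
            raise ValidationError(f"non-finite home coordinates: {home!r}")
        if not (-90 <= lat <= 90 and -180 <= lon <= 180):
            raise ValidationError(f"home coordinates out of range: {home!r}")
        return Trajectory(cat_id=traj.cat_id, fixes=list(traj.fixes), home=(lat, lon))
    first = traj.fixes[0]
    return Trajectory(cat_id=traj.cat_id, fixes=list(traj.fixes), home=(first.lat, first.lon))


def dedupe(traj: Trajectory) -> Trajectory:
    """Collapse fixes sharing a timestamp to the first record.

    Output timestamps are strictly increasing. Idempotent.
    """
    kept: list[Fix] = []
    last_t: datetime | None = None
    for f in traj.fixes:
        if last_t is not None and f.time == last_t:
            continue
        kept.append(f)
        last_t = f.time
    if len(kept) < 2:
        raise DegenerateTrajectoryError(
            f"trajectory {traj.cat_id!r}: deduplication left {len(kept)} fixes"
        )
    return Trajectory(cat_id=traj.cat_id, fixes=kept, home=traj.home)


def select_speed_threshold(traj: Trajectory, min_band_count: int = 3) -> float:
    """Pick the per-cat cleaning threshold: 10 m/s when the cat shows
    ``min_band_count`` or more segments in the (5, 10] m/s band, else 5 m/s.
    """
    if len(traj) < 2:
        raise InsufficientDataError("need >= 2 fixes to compute speeds")
    speeds = traj.segment_speeds()
    band = int(np.sum((speeds > 5.0) & (speeds <= 10.0)))
    return 10.0 if band >= min_band_count else 5.0


def speed_filter(traj: Trajectory, threshold: float) -> tuple[Trajectory, int]:
    """Remove fixes implying movement faster than ``threshold`` m/s.

    The destination fix of each violating segment is deleted and the scan
    resumes from the last surviving fix, so a single blunder (which creates
    two violating segments) is removed in one pass. Idempotent.
    """
    if not threshold > 0:
        raise ValidationError(f"threshold must be > 0, got {threshold!r}")
    fixes = traj.fixes
    kept = [fixes[0]]
    removed = 0
    for f in fixes[1:]:
        prev = kept[-1]
        dt = f.epoch_s - prev.epoch_s
        d = geodesic_m((prev.lat, prev.lon), (f.lat, f.lon))
        speed = d / dt if dt > 0 else math.inf
        if speed > threshold:
            removed += 1
        else:
            kept.append(f)
    if len(kept) < 2:
        raise DegenerateTrajectoryError(
            f"trajectory {traj.cat_id!r}: speed filter left {len(kept)} fixes"
        )
    return Trajectory(cat_id=traj.cat_id, fixes=kept, home=traj.home), removed


def clean_track(
    traj: Trajectory, min_band_count: int = 3, threshold: float | None = None
) -> tuple[Trajectory, dict]:
    """Dedupe, pick a speed threshold, and speed-filter, returning a log."""
    n0 = len(traj)
    traj = dedupe(traj)
    dups = n0 - len(traj)
    thr = threshold if threshold is not None else select_speed_threshold(traj)
    traj, removed = speed_filter(traj, thr)
    log = {
        "n_raw": n0,
        "duplicates_removed": dups,
        "speed_threshold_mps": thr,
        "speed_removed": removed,
        "n_clean": len(traj),
    }
    return traj, log


class LocalProjection:
    """Azimuthal equidistant projection on the sphere, centred on a point.

    Distances from the centre are preserved exactly; pairwise distances are
    within 0.1% of geodesic over a ~10 km span. Forward maps (lat, lon)
    degrees to (x, y) meters with the centre at the origin and +y north.
    """

    def __init__(self, lat0: float, lon0: float):
        self.lat0 = float(lat0)
        self.lon0 = float(lon0)
        self._sin0 = math.sin(math.radians(lat0))
        self._cos0 = math.cos(math.radians(lat0))

    def forward(self, lat, lon) -> tuple[np.ndarray, np.ndarray]:
        lat = np.radians(np.asarray(lat, dtype=float))
        lon = np.radians(np.asarray(lon, dtype=float))
        dlon = lon - math.radians(self.lon0)
        cosc = np.clip(
            self._sin0 * np.sin(lat) + self._cos0 * np.cos(lat) * np.cos(dlon), -1.0, 1.0
        )
        c = np.arccos(cosc)
        sinc = np.sin(c)
        with np.errstate(divide="ignore", invalid="ignore"):
            k = np.where(sinc > 1e-12, c / np.where(sinc > 1e-12, sinc, 1.0), 1.0)
        x = EARTH_RADIUS_M * k * np.cos(lat) * np.sin(dlon)
        y = EARTH_RADIUS_M * k * (
            self._cos0 * np.sin(lat) - self._sin0 * np.cos(lat) * np.cos(dlon)
        )
        return x, y

    def inverse(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        rho = np.hypot(x, y)
        c = rho / EARTH_RADIUS_M
        sinc, cosc = np.sin(c), np.cos(c)
        safe = rho > 1e-12
        with np.errstate(divide="ignore", invalid="ignore"):
            lat = np.arcsin(
                np.clip(cosc * self._sin0 + np.where(safe, y * sinc * self._cos0 / np.where(safe, rho, 1.0), 0.0), -1, 1)
            )
            lon = math.radians(self.lon0) + np.arctan2(
                x * sinc, rho * cosc * self._cos0 - y * sinc * self._sin0
            )
        lat = np.where(safe, lat, math.radians(self.lat0))
        lon = np.where(safe, lon, math.radians(self.lon0))
        return np.degrees(lat), np.degrees(lon)


@dataclass
class LocalTrack:
    """A trajectory in the local planar frame (meters from the home anchor)."""

    cat_id: str
    t: np.ndarray  # POSIX seconds, strictly increasing
    xy: np.ndarray  # (n, 2) meters
    loc_err_sd: np.ndarray  # (n,) meters
    projection: LocalProjection

    def __len__(self) -> int:
        return len(self.t)


MAX_PROJECTION_SPAN_M = 50_000.0


def to_local_xy(traj: Trajectory, max_span_m: float = MAX_PROJECTION_SPAN_M) -> LocalTrack:
    """Project a trajectory to a planar frame centred on its home anchor."""
    proj = LocalProjection(traj.home[0], traj.home[1])
    ll = traj.latlon
    x, y = proj.forward(ll[:, 0], ll[:, 1])
    xy = np.column_stack([x, y])
    span = float(np.max(np.hypot(x, y), initial=0.0))
    if span > max_span_m:
        raise ProjectionError(
            f"trajectory {traj.cat_id!r} extends {span:.0f} m from home; "
            f"local projection valid to {max_span_m:.0f} m"
        )
    return LocalTrack(
        cat_id=traj.cat_id,
        t=traj.times_s,
        xy=xy,
        loc_err_sd=traj.loc_err_sd,
        projection=proj,
    )


def read_cat_records(path: str | Path) -> pd.DataFrame:
    """Read the per-animal covariate table, enforcing the closed category sets."""
    df = pd.read_csv(path, dtype=str)
    required = {"cat_id", *CAT_RECORD_LEVELS, "municipality"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    for col, levels in CAT_RECORD_LEVELS.items():
        bad = set(df[col].dropna()) - set(levels)
        if bad:
            raise ValidationError(f"{path}: column {col!r} has values outside {levels}: {sorted(bad)}")
        df[col] = pd.Categorical(df[col], categories=levels)
    return df


def read_rainfall(path: str | Path) -> pd.DataFrame:
    """Read the (municipality, date, rainfall_mm) table."""
    df = pd.read_csv(path, dtype={"municipality": str})
    missing = {"municipality", "date", "rainfall_mm"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    if (df["rainfall_mm"] < 0).any() or not np.isfinite(df["rainfall_mm"]).all():
        raise ValidationError(f"{path}: rainfall_mm must be finite and non-negative")
    if df.duplicated(["municipality", "date"]).any():
        raise ValidationError(f"{path}: duplicate municipality-date records")
    return df
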