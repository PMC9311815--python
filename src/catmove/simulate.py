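"""Cohort simulator with known ground truth.

Movement is a two-state bout process: HOME dwells (a fixed jittered point at
the anchor) alternating with EXCURSIONS — straight travel to an attractor,
an Ornstein-Uhlenbeck wander around it, and straight travel back. The OU
wander has a closed-form stationary 95% ellipse, giving an analytic surface
the home-range estimator can be checked against. Device behaviour emulates
an accelerometer-triggered tracker: fixes every 2-10 min while moving and
hourly when stationary, with i.i.d. Gaussian location error per axis and
optional kilometre-scale blunders to exercise the speed filter.

Covariate effects are multiplicative (log scale) on excursion duration
(time away), excursion rate (distance) and spatial scale (home range);
rainfall shortens excursions via ``exp(rain_slope_per_mm * mm)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, time as dtime, timedelta
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

from catmove.errors import ValidationError
from catmove.tracks_io import (
    AGE_LEVELS,
    BREED_LEVELS,
    CAT_RECORD_LEVELS,
    DEFAULT_TIMEZONE,
    FOOD_LEVELS,
    LAND_USE_LEVELS,
    SEX_LEVELS,
    YES_NO_LEVELS,
    Fix,
    LocalProjection,
    Trajectory,
)

CHI2_2_Q95 = 5.991464547107979

DEFAULT_COVARIATE_WEIGHTS = {
    # roughly the cohort composition of a ~100-cat Danish companion-cat study
    "sex": [0.04, 0.46, 0.03, 0.47],
    "age_group": [0.33, 0.33, 0.34],
    "breed": [0.66, 0.15, 0.19],
    "food_access": [0.81, 0.19],
    "land_use": [0.32, 0.56, 0.12],
    "busy_road": [0.47, 0.53],
    "nature_access": [0.84, 0.16],
}

DEFAULT_AWAY_EFFECTS = {
    "age_group": {"8-16": -0.5},
    "nature_access": {"no": -0.6},
    "sex": {"neutered male": -0.25, "neutered female": -0.25},
}

DEFAULT_DIST_EFFECTS = {
    "age_group": {"8-16": -0.4},
    "nature_access": {"no": -0.4},
    "breed": {"domestic shorthair": -0.2},
}

DEFAULT_RANGE_EFFECTS = {
    "age_group": {"8-16": -0.4},
    "nature_access": {"no": -0.3},
}


@dataclass
class SimConfig:
    n_cats: int = 97
    days: int = 7
    seed: int = 0
    start_date: date = date(2021, 6, 1)
    tz: str = DEFAULT_TIMEZONE
    n_municipalities: int = 5
    n_interrupted: int = 0          # cats given one empty interior day
    covariate_weights: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_WEIGHTS))
    away_effects: dict = field(default_factory=lambda: dict(DEFAULT_AWAY_EFFECTS))
    dist_effects: dict = field(default_factory=lambda: dict(DEFAULT_DIST_EFFECTS))
    range_effects: dict = field(default_factory=lambda: dict(DEFAULT_RANGE_EFFECTS))
    rain_slope_per_mm: float = -0.08   # log-scale effect on excursion duration
    # movement
    home_dwell_mean_s: float = 3.0 * 3600
    excursion_mean_s: float = 2.5 * 3600
    attractor_dist_m: float = 200.0
    ou_sd_m: float = 50.0
    ou_tau_s: float = 900.0
    knot_s: float = 300.0
    travel_speed_mps: float = 1.0
    home_jitter_m: float = 10.0
    # device
    move_interval_s: tuple[float, float] = (120.0, 600.0)
    stationary_interval_s: float = 3600.0
    loc_err_sd: float = 13.1
    speed_move_threshold: float = 0.05
    blunder_rate_per_day: float = 0.0
    blunder_dist_m: tuple[float, float] = (500.0, 2000.0)
    # rainfall (zero-inflated gamma)
    rain_p_dry: float = 0.5
    rain_gamma_shape: float = 1.2
    rain_gamma_scale: float = 6.0

    def validate(self) -> None:
        for col, w in self.covariate_weights.items():
            levels = CAT_RECORD_LEVELS[col]
            if len(w) != len(levels):
                raise ValidationError(f"weights for {col!r} must have {len(levels)} entries")
            if any(p < 0 for p in w) or not math.isclose(sum(w), 1.0, abs_tol=1e-6):
                raise ValidationError(f"weights for {col!r} must be a probability vector")
        for name in ("home_dwell_mean_s", "excursion_mean_s", "ou_sd_m", "ou_tau_s",
                     "knot_s", "travel_speed_mps", "loc_err_sd"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if not 0 <= self.rain_p_dry <= 1:
            raise ValidationError("rain_p_dry must be in [0,1]")


@dataclass
class SimCohort:
    cats: pd.DataFrame            # CatRecord table + home lat/lon
    rainfall: pd.DataFrame        # municipality, date, rainfall_mm
    trajectories: list[Trajectory]
    truth_daily: pd.DataFrame     # cat_id, date, true_away_frac, true_path_m, rainfall_mm
    truth_cats: pd.DataFrame      # cat_id, multipliers, true_range_ha
    config: SimConfig


def _effect_multiplier(record: dict, effects: dict) -> float:
    s = 0.0
    for cov, per_level in effects.items():
        s += per_level.get(record[cov], 0.0)
    return math.exp(s)


def _clip_knots(kt: np.ndarray, kxy: np.ndarray, t_end: float) -> tuple[np.ndarray, np.ndarray]:
    """Truncate a piecewise-linear path at t_end, interpolating the endpoint."""
    if kt[-1] <= t_end:
        return kt, kxy
    i = int(np.searchsorted(kt, t_end))
    x = np.interp(t_end, kt, kxy[:, 0])
    y = np.interp(t_end, kt, kxy[:, 1])
    kt = np.append(kt[:i], t_end)
    kxy = np.vstack([kxy[:i], [x, y]])
    return kt, kxy


def simulate_cat_day(
    rng: np.random.Generator,
    cfg: SimConfig,
    away_mult: float = 1.0,
    range_mult: float = 1.0,
    excursion_rate_mult: float = 1.0,
    rainfall_mm: float = 0.0,
    day_s: float = 86400.0,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """One day of movement as a piecewise-linear path.

    Returns (knot_times_s, knot_xy_m, true_away_frac, true_path_m); truth is
    measured on a 1 s grid, with 'away' meaning > 50 m from the origin.
    """
    rain_mult = math.exp(cfg.rain_slope_per_mm * rainfall_mm)
    exc_mean = cfg.excursion_mean_s * away_mult * rain_mult
    dwell_mean = cfg.home_dwell_mean_s / max(excursion_rate_mult, 1e-6)
    sd = cfg.ou_sd_m * range_mult
    attract = cfg.attractor_dist_m * range_mult
    phi = math.exp(-cfg.knot_s / cfg.ou_tau_s)
    step_sd = sd * math.sqrt(1.0 - phi * phi)

    kt: list[float] = []
    kxy: list[tuple[float, float]] = []
    t = 0.0
    while t < day_s:
        # home dwell at a fixed jittered point
        r = cfg.home_jitter_m * math.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * math.pi)
        ph = (r * math.cos(th), r * math.sin(th))
        d = rng.exponential(dwell_mean)
        kt.extend([t, min(t + d, day_s)])
        kxy.extend([ph, ph])
        t += d
        if t >= day_s:
            break
        # excursion: out, wander, back
        e = rng.exponential(exc_mean)
        th_a = rng.uniform(0, 2 * math.pi)
        ra = attract * (0.6 + 0.8 * rng.uniform())
        a = np.array([ra * math.cos(th_a), ra * math.sin(th_a)])
        travel_out = ra / cfg.travel_speed_mps
        e = max(e, 2 * travel_out + cfg.knot_s)
        kt.append(t + travel_out)
        kxy.append(tuple(a))
        wander = e - 2 * travel_out
        m = max(int(wander // cfg.knot_s), 1)
        pos = a.copy()
        tw = t + travel_out
        for _ in range(m):
            pos = a + phi * (pos - a) + step_sd * rng.standard_normal(2)
            tw += cfg.knot_s
            kt.append(tw)
            kxy.append(tuple(pos))
        back = float(np.hypot(*pos)) / cfg.travel_speed_mps
        t = tw + back
        # the closing home point is appended by the next dwell iteration
        if t >= day_s:
            kt.append(t)
            kxy.append((0.0, 0.0))
            break

    kt_a = np.asarray(kt)
    kxy_a = np.asarray(kxy)
    # collapse any zero-length segments created by truncation
    keep = np.concatenate([[True], np.diff(kt_a) > 0])
    kt_a, kxy_a = kt_a[keep], kxy_a[keep]
    kt_a, kxy_a = _clip_knots(kt_a, kxy_a, day_s)

    grid = np.arange(0.0, day_s, 1.0)
    gx = np.interp(grid, kt_a, kxy_a[:, 0])
    gy = np.interp(grid, kt_a, kxy_a[:, 1])
    away_frac = float(np.mean(np.hypot(gx, gy) > 50.0))
    path_m = float(np.sum(np.hypot(np.diff(gx), np.diff(gy))))
    return kt_a, kxy_a, away_frac, path_m


def emit_fix_schedule(
    knot_t: np.ndarray,
    knot_xy: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
    t_start: float = 0.0,
    day_s: float = 86400.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample device fixes from a continuous path.

    The next-fix interval is uniform 2-10 min while the true speed exceeds
    the movement threshold and 60 min otherwise; like an accelerometer
    tracker, the device wakes early when movement resumes during a
    stationary interval. Gaussian location error is added per axis;
    optional blunders displace a fix by 0.5-2 km.
    """
    seg_t0 = knot_t[:-1]
    seg_dt = np.diff(knot_t)
    seg_v = np.hypot(*np.diff(knot_xy, axis=0).T) / seg_dt
    moving = seg_v > cfg.speed_move_threshold
    times = []
    t = t_start
    lo, hi = cfg.move_interval_s
    while t < day_s:
        times.append(t)
        i = min(int(np.searchsorted(seg_t0, t, side="right")) - 1, len(seg_v) - 1)
        i = max(i, 0)
        if moving[i]:
            t += rng.uniform(lo, hi)
        else:
            t_next = t + cfg.stationary_interval_s
            # accelerometer wake-up: first movement onset after t
            later = np.nonzero(moving & (seg_t0 > t))[0]
            if later.size and seg_t0[later[0]] < t_next:
                t_next = seg_t0[later[0]] + rng.uniform(10.0, 60.0)
            t = t_next
    times = np.asarray(times)
    x = np.interp(times, knot_t, knot_xy[:, 0])
    y = np.interp(times, knot_t, knot_xy[:, 1])
    xy = np.column_stack([x, y])
    xy += rng.normal(0.0, cfg.loc_err_sd, size=xy.shape)
    is_blunder = np.zeros(len(times), dtype=bool)
    # triangulation blunders: spurious fixes logged 30-90 s after a genuine
    # one, displaced 0.5-2 km (a displaced isolated fix at the regular
    # cadence would imply < 5 m/s and be invisible to the speed filter)
    n_blunder = rng.poisson(cfg.blunder_rate_per_day)
    if n_blunder > 0 and len(times) > 1:
        idx = rng.choice(len(times) - 1, size=min(n_blunder, len(times) - 1), replace=False)
        bt = times[idx] + rng.uniform(30.0, 90.0, size=len(idx))
        r = rng.uniform(*cfg.blunder_dist_m, size=len(idx))
        th = rng.uniform(0, 2 * math.pi, size=len(idx))
        bx = np.interp(bt, knot_t, knot_xy[:, 0]) + r * np.cos(th)
        by = np.interp(bt, knot_t, knot_xy[:, 1]) + r * np.sin(th)
        times = np.concatenate([times, bt])
        xy = np.vstack([xy, np.column_stack([bx, by])])
        is_blunder = np.concatenate([is_blunder, np.ones(len(idx), dtype=bool)])
        order = np.argsort(times)
        times, xy, is_blunder = times[order], xy[order], is_blunder[order]
    return times, xy, is_blunder


def _draw_covariates(rng: np.random.Generator, cfg: SimConfig, cat_id: str) -> dict:
    rec = {"cat_id": cat_id}
    for col, levels in CAT_RECORD_LEVELS.items():
        w = np.asarray(cfg.covariate_weights[col], dtype=float)
        rec[col] = levels[int(rng.choice(len(levels), p=w / w.sum()))]
    return rec


def simulate_rainfall(rng: np.random.Generator, cfg: SimConfig, dates: list[date]) -> pd.DataFrame:
    rows = []
    for m in range(cfg.n_municipalities):
        for d in dates:
            wet = rng.uniform() >= cfg.rain_p_dry
            mm = float(rng.gamma(cfg.rain_gamma_shape, cfg.rain_gamma_scale)) if wet else 0.0
            rows.append({"municipality": f"M{m:02d}", "date": d, "rainfall_mm": round(mm, 2)})
    return pd.DataFrame(rows)


def simulate_cohort(cfg: SimConfig) -> SimCohort:
    """Generate covariates, rainfall, trajectories and ground truth.

    Fully reproducible from ``cfg.seed``: identical config and seed give
    byte-identical outputs.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    zone = ZoneInfo(cfg.tz)
    dates = [cfg.start_date + timedelta(days=i) for i in range(cfg.days)]
    rainfall = simulate_rainfall(rng, cfg, dates)
    rain_lookup = {(r.municipality, r.date): r.rainfall_mm for r in rainfall.itertuples()}

    cat_rows, traj_list, daily_rows, catruth_rows = [], [], [], []
    for c in range(cfg.n_cats):
        cat_id = f"cat{c + 1:03d}"
        rec = _draw_covariates(rng, cfg, cat_id)
        rec["municipality"] = f"M{int(rng.integers(cfg.n_municipalities)):02d}"
        home_lat = float(rng.uniform(54.9, 57.4))
        home_lon = float(rng.uniform(8.3, 12.4))
        rec["home_lat"], rec["home_lon"] = home_lat, home_lon
        proj = LocalProjection(home_lat, home_lon)
        away_mult = _effect_multiplier(rec, cfg.away_effects)
        dist_mult = _effect_multiplier(rec, cfg.dist_effects)
        range_mult = _effect_multiplier(rec, cfg.range_effects)
        interrupted_day = cfg.days // 2 if c < cfg.n_interrupted and cfg.days >= 3 else None

        all_t, all_xy = [], []
        for di, d in enumerate(dates):
            day_start = datetime.combine(d, dtime(0, 0), tzinfo=zone).timestamp()
            mm = rain_lookup[(rec["municipality"], d)]
            kt, kxy, away_frac, path_m = simulate_cat_day(
                rng, cfg, away_mult=away_mult, range_mult=range_mult,
                excursion_rate_mult=dist_mult, rainfall_mm=mm,
            )
            daily_rows.append({
                "cat_id": cat_id, "date": d, "true_away_frac": away_frac,
                "true_path_m": path_m, "rainfall_mm": mm,
            })
            if di == interrupted_day:
                continue  # device outage: no fixes this day
            t0 = 60.0 if di == 0 else 0.0
            ft, fxy, _ = emit_fix_schedule(kt, kxy, cfg, rng, t_start=t0)
            all_t.append(ft + day_start)
            all_xy.append(fxy)

        t = np.concatenate(all_t)
        xy = np.vstack(all_xy)
        lat, lon = proj.inverse(xy[:, 0], xy[:, 1])
        fixes = [Fix(time=datetime.fromtimestamp(round(ti), tz=ZoneInfo("UTC")),
                     lat=float(la), lon=float(lo), loc_err_sd=cfg.loc_err_sd)
                 for ti, la, lo in zip(t, lat, lon)]
        # first coordinate equals the home address, anchoring 'home'
        first_time = min(f.time for f in fixes) - timedelta(seconds=30)
        fixes.insert(0, Fix(time=first_time, lat=home_lat, lon=home_lon,
                            loc_err_sd=cfg.loc_err_sd))
        traj_list.append(Trajectory(cat_id=cat_id, fixes=fixes, home=(home_lat, home_lon)))
        cat_rows.append(rec)
        catruth_rows.append({
            "cat_id": cat_id, "away_mult": away_mult, "dist_mult": dist_mult,
            "range_mult": range_mult,
            "true_range_ha": math.pi * (cfg.ou_sd_m * range_mult) ** 2 * CHI2_2_Q95 / 1e4,
            "interrupted": interrupted_day is not None,
        })

    cats = pd.DataFrame(cat_rows)
    for col, levels in CAT_RECORD_LEVELS.items():
        cats[col] = pd.Categorical(cats[col], categories=levels)
    return SimCohort(
        cats=cats,
        rainfall=rainfall,
        trajectories=traj_list,
        truth_daily=pd.DataFrame(daily_rows),
        truth_cats=pd.DataFrame(catruth_rows),
        config=cfg,
    )


# ---------------------------------------------------------------------------
# elementary reference tracks for estimator checks

def simulate_brownian_track(
    n_fixes: int,
    dt_s: float,
    sigma1: float,
    loc_err_sd: float,
    seed: int = 0,
    home: tuple[float, float] = (55.7, 12.5),
):
    """Pure Brownian motion observed with Gaussian error at fixed intervals."""
    from catmove.tracks_io import LocalTrack

    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, sigma1 * math.sqrt(dt_s), size=(n_fixes - 1, 2))
    xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    xy_obs = xy + rng.normal(0.0, loc_err_sd, size=xy.shape)
    t = np.arange(n_fixes, dtype=float) * dt_s
    return LocalTrack(
        cat_id=f"bm-{seed}", t=t, xy=xy_obs,
        loc_err_sd=np.full(n_fixes, loc_err_sd),
        projection=LocalProjection(*home),
    )


def simulate_ou_track(
    n_fixes: int,
    dt_s: float,
    sd_m: float,
    tau_s: float,
    loc_err_sd: float,
    seed: int = 0,
    home: tuple[float, float] = (55.7, 12.5),
):
    """Stationary Ornstein-Uhlenbeck track (per-axis stationary SD ``sd_m``)
    observed with Gaussian error. Its true 95% region has closed-form area
    pi * sd^2 * 5.991."""
    from catmove.tracks_io import LocalTrack

    rng = np.random.default_rng(seed)
    phi = math.exp(-dt_s / tau_s)
    innov_sd = sd_m * math.sqrt(1 - phi * phi)
    xy = np.empty((n_fixes, 2))
    xy[0] = rng.normal(0.0, sd_m, size=2)
    noise = rng.normal(0.0, innov_sd, size=(n_fixes - 1, 2))
    for i in range(1, n_fixes):
        xy[i] = phi * xy[i - 1] + noise[i - 1]
    xy_obs = xy + rng.normal(0.0, loc_err_sd, size=xy.shape)
    t = np.arange(n_fixes, dtype=float) * dt_s
    return LocalTrack(
        cat_id=f"ou-{seed}", t=t, xy=xy_obs,
        loc_err_sd=np.full(n_fixes, loc_err_sd),
        projection=LocalProjection(*home),
    )


def ou_area95_ha(sd_m: float) -> float:
    """Closed-form 95% ellipse area (ha) of an isotropic OU stationary law."""
    return math.pi * sd_m**2 * CHI2_2_Q95 / 1e4


# ---------------------------------------------------------------------------
# writers

def write_cohort(cohort: SimCohort, outdir, track_format: str = "csv") -> None:
    """Write tracks, covariates, rainfall and truth tables as plain text."""
    from pathlib import Path

    from catmove.tracks_io import write_track_csv

    outdir = Path(outdir)
    tracks = outdir / "tracks"
    tracks.mkdir(parents=True, exist_ok=True)
    for traj in cohort.trajectories:
        if track_format == "csv":
            write_track_csv(traj, tracks / f"{traj.cat_id}.csv")
        elif track_format == "gpx":
            write_track_gpx(traj, tracks / f"{traj.cat_id}.gpx")
        else:
            raise ValidationError(f"unknown track format {track_format!r}")
    cohort.cats.to_csv(outdir / "cats.csv", index=False)
    cohort.rainfall.to_csv(outdir / "rainfall.csv", index=False)
    cohort.truth_daily.to_csv(outdir / "truth_daily.csv", index=False)
    cohort.truth_cats.to_csv(outdir / "truth_cats.csv", index=False)


def write_track_gpx(traj: Trajectory, path) -> None:
    """Minimal GPX 1.1 writer (one track, one segment)."""
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<gpx version="1.1" creator="catmove" xmlns="http://www.topografix.com/GPX/1/1">',
        "<trk><trkseg>",
    ]
    for f in traj.fixes:
        lines.append(
            f'<trkpt lat="{f.lat!r}" lon="{f.lon!r}">'
            f"<time>{f.time.strftime('%Y-%m-%dT%H:%M:%SZ')}</time></trkpt>"
        )
    lines += ["</trkseg></trk>", "</gpx>", ""]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))
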