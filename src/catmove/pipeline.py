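"""End-to-end orchestration: simulate | clean | metrics | homerange | models | report.

Every stage reads and writes plain-text artifacts under the run directory,
stamped with the config hash and seed, so a rerun with the same config is
byte-identical. Exclusions (interrupted cats, area outliers) are logged
with machine-readable reason codes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from catmove import bbkde, inference, movement_metrics as mm, reports, simulate, tracks_io
from catmove.errors import CatmoveError, ConfigError, DataError

log = logging.getLogger("catmove")

ALL_STAGES = ["simulate", "clean", "metrics", "homerange", "models", "report"]

COVARIATE_TERMS = [
    "sex", "age_group", "breed", "food_access", "land_use", "busy_road", "nature_access",
]

RAIN_PREDICTION_LEVELS = [0.0, 5.0, 10.0, 15.0, 25.0, 30.0, 35.0, 45.0]


@dataclass
class RunConfig:
    out_dir: str = "run"
    tracks_dir: str | None = None     # defaults to <out>/sim/tracks after simulate
    cats_csv: str | None = None
    rainfall_csv: str | None = None
    seed: int = 0
    tz: str = tracks_io.DEFAULT_TIMEZONE
    # simulate
    n_cats: int = 20
    days: int = 7
    n_interrupted: int = 0
    blunder_rate_per_day: float = 0.0
    # clean
    min_band_count: int = 3
    # metrics
    home_radius_m: float = 50.0
    # homerange
    cell_m: float = 10.0
    ud_n_t: int = 10
    max_gap_s: float = 4 * 3600.0
    isopleth_levels: tuple[float, ...] = (0.5, 0.95)
    loc_err_sd: float = 13.1
    # models
    screen_alpha: float = 0.05
    alpha_timeaway: float = 0.05
    alpha_distance: float = 0.05
    alpha_homerange: float = 0.10
    outlier_ha: float = 90.0
    power_mode: str = "simple"
    log_base: float = 10.0
    confounding_threshold: float = 0.20

    def validate(self) -> None:
        if not 0 < self.home_radius_m:
            raise ConfigError("home_radius_m must be > 0")
        if not 0 < self.cell_m:
            raise ConfigError("cell_m must be > 0")
        for a in (self.screen_alpha, self.alpha_timeaway, self.alpha_distance,
                  self.alpha_homerange):
            if not 0 < a <= 1:
                raise ConfigError("alpha levels must be in (0, 1]")
        if self.power_mode not in ("simple", "normalized"):
            raise ConfigError("power_mode must be 'simple' or 'normalized'")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load a TOML config; unknown keys are rejected."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "isopleth_levels" in raw:
        raw["isopleth_levels"] = tuple(raw["isopleth_levels"])
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")


def _stamp(cfg: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    info = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
            "config": dataclasses.asdict(cfg)}
    (out / "run_info.json").write_text(json.dumps(info, indent=2, default=str, sort_keys=True))


def stage_simulate(cfg: RunConfig, out: Path) -> None:
    sim_cfg = simulate.SimConfig(
        n_cats=cfg.n_cats, days=cfg.days, seed=cfg.seed, tz=cfg.tz,
        n_interrupted=cfg.n_interrupted, blunder_rate_per_day=cfg.blunder_rate_per_day,
        loc_err_sd=cfg.loc_err_sd,
    )
    cohort = simulate.simulate_cohort(sim_cfg)
    simulate.write_cohort(cohort, out / "sim")
    log.info("simulated %d cats x %d days", cfg.n_cats, cfg.days)


def _resolve_inputs(cfg: RunConfig, out: Path):
    tracks_dir = Path(cfg.tracks_dir) if cfg.tracks_dir else out / "sim" / "tracks"
    cats_csv = Path(cfg.cats_csv) if cfg.cats_csv else out / "sim" / "cats.csv"
    rain_csv = Path(cfg.rainfall_csv) if cfg.rainfall_csv else out / "sim" / "rainfall.csv"
    if not tracks_dir.is_dir():
        raise DataError(f"tracks directory not found: {tracks_dir}")
    return tracks_dir, cats_csv, rain_csv


def stage_clean(cfg: RunConfig, out: Path) -> None:
    tracks_dir, _, _ = _resolve_inputs(cfg, out)
    clean_dir = out / "clean"
    clean_dir.mkdir(parents=True, exist_ok=True)
    logs = []
    paths = sorted(list(tracks_dir.glob("*.csv")) + list(tracks_dir.glob("*.gpx")))
    if not paths:
        raise DataError(f"no track files in {tracks_dir}")
    for p in paths:
        traj = tracks_io.read_track(p)
        traj = tracks_io.anchor_home(traj)
        cleaned, clog = tracks_io.clean_track(traj, min_band_count=cfg.min_band_count)
        tracks_io.write_track_csv(cleaned, clean_dir / f"{traj.cat_id}.csv")
        logs.append({"cat_id": traj.cat_id, **clog})
    _write_csv(pd.DataFrame(logs), out / "cleaning_log.csv")


def _load_clean_tracks(cfg: RunConfig, out: Path) -> list[tracks_io.Trajectory]:
    clean_dir = out / "clean"
    if not clean_dir.is_dir():
        raise DataError("run the 'clean' stage first")
    trajs = []
    for p in sorted(clean_dir.glob("*.csv")):
        traj = tracks_io.read_track(p)
        # home anchor is the first coordinate by construction
        trajs.append(tracks_io.anchor_home(traj))
    return trajs


def stage_metrics(cfg: RunConfig, out: Path) -> None:
    _, cats_csv, rain_csv = _resolve_inputs(cfg, out)
    cats = tracks_io.read_cat_records(cats_csv)
    rain = tracks_io.read_rainfall(rain_csv) if Path(rain_csv).exists() else None
    muni = dict(zip(cats["cat_id"], cats["municipality"]))
    trajs = _load_clean_tracks(cfg, out)
    daily_all, summaries, exclusions = [], [], []
    n_cohort = len(trajs)
    for traj in trajs:
        df = mm.daily_metrics(traj, radius=cfg.home_radius_m, tz=cfg.tz,
                              rainfall=rain, municipality=muni.get(traj.cat_id))
        try:
            trimmed = mm.trim_first_last_days(df)
        except CatmoveError as exc:
            exclusions.append({"cat_id": traj.cat_id, "stage": "metrics",
                               "reason_code": "TOO_FEW_DAYS", "detail": str(exc)})
            continue
        daily_all.append(trimmed)
        s = mm.summarize_cat(traj, trimmed, n_cohort=n_cohort, tz=cfg.tz)
        summaries.append(dataclasses.asdict(s))
        if s.interrupted:
            exclusions.append({"cat_id": traj.cat_id, "stage": "metrics",
                               "reason_code": "INTERRUPTED",
                               "detail": "empty interior tracking day"})
    if not daily_all:
        raise DataError("no cat produced usable daily metrics")
    _write_csv(pd.concat(daily_all, ignore_index=True), out / "daily_metrics.csv")
    _write_csv(pd.DataFrame(summaries), out / "cat_summary.csv")
    _append_exclusions(out, exclusions)


def _append_exclusions(out: Path, rows: list[dict]) -> None:
    path = out / "exclusions.csv"
    df = pd.DataFrame(rows, columns=["cat_id", "stage", "reason_code", "detail"])
    if path.exists():
        prev = pd.read_csv(path)
        df = pd.concat([prev, df], ignore_index=True).drop_duplicates(
            subset=["cat_id", "stage", "reason_code"])
    _write_csv(df, path)


def stage_homerange(cfg: RunConfig, out: Path) -> None:
    trajs = _load_clean_tracks(cfg, out)
    rows = []
    for traj in trajs:
        try:
            hr = bbkde.home_range(
                traj, levels=cfg.isopleth_levels, loc_err_sd=cfg.loc_err_sd,
                cell=cfg.cell_m, n_t=cfg.ud_n_t, max_gap_s=cfg.max_gap_s,
            )
        except CatmoveError as exc:
            raise DataError(f"home range failed for {traj.cat_id}: {exc}") from exc
        row = {"cat_id": hr.cat_id, "sigma1": hr.sigma1}
        for lv, a in hr.areas_ha.items():
            row[f"area{int(round(lv * 100))}_ha"] = a
        rows.append(row)
    _write_csv(pd.DataFrame(rows), out / "homerange.csv")


def _eliminate_with_pruning(data, response, terms, alpha, kind, out, label, **options):
    """Backward elimination, dropping trailing candidate terms while the full
    model is unidentifiable (small cohorts); prunes are logged."""
    from catmove.errors import FitError

    terms = list(terms)
    pruned = []
    while terms:
        try:
            return inference.backward_eliminate(data, response, terms, alpha, kind, **options)
        except FitError as exc:
            if "cannot identify" not in str(exc) or len(terms) == 1:
                raise
            pruned.append(terms.pop())
            log.warning("%s: pruned term %s (%s)", label, pruned[-1], exc)
    raise DataError(f"{label}: no identifiable model")


def stage_models(cfg: RunConfig, out: Path) -> None:
    _, cats_csv, _ = _resolve_inputs(cfg, out)
    cats = tracks_io.read_cat_records(cats_csv)
    summary = pd.read_csv(out / "cat_summary.csv")
    daily = pd.read_csv(out / "daily_metrics.csv", parse_dates=["date"])
    hr = pd.read_csv(out / "homerange.csv")

    screen = inference.association_screen(cats, COVARIATE_TERMS,
                                          alpha=cfg.screen_alpha, seed=cfg.seed)
    _write_csv(screen.pairs, out / "association_screen.csv")
    terms = [t for t in COVARIATE_TERMS if t not in screen.exclusions]
    exclusions: list[dict] = []

    # --- time away: beta regression on per-cat fraction
    tbl = summary.merge(cats, on="cat_id")
    for col, levels in tracks_io.CAT_RECORD_LEVELS.items():
        tbl[col] = pd.Categorical(tbl[col], categories=levels)
    fit_away, trace_away = _eliminate_with_pruning(
        tbl, "frac_away", terms, cfg.alpha_timeaway, "beta", out, "timeaway")
    _write_csv(_coef_table(fit_away), out / "table1_timeaway.csv")
    _write_csv(trace_away, out / "trace_timeaway.csv")
    conf_away = inference.confounding_check(
        tbl, "frac_away", fit_away.terms, "beta",
        threshold=cfg.confounding_threshold) if len(fit_away.terms) >= 2 else pd.DataFrame()
    _write_csv(conf_away, out / "confounding_timeaway.csv")

    # --- daily distance: Box-Cox + AR1 mixed model
    dd = daily.merge(cats, on="cat_id")
    for col, levels in tracks_io.CAT_RECORD_LEVELS.items():
        dd[col] = pd.Categorical(dd[col], categories=levels)
    interrupted = set(summary.loc[summary["interrupted"].astype(bool), "cat_id"])
    for cid in sorted(interrupted):
        exclusions.append({"cat_id": cid, "stage": "models",
                           "reason_code": "INTERRUPTED",
                           "detail": "excluded from distance model"})
    dd = dd[~dd["cat_id"].isin(interrupted)]
    dd = dd[dd["distance_m"] > 0].copy()
    if "rainfall_mm" not in dd.columns:
        dd["rainfall_mm"] = 0.0
    dd["rainfall_mm"] = dd["rainfall_mm"].fillna(0.0)
    dd["day"] = (dd["date"] - dd["date"].min()).dt.days
    lam = inference.boxcox_lambda(dd["distance_m"].to_numpy(), dd,
                                  ["rainfall_mm"] + terms)
    dist_terms = ["rainfall_mm"] + terms
    fit_dist, trace_dist = _eliminate_with_pruning(
        dd, "distance_m", dist_terms, cfg.alpha_distance, "lmm_ar1", out, "distance",
        lam=lam, power_mode=cfg.power_mode)
    _write_csv(_coef_table(fit_dist), out / "table2_distance.csv")
    _write_csv(trace_dist, out / "trace_distance.csv")
    pd.DataFrame([{"lambda": lam, "sigma2": fit_dist.extra["sigma2"],
                   "tau2": fit_dist.extra["tau2"],
                   "ar1_rho": fit_dist.extra["ar1_rho"]}]).to_csv(
        out / "distance_model_params.csv", index=False)
    if "rainfall_mm" in fit_dist.terms:
        pred = inference.predict_rainfall_curve(fit_dist, RAIN_PREDICTION_LEVELS)
        _write_csv(pred, out / "table3_rainfall.csv")
    conf_dist = inference.confounding_check(
        dd, "distance_m", fit_dist.terms, "lmm_ar1",
        threshold=cfg.confounding_threshold, lam=lam,
        power_mode=cfg.power_mode) if len(fit_dist.terms) >= 2 else pd.DataFrame()
    _write_csv(conf_dist, out / "confounding_distance.csv")

    # --- home range: log-scale linear model
    ht = hr.merge(cats, on="cat_id")
    for col, levels in tracks_io.CAT_RECORD_LEVELS.items():
        ht[col] = pd.Categorical(ht[col], categories=levels)
    # outlier filter + log transform via an intercept-only prep fit, so small
    # cohorts cannot fail on an over-parameterized full model here
    fit_hr0, kept = inference.fit_homerange_lm(
        ht, [], outlier_ha=cfg.outlier_ha, log_base=cfg.log_base)
    for cid in ht.loc[~ht["cat_id"].isin(kept["cat_id"]), "cat_id"]:
        exclusions.append({"cat_id": cid, "stage": "models",
                           "reason_code": "AREA_OUTLIER",
                           "detail": f"area95_ha > {cfg.outlier_ha}"})
    fit_hr, trace_hr = _eliminate_with_pruning(
        kept, fit_hr0.response, terms, cfg.alpha_homerange, "lm", out, "homerange")
    _write_csv(_coef_table(fit_hr), out / "table5_homerange.csv")
    _write_csv(trace_hr, out / "trace_homerange.csv")

    _append_exclusions(out, exclusions)


def _coef_table(fit: inference.ModelFit) -> pd.DataFrame:
    tab = fit.coef_table().reset_index(names="coef")
    var, level = [], []
    for name in tab["coef"]:
        if "[" in name:
            v, l = name.split("[", 1)
            var.append(v)
            level.append(l.rstrip("]"))
        else:
            var.append(name)
            level.append("")
    tab.insert(0, "variable", var)
    tab.insert(1, "level", level)
    return tab[["variable", "level", "estimate", "se", "stat", "p"]]


def stage_report(cfg: RunConfig, out: Path) -> None:
    _, cats_csv, _ = _resolve_inputs(cfg, out)
    cats = tracks_io.read_cat_records(cats_csv)
    hr = pd.read_csv(out / "homerange.csv").merge(cats, on="cat_id")
    for col, levels in tracks_io.CAT_RECORD_LEVELS.items():
        hr[col] = pd.Categorical(hr[col], categories=levels)
    table4 = reports.report_descriptives(hr, "area95_ha", COVARIATE_TERMS)
    _write_csv(table4, out / "table4_descriptives.csv")


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "clean": stage_clean,
    "metrics": stage_metrics,
    "homerange": stage_homerange,
    "models": stage_models,
    "report": stage_report,
}


def run_pipeline(cfg: RunConfig, stages: list[str] | None = None) -> Path:
    """Execute the requested stages in canonical order; returns the run dir."""
    cfg.validate()
    stages = stages or ALL_STAGES
    bad = [s for s in stages if s not in STAGE_FUNCS]
    if bad:
        raise ConfigError(f"unknown stages: {bad}")
    ordered = [s for s in ALL_STAGES if s in stages]
    out = Path(cfg.out_dir)
    _stamp(cfg, out)
    for s in ordered:
        log.info("stage %s", s)
        try:
            STAGE_FUNCS[s](cfg, out)
        except CatmoveError:
            raise
        except Exception as exc:  # structured halt naming the stage
            raise CatmoveError(f"stage {s!r} failed: {exc}") from exc
    return out
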