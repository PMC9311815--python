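"""Brownian-bridge kernel utilization distributions and isopleth home ranges.

The utilization distribution (UD) spreads probability along the straight
path between consecutive fixes. Conditional on the two endpoints, the
position at relative time ``t`` in a segment of duration ``T`` is bivariate
normal with mean on the chord and variance

    s^2(t) = T * t * (1 - t) * sigma1^2 + (1 - t)^2 * delta^2 + t^2 * delta^2

where ``sigma1`` (m * s^-1/2) is the diffusion coefficient and ``delta`` the
GPS location-error SD. The diffusion coefficient is estimated by
leave-one-out likelihood on the odd-indexed fixes, and the UD is a
time-weighted mixture of these bridge normals, discretized on a raster.
Home-range areas are cell-counting isopleths of the raster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from shapely.geometry import MultiPoint

from catmove.errors import InsufficientDataError, ValidationError
from catmove.tracks_io import DEFAULT_LOC_ERR_SD, LocalTrack, Trajectory, to_local_xy

SIGMA1_MAX_DEFAULT = 5.0  # m s^-1/2
DEFAULT_CELL_M = 10.0
DEFAULT_N_T = 10
DEFAULT_MAX_GAP_S = 4 * 3600.0
CHI2_2_Q95 = 5.991464547107979  # 95% quantile of chi-square with 2 df


@dataclass(frozen=True)
class BridgeModel:
    """Parameters of the bridge kernel: diffusion and location error."""

    sigma1: float  # m s^-1/2
    loc_err_sd: float = DEFAULT_LOC_ERR_SD

    def __post_init__(self) -> None:
        if self.sigma1 < 0:
            raise ValidationError(f"sigma1 must be >= 0, got {self.sigma1}")
        if not self.loc_err_sd > 0:
            raise ValidationError(f"loc_err_sd must be > 0, got {self.loc_err_sd}")


@dataclass
class UDGrid:
    """Raster utilization distribution.

    ``origin`` is the centre of cell [0, 0] (row 0 = smallest y);
    ``masses[iy, ix]`` is the probability mass of a cell.
    """

    origin: tuple[float, float]
    cell: float
    masses: np.ndarray

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin[0] + self.cell * np.arange(self.masses.shape[1])

    @property
    def y_centers(self) -> np.ndarray:
        return self.origin[1] + self.cell * np.arange(self.masses.shape[0])

    def total_mass(self) -> float:
        return float(self.masses.sum())


@dataclass
class HomeRangeResult:
    cat_id: str
    sigma1: float
    areas_ha: dict[float, float]
    cell: float
    extent: tuple[float, float, float, float]  # xmin, xmax, ymin, ymax


def _loo_terms(t: np.ndarray, xy: np.ndarray, loc_err_sd: float):
    """Bridge prediction terms for odd-indexed fixes between their neighbours."""
    n = len(t)
    idx = np.arange(1, n - 1, 2)
    if len(idx) == 0:
        raise InsufficientDataError("need >= 3 fixes to estimate sigma1")
    t0, t1, t2 = t[idx - 1], t[idx], t[idx + 1]
    total = t2 - t0
    tstar = (t1 - t0) / total
    mu = xy[idx - 1] + tstar[:, None] * (xy[idx + 1] - xy[idx - 1])
    d2 = np.sum((xy[idx] - mu) ** 2, axis=1)
    alpha = total * tstar * (1.0 - tstar)  # multiplies sigma1^2
    # endpoint errors propagate through the interpolation; the predicted
    # fix carries its own observation error too (omitting it biases
    # sigma1^2 upward by delta^2 / alpha)
    noise = (1.0 + (1.0 - tstar) ** 2 + tstar**2) * loc_err_sd**2
    return d2, alpha, noise


def estimate_sigma1(
    track: LocalTrack,
    loc_err_sd: float | None = None,
    sigma1_max: float = SIGMA1_MAX_DEFAULT,
) -> float:
    """Maximum-likelihood diffusion coefficient via leave-one-out bridges.

    Every odd-indexed fix is predicted from its two neighbours; the product
    of the resulting bivariate normal densities is maximized over
    ``sigma1`` in [0, sigma1_max] by bounded 1-D search.
    """
    if len(track) < 3:
        raise InsufficientDataError("need >= 3 fixes to estimate sigma1")
    delta = float(loc_err_sd) if loc_err_sd is not None else float(np.median(track.loc_err_sd))
    d2, alpha, noise = _loo_terms(track.t, track.xy, delta)

    def nll(sigma1: float) -> float:
        s2 = alpha * sigma1**2 + noise
        # bivariate isotropic normal: log f = -log(2 pi s2) - d2 / (2 s2)
        return float(np.sum(np.log(s2) + d2 / (2.0 * s2)))

    res = minimize_scalar(nll, bounds=(0.0, sigma1_max), method="bounded", options={"xatol": 1e-6})
    sigma1 = float(res.x)
    if sigma1 > sigma1_max * (1 - 1e-3):
        warnings.warn(
            f"sigma1 estimate {sigma1:.3f} at upper bound {sigma1_max}; "
            "consider raising sigma1_max",
            stacklevel=2,
        )
    return sigma1


def bridge_nll(track: LocalTrack, sigma1: float, loc_err_sd: float) -> float:
    """Leave-one-out negative log-likelihood at a given sigma1 (for checks)."""
    d2, alpha, noise = _loo_terms(track.t, track.xy, loc_err_sd)
    s2 = alpha * sigma1**2 + noise
    return float(np.sum(np.log(2.0 * np.pi * s2) + d2 / (2.0 * s2)))


def compute_ud(
    track: LocalTrack,
    model: BridgeModel,
    cell: float = DEFAULT_CELL_M,
    pad: float | None = None,
    n_t: int = DEFAULT_N_T,
    max_gap_s: float | None = DEFAULT_MAX_GAP_S,
) -> UDGrid:
    """Discretized Brownian-bridge UD over a raster covering the track.

    The time integral along each segment is evaluated by the midpoint rule
    at ``n_t`` points; each point contributes an isotropic Gaussian weighted
    by its share of total tracked time. Segments longer than ``max_gap_s``
    are dropped (with their time removed from the denominator) so bridges do
    not fabricate corridors across tracking interruptions. Masses are
    normalized to sum to 1.
    """
    if not cell > 0:
        raise ValidationError(f"cell must be > 0, got {cell}")
    delta = model.loc_err_sd
    if cell > 3.0 * delta:
        warnings.warn(
            f"cell {cell} m is coarse relative to location error {delta} m",
            stacklevel=2,
        )
    t, xy = track.t, track.xy
    if len(t) < 2:
        raise InsufficientDataError("need >= 2 fixes for a UD")
    dt = np.diff(t)
    keep = dt > 0
    if max_gap_s is not None:
        keep &= dt <= max_gap_s
    if not keep.any():
        raise InsufficientDataError("no usable segments after gap exclusion")

    seg_i = np.nonzero(keep)[0]
    seg_dt = dt[seg_i]
    total_time = float(seg_dt.sum())

    # bridge spread at the midpoint bounds the kernel width
    s_mid = np.sqrt(seg_dt * model.sigma1**2 / 4.0 + delta**2 / 2.0)
    s_max = float(max(np.max(s_mid), delta))
    if pad is None:
        pad = 3.0 * s_max

    used = np.unique(np.concatenate([seg_i, seg_i + 1]))
    xmin, ymin = xy[used].min(axis=0) - pad
    xmax, ymax = xy[used].max(axis=0) + pad
    nx = int(np.ceil((xmax - xmin) / cell)) + 1
    ny = int(np.ceil((ymax - ymin) / cell)) + 1
    xc = xmin + cell * np.arange(nx)
    yc = ymin + cell * np.arange(ny)
    masses = np.zeros((ny, nx))

    # midpoint quadrature nodes in (0, 1)
    tq = (np.arange(n_t) + 0.5) / n_t
    w_time = seg_dt / (total_time * n_t)  # per-node weight of each segment

    a = xy[seg_i]
    b = xy[seg_i + 1]
    sig2 = model.sigma1**2
    cell2 = cell * cell
    for j, tj in enumerate(tq):
        mu = a + tj * (b - a)
        s2 = seg_dt * tj * (1.0 - tj) * sig2 + ((1.0 - tj) ** 2 + tj**2) * delta**2
        s = np.sqrt(s2)
        # accumulate each Gaussian on a local window of ~5 SD
        for k in range(len(seg_i)):
            sk = s[k]
            mx, my = mu[k]
            half = 5.0 * sk
            ix0 = max(int((mx - half - xmin) // cell), 0)
            ix1 = min(int((mx + half - xmin) // cell) + 2, nx)
            iy0 = max(int((my - half - ymin) // cell), 0)
            iy1 = min(int((my + half - ymin) // cell) + 2, ny)
            if ix0 >= ix1 or iy0 >= iy1:
                continue
            gx = np.exp(-0.5 * ((xc[ix0:ix1] - mx) / sk) ** 2)
            gy = np.exp(-0.5 * ((yc[iy0:iy1] - my) / sk) ** 2)
            masses[iy0:iy1, ix0:ix1] += (
                w_time[k] * cell2 / (2.0 * np.pi * s2[k])
            ) * np.outer(gy, gx)

    total = masses.sum()
    if total <= 0:
        raise ValidationError("UD accumulated zero mass; grid misconfigured")
    masses /= total
    return UDGrid(origin=(float(xmin), float(ymin)), cell=float(cell), masses=masses)


def isopleth_area(ud: UDGrid, level: float) -> float:
    """Area (hectares) of the smallest set of cells whose cumulative mass
    reaches ``level``, taking cells in order of decreasing mass."""
    if not 0.0 < level < 1.0:
        raise ValidationError(f"isopleth level must be in (0,1), got {level}")
    flat = np.sort(ud.masses.ravel())[::-1]
    csum = np.cumsum(flat)
    n_cells = int(np.searchsorted(csum, level) + 1)
    n_cells = min(n_cells, flat.size)
    return n_cells * ud.cell**2 / 1e4


def home_range(
    traj: Trajectory,
    levels: tuple[float, ...] = (0.5, 0.95),
    loc_err_sd: float | None = None,
    cell: float = DEFAULT_CELL_M,
    n_t: int = DEFAULT_N_T,
    max_gap_s: float | None = DEFAULT_MAX_GAP_S,
    sigma1_max: float = SIGMA1_MAX_DEFAULT,
) -> HomeRangeResult:
    """End-to-end home range: project, estimate sigma1, build the UD, and
    measure the isopleth area at each requested level."""
    track = to_local_xy(traj)
    delta = float(loc_err_sd) if loc_err_sd is not None else float(np.median(track.loc_err_sd))
    sigma1 = estimate_sigma1(track, loc_err_sd=delta, sigma1_max=sigma1_max)
    model = BridgeModel(sigma1=sigma1, loc_err_sd=delta)
    ud = compute_ud(track, model, cell=cell, n_t=n_t, max_gap_s=max_gap_s)
    areas = {lv: isopleth_area(ud, lv) for lv in sorted(levels)}
    ny, nx = ud.masses.shape
    extent = (
        ud.origin[0] - cell / 2,
        ud.origin[0] + cell * (nx - 0.5),
        ud.origin[1] - cell / 2,
        ud.origin[1] + cell * (ny - 0.5),
    )
    return HomeRangeResult(
        cat_id=traj.cat_id, sigma1=sigma1, areas_ha=areas, cell=cell, extent=extent
    )


def mcp_area(xy: np.ndarray, fraction: float = 1.0) -> float:
    """Minimum-convex-polygon area (hectares) of the ``fraction`` of fixes
    closest to the centroid. Comparison utility only."""
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 3:
        raise InsufficientDataError("need >= 3 fixes for a convex polygon")
    if not 0.0 < fraction <= 1.0:
        raise ValidationError(f"fraction must be in (0,1], got {fraction}")
    if fraction < 1.0:
        centroid = xy.mean(axis=0)
        d = np.hypot(*(xy - centroid).T)
        n_keep = max(int(round(fraction * len(xy))), 3)
        xy = xy[np.argsort(d)[:n_keep]]
    hull = MultiPoint([tuple(p) for p in xy]).convex_hull
    area = getattr(hull, "area", 0.0)
    if area == 0.0:
        warnings.warn("collinear fixes: MCP area is zero", stacklevel=2)
    return area / 1e4


def write_esri_ascii(ud: UDGrid, path) -> None:
    """Write the UD raster as an ESRI ASCII grid (probability mass per cell)."""
    ny, nx = ud.masses.shape
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {nx}\n")
        fh.write(f"nrows {ny}\n")
        fh.write(f"xllcorner {ud.origin[0] - ud.cell / 2}\n")
        fh.write(f"yllcorner {ud.origin[1] - ud.cell / 2}\n")
        fh.write(f"cellsize {ud.cell}\n")
        fh.write("NODATA_value -9999\n")
        for row in ud.masses[::-1]:  # ESRI rows run north to south
            fh.write(" ".join(f"{v:.10e}" for v in row) + "\n")


def isopleth_geojson(ud: UDGrid, level: float, projection) -> dict:
    """Isopleth cell outlines as a GeoJSON MultiPolygon in WGS84.

    Each selected cell becomes a square ring, unprojected through the
    inverse local projection. Coarse but dependency-free.
    """
    if not 0.0 < level < 1.0:
        raise ValidationError(f"isopleth level must be in (0,1), got {level}")
    flat = ud.masses.ravel()
    order = np.argsort(flat)[::-1]
    csum = np.cumsum(flat[order])
    n_cells = int(np.searchsorted(csum, level) + 1)
    chosen = order[:n_cells]
    ny, nx = ud.masses.shape
    half = ud.cell / 2.0
    polys = []
    for flat_i in chosen:
        iy, ix = divmod(int(flat_i), nx)
        cx = ud.origin[0] + ud.cell * ix
        cy = ud.origin[1] + ud.cell * iy
        corners = [
            (cx - half, cy - half),
            (cx + half, cy - half),
            (cx + half, cy + half),
            (cx - half, cy + half),
            (cx - half, cy - half),
        ]
        ring = []
        for x, y in corners:
            lat, lon = projection.inverse(np.array([x]), np.array([y]))
            ring.append([float(lon[0]), float(lat[0])])
        polys.append([ring])
    return {
        "type": "Feature",
        "properties": {"level": level},
        "geometry": {"type": "MultiPolygon", "coordinates": polys},
    }
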