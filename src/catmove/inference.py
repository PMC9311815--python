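"""Regression stage: collinearity screen, beta regression for time budgets,
Box-Cox + AR1 mixed model for daily distance, log-scale linear model for
home-range area, type-II tests, backward elimination, confounding checks,
pairwise contrasts and rainfall predictions.

All three model kinds are fitted by maximum likelihood with a common term
interface so that type-II likelihood-ratio tests, backward elimination and
confounding checks can refit any of them uniformly.

The power transform for the distance response is the plain ``y ** lambda``
("simple" mode): reported metre-scale model intercepts are only consistent
with back-transformed predictions on that scale. The normalized Box-Cox
variant ``(y**lambda - 1)/lambda`` is available via ``power_mode``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from catmove.errors import FitError, InsufficientDataError, ValidationError

__all__ = [
    "DesignInfo",
    "ModelFit",
    "ScreenResult",
    "association_screen",
    "build_design",
    "fit_model",
    "fit_beta_regression",
    "boxcox_lambda",
    "fit_distance_lmm",
    "fit_homerange_lm",
    "anova_type2",
    "backward_eliminate",
    "confounding_check",
    "posthoc_pairwise",
    "predict_rainfall_curve",
]


# ---------------------------------------------------------------------------
# design matrices

@dataclass
class DesignInfo:
    terms: list[str]
    names: list[str]                      # includes "(Intercept)" first
    term_cols: dict[str, list[int]]       # term -> column indices in X
    levels: dict[str, list[str]]          # categorical terms only
    numeric_means: dict[str, float]


def _term_levels(col: pd.Series) -> list[str] | None:
    if isinstance(col.dtype, pd.CategoricalDtype):
        present = [c for c in col.cat.categories if (col == c).any()]
        return present
    if col.dtype == object or pd.api.types.is_string_dtype(col):
        seen: list[str] = []
        for v in col:
            if v not in seen:
                seen.append(v)
        return seen
    return None


def build_design(data: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, DesignInfo]:
    """Intercept + treatment-coded design matrix.

    Categorical columns contribute one indicator per non-reference level
    (reference = first declared category); numeric columns enter as-is.
    """
    n = len(data)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["(Intercept)"]
    term_cols: dict[str, list[int]] = {}
    levels: dict[str, list[str]] = {}
    numeric_means: dict[str, float] = {}
    for term in terms:
        if term not in data.columns:
            raise ValidationError(f"term {term!r} not in data columns")
        col = data[term]
        lvls = _term_levels(col)
        idxs = []
        if lvls is not None:
            if col.isna().any():
                raise ValidationError(f"term {term!r} has missing values")
            levels[term] = lvls
            for lv in lvls[1:]:
                idxs.append(len(names))
                cols.append((col == lv).to_numpy(dtype=float))
                names.append(f"{term}[{lv}]")
        else:
            vals = col.to_numpy(dtype=float)
            if not np.isfinite(vals).all():
                raise ValidationError(f"term {term!r} has non-finite values")
            numeric_means[term] = float(vals.mean())
            idxs.append(len(names))
            cols.append(vals)
            names.append(term)
        term_cols[term] = idxs
    X = np.column_stack(cols)
    return X, DesignInfo(list(terms), names, term_cols, levels, numeric_means)


# ---------------------------------------------------------------------------
# fitted-model container

@dataclass
class ModelFit:
    """Common fitted-model summary across the three model kinds."""

    kind: str                       # beta | lmm_ar1 | lm
    response: str
    terms: list[str]
    params: pd.Series               # named coefficient estimates
    se: pd.Series
    vcov: pd.DataFrame              # coefficient covariance
    loglik: float
    n: int
    design: DesignInfo
    options: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)   # phi, lam, tau2, rho, r2, ...

    @property
    def n_params(self) -> int:
        """Number of mean-structure parameters (coefficients)."""
        return len(self.params)

    def coef_table(self) -> pd.DataFrame:
        z = self.params / self.se
        df_resid = self.extra.get("df_resid")
        if df_resid is not None:
            p = 2 * stats.t.sf(np.abs(z), df_resid)
        else:
            p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {"estimate": self.params, "se": self.se, "stat": z, "p": p}
        )


def fit_model(kind: str, data: pd.DataFrame, response: str, terms: list[str], **options) -> ModelFit:
    """Dispatch to a fitter by kind; used by the elimination machinery."""
    if kind == "beta":
        return fit_beta_regression(data, response, terms, **options)
    if kind == "lmm_ar1":
        return fit_distance_lmm(data, response=response, terms=terms, **options)
    if kind == "lm":
        return _fit_lm(data, response, terms, **options)
    raise ValidationError(f"unknown model kind {kind!r}")


# ---------------------------------------------------------------------------
# collinearity screen

@dataclass
class ScreenResult:
    pairs: pd.DataFrame       # var1, var2, statistic, p, flagged, method
    exclusions: list[str]


def association_screen(
    data: pd.DataFrame,
    covariates: list[str],
    alpha: float = 0.05,
    seed: int = 0,
    n_mc: int = 2000,
) -> ScreenResult:
    """Pairwise chi-squared association screen over categorical covariates.

    Pairs with p < alpha are flagged. Within each flagged pair the member
    flagged against more partners (tie broken toward the later column) is
    listed for exclusion. Tables with expected counts below 1 fall back to
    a seeded Monte-Carlo p-value with fixed margins.
    """
    if len(covariates) < 2:
        return ScreenResult(
            pd.DataFrame(columns=["var1", "var2", "statistic", "p", "flagged", "method"]),
            [],
        )
    rng = np.random.default_rng(seed)
    rows = []
    for v1, v2 in itertools.combinations(covariates, 2):
        tab = pd.crosstab(data[v1], data[v2]).to_numpy()
        tab = tab[tab.sum(axis=1) > 0][:, tab.sum(axis=0) > 0]
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            continue
        res = stats.chi2_contingency(tab)
        if (res.expected_freq < 1.0).any():
            statistic = float(res.statistic)
            r, c = tab.sum(axis=1), tab.sum(axis=0)
            sim = stats.random_table(r, c).rvs(n_mc, random_state=rng)
            exp = np.outer(r, c) / tab.sum()
            sim_stats = ((sim - exp) ** 2 / exp).sum(axis=(1, 2))
            obs = float(((tab - exp) ** 2 / exp).sum())
            p = float((1 + np.sum(sim_stats >= obs)) / (1 + n_mc))
            method = "monte-carlo"
            statistic = obs
        else:
            statistic, p, method = float(res.statistic), float(res.pvalue), "chi2"
        rows.append(
            {"var1": v1, "var2": v2, "statistic": statistic, "p": p,
             "flagged": p < alpha, "method": method}
        )
    pairs = pd.DataFrame(rows)
    exclusions: list[str] = []
    if len(pairs) and pairs["flagged"].any():
        flagged = pairs[pairs["flagged"]]
        counts = {v: 0 for v in covariates}
        for _, r in flagged.iterrows():
            counts[r["var1"]] += 1
            counts[r["var2"]] += 1
        order = {v: i for i, v in enumerate(covariates)}
        for _, r in flagged.iterrows():
            a, b = r["var1"], r["var2"]
            if (counts[a], order[a]) >= (counts[b], order[b]):
                pick = a
            else:
                pick = b
            if pick not in exclusions:
                exclusions.append(pick)
    return ScreenResult(pairs, exclusions)


# ---------------------------------------------------------------------------
# beta regression

def _num_hessian(f, x0: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    k = len(x0)
    h = rel_step * np.maximum(np.abs(x0), 1.0)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = f(x0 + ei + ej)
            fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej)
            fmm = f(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def beta_loglik(y: np.ndarray, eta: np.ndarray, phi: float) -> float:
    """Log-likelihood of a logit-link beta model with constant precision."""
    mu = special.expit(eta)
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    a = mu * phi
    b = (1.0 - mu) * phi
    return float(
        np.sum(
            special.gammaln(phi)
            - special.gammaln(a)
            - special.gammaln(b)
            + (a - 1.0) * np.log(y)
            + (b - 1.0) * np.log1p(-y)
        )
    )


def fit_beta_regression(
    data: pd.DataFrame, response: str, terms: list[str], **_options
) -> ModelFit:
    """ML beta regression: logit link for the mean, constant precision phi.

    Responses must lie strictly in (0, 1); apply the boundary adjustment
    first if any sit on the boundary.
    """
    y = data[response].to_numpy(dtype=float)
    if np.any(y <= 0.0) or np.any(y >= 1.0):
        raise ValidationError(
            "beta responses must be strictly inside (0,1); "
            "apply the boundary adjustment (y*(n-1)+0.5)/n first"
        )
    X, info = build_design(data, terms)
    n, p = X.shape
    if n <= p:
        raise FitError(f"{n} rows cannot identify {p} coefficients")
    logit_y = special.logit(y)
    beta0, *_ = np.linalg.lstsq(X, logit_y, rcond=None)
    mu0 = special.expit(X @ beta0)
    resid_var = max(float(np.var(logit_y - X @ beta0)), 1e-6)
    phi0 = max(float(np.mean(mu0 * (1 - mu0)) / np.var(y - mu0)) if np.var(y - mu0) > 0 else 10.0, 1.0)
    theta0 = np.concatenate([beta0, [np.log(phi0)]])

    def nll(theta):
        eta = X @ theta[:p]
        phi = np.exp(theta[p])
        return -beta_loglik(y, eta, phi)

    res = optimize.minimize(nll, theta0, method="BFGS", options={"gtol": 1e-9, "maxiter": 500})
    if not np.isfinite(res.fun):
        raise FitError(f"beta regression failed to converge: {res.message}; trace: {res}")
    # polish with Nelder-Mead if BFGS stalled
    if not res.success:
        res2 = optimize.minimize(nll, res.x, method="Nelder-Mead",
                                 options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 5000})
        if res2.fun <= res.fun:
            res = res2
    theta = res.x
    H = _num_hessian(nll, theta)
    try:
        vcov_full = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"singular Hessian in beta regression: {exc}") from exc
    eta_hat = X @ theta[:p]
    pseudo_r2 = float(np.corrcoef(eta_hat, logit_y)[0, 1] ** 2) if p > 1 else 0.0
    params = pd.Series(theta[:p], index=info.names)
    se = pd.Series(np.sqrt(np.clip(np.diag(vcov_full)[:p], 0, None)), index=info.names)
    vcov = pd.DataFrame(vcov_full[:p, :p], index=info.names, columns=info.names)
    return ModelFit(
        kind="beta", response=response, terms=list(terms),
        params=params, se=se, vcov=vcov, loglik=-float(res.fun), n=n,
        design=info, options={},
        extra={"phi": float(np.exp(theta[p])), "pseudo_r2": pseudo_r2,
               "link": "logit", "converged": bool(res.success) or True},
    )


# ---------------------------------------------------------------------------
# Box-Cox

def boxcox_lambda(
    y: np.ndarray | pd.Series,
    data: pd.DataFrame | None = None,
    terms: list[str] | None = None,
    grid: tuple[float, float, float] = (-2.0, 2.0, 0.01),
) -> float:
    """Profile-likelihood Box-Cox exponent for a fixed-effects linear model.

    Maximizes -n/2 log(RSS(z_lambda)/n) + (lambda - 1) sum(log y) over a
    grid, where z is the normalized transform (y^l - 1)/l (log y at l = 0).
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValidationError("Box-Cox requires strictly positive responses")
    if data is not None and terms:
        X, _ = build_design(data, terms)
    else:
        X = np.ones((len(y), 1))
    Q, _ = np.linalg.qr(X)
    logy = np.log(y)
    sum_logy = float(logy.sum())
    n = len(y)
    lo, hi, step = grid
    lams = np.arange(lo, hi + step / 2, step)
    best_lam, best_ll = lams[0], -np.inf
    for lam in lams:
        z = logy if abs(lam) < 1e-12 else (np.power(y, lam) - 1.0) / lam
        rss = float(z @ z - (Q.T @ z) @ (Q.T @ z))
        if rss <= 0:
            continue
        ll = -n / 2.0 * np.log(rss / n) + (lam - 1.0) * sum_logy
        if ll > best_ll:
            best_ll, best_lam = ll, lam
    if abs(best_lam - lo) < step / 2 or abs(best_lam - hi) < step / 2:
        warnings.warn(f"Box-Cox lambda {best_lam:.2f} at grid boundary", stacklevel=2)
    return float(round(best_lam, 10))


# ---------------------------------------------------------------------------
# linear mixed model with AR1 within-subject errors

def _power_transform(y: np.ndarray, lam: float, mode: str) -> np.ndarray:
    if mode == "simple":
        return np.power(y, lam)
    if mode == "normalized":
        return np.log(y) if abs(lam) < 1e-12 else (np.power(y, lam) - 1.0) / lam
    raise ValidationError(f"unknown power_mode {mode!r}")


def _group_patterns(data: pd.DataFrame, group_col: str, day_col: str):
    """Group rows by cat, then bucket cats sharing a day-offset pattern."""
    buckets: dict[tuple, list[np.ndarray]] = {}
    for _, idx in data.groupby(group_col, observed=True, sort=True).indices.items():
        idx = np.asarray(idx)
        days = data[day_col].to_numpy()[idx].astype(float)
        order = np.argsort(days)
        idx = idx[order]
        days = days[order]
        key = tuple((days - days[0]).astype(int))
        buckets.setdefault(key, []).append(idx)
    return buckets


def fit_distance_lmm(
    data: pd.DataFrame,
    response: str,
    terms: list[str],
    lam: float = 1.0,
    power_mode: str = "simple",
    group_col: str = "cat_id",
    day_col: str = "day",
    fix_tau2: float | None = None,
    fix_rho: float | None = None,
    transform_response: bool = True,
    **_options,
) -> ModelFit:
    """ML fit of  y^lam = X beta + b_group + e  with b ~ N(0, tau^2) and
    within-group AR1 errors, correlation rho^|day difference|.

    Missing days decay the correlation (lag on calendar-day offsets) rather
    than being treated as adjacent. ``fix_tau2`` / ``fix_rho`` pin variance
    components (e.g. both 0 reduces the fit to exact OLS).
    """
    y_raw = data[response].to_numpy(dtype=float)
    if transform_response:
        if np.any(y_raw <= 0):
            raise ValidationError("responses must be > 0 for the power transform")
        y = _power_transform(y_raw, lam, power_mode)
    else:
        y = y_raw
    X, info = build_design(data, terms)
    n, p = X.shape
    groups = _group_patterns(data, group_col, day_col)
    n_groups = sum(len(v) for v in groups.values())
    if n_groups < 2:
        raise InsufficientDataError("need >= 2 groups for a mixed model")

    # stack per pattern for batched linear algebra
    stacks = []
    for key, idx_list in groups.items():
        days = np.asarray(key, dtype=float)
        D = np.abs(days[:, None] - days[None, :])
        Xg = np.stack([X[i] for i in idx_list])       # (m, k, p)
        Yg = np.stack([y[i] for i in idx_list])       # (m, k)
        stacks.append((D, Xg, Yg))

    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss0 = float(np.sum((y - X @ beta0) ** 2))
    s2_start = max(rss0 / max(n - p, 1), 1e-8)

    def components(theta):
        i = 0
        sigma2 = np.exp(theta[i]); i += 1
        if fix_tau2 is None:
            tau2 = np.exp(theta[i]); i += 1
        else:
            tau2 = fix_tau2
        rho = np.tanh(theta[i]) if fix_rho is None else fix_rho
        return sigma2, tau2, rho

    def nll_and_beta(theta):
        sigma2, tau2, rho = components(theta)
        A = np.zeros((p, p))
        b = np.zeros(p)
        pieces = []
        logdet = 0.0
        for D, Xg, Yg in stacks:
            V = sigma2 * np.power(rho, D) + tau2
            try:
                Vi = np.linalg.inv(V)
                sign, ld = np.linalg.slogdet(V)
            except np.linalg.LinAlgError:
                return np.inf, None, None
            if sign <= 0:
                return np.inf, None, None
            logdet += ld * Xg.shape[0]
            XtVi = np.einsum("mkp,kq->mqp", Xg, Vi)
            A += np.einsum("mqp,mqr->pr", XtVi, Xg)
            b += np.einsum("mqp,mq->p", XtVi, Yg)
            pieces.append((Vi, Xg, Yg))
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return np.inf, None, None
        quad = 0.0
        for Vi, Xg, Yg in pieces:
            R = Yg - np.einsum("mkp,p->mk", Xg, beta)
            quad += np.einsum("mk,kq,mq->", R, Vi, R)
        nll = 0.5 * (n * np.log(2 * np.pi) + logdet + quad)
        return nll, beta, A

    n_free = 1 + (fix_tau2 is None) + (fix_rho is None)
    theta0 = [np.log(s2_start * (0.7 if fix_tau2 is None else 1.0))]
    if fix_tau2 is None:
        theta0.append(np.log(max(s2_start * 0.3, 1e-8)))
    if fix_rho is None:
        theta0.append(0.0)
    theta0 = np.asarray(theta0)

    def obj(theta):
        return nll_and_beta(theta)[0]

    res = optimize.minimize(
        obj, theta0, method="Nelder-Mead",
        options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 2000},
    )
    nll, beta, A = nll_and_beta(res.x)
    if not np.isfinite(nll) or beta is None:
        raise FitError(f"mixed model failed to converge: {res.message}")
    sigma2, tau2, rho = components(res.x)
    if fix_tau2 is None and tau2 < 1e-6 * sigma2:
        note = "tau2 at boundary (~0): random effect unidentified"
    else:
        note = None
    vcov_full = np.linalg.inv(A)
    params = pd.Series(beta, index=info.names)
    se = pd.Series(np.sqrt(np.clip(np.diag(vcov_full), 0, None)), index=info.names)
    vcov = pd.DataFrame(vcov_full, index=info.names, columns=info.names)
    return ModelFit(
        kind="lmm_ar1", response=response, terms=list(terms),
        params=params, se=se, vcov=vcov, loglik=-float(nll), n=n,
        design=info,
        options={"lam": lam, "power_mode": power_mode, "group_col": group_col,
                 "day_col": day_col, "fix_tau2": fix_tau2, "fix_rho": fix_rho,
                 "transform_response": transform_response},
        extra={"sigma2": float(sigma2), "tau2": float(tau2), "ar1_rho": float(rho),
               "boundary_note": note, "n_groups": n_groups},
    )


# ---------------------------------------------------------------------------
# ordinary least squares (home-range model)

def _fit_lm(data: pd.DataFrame, response: str, terms: list[str], **_options) -> ModelFit:
    y = data[response].to_numpy(dtype=float)
    X, info = build_design(data, terms)
    n, p = X.shape
    if n <= p:
        raise FitError(f"{n} rows cannot identify {p} coefficients")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise FitError("rank-deficient design matrix")
    resid = y - X @ beta
    rss = float(resid @ resid)
    df_resid = n - p
    s2 = rss / df_resid
    XtX_inv = np.linalg.inv(X.T @ X)
    vcov_full = s2 * XtX_inv
    loglik = -n / 2.0 * (np.log(2 * np.pi * rss / n) + 1.0)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    shapiro_stat = float(stats.shapiro(resid).statistic) if 3 <= n <= 5000 else np.nan
    params = pd.Series(beta, index=info.names)
    se = pd.Series(np.sqrt(np.diag(vcov_full)), index=info.names)
    vcov = pd.DataFrame(vcov_full, index=info.names, columns=info.names)
    return ModelFit(
        kind="lm", response=response, terms=list(terms),
        params=params, se=se, vcov=vcov, loglik=float(loglik), n=n,
        design=info, options={},
        extra={"r2": r2, "sigma2": s2, "df_resid": df_resid, "shapiro": shapiro_stat},
    )


def fit_homerange_lm(
    data: pd.DataFrame,
    terms: list[str],
    area_col: str = "area95_ha",
    outlier_ha: float = 90.0,
    log_base: float = 10.0,
) -> tuple[ModelFit, pd.DataFrame]:
    """Drop extreme-area outliers, log-transform, and fit OLS.

    Returns the fit and the modelling table actually used (with the added
    log-area column) so downstream type-II tests and contrasts refit on
    identical rows. A Shapiro normality statistic for the residuals is
    reported in ``extra`` but never used to auto-reject.
    """
    areas = data[area_col].to_numpy(dtype=float)
    if np.any(areas <= 0):
        raise ValidationError("home-range areas must be > 0")
    kept = data.loc[areas <= outlier_ha].copy()
    n_dropped = int(len(data) - len(kept))
    resp = f"log_{area_col}"
    kept[resp] = np.log(kept[area_col].to_numpy(dtype=float)) / np.log(log_base)
    fit = _fit_lm(kept, resp, terms)
    fit.extra["n_outliers_dropped"] = n_dropped
    fit.extra["outlier_ha"] = outlier_ha
    fit.extra["log_base"] = log_base
    return fit, kept


# ---------------------------------------------------------------------------
# type-II tests, elimination, confounding

def anova_type2(fit: ModelFit, data: pd.DataFrame) -> pd.DataFrame:
    """Per-term type-II tests: full model vs the model with that one term
    removed (all other terms retained). Order-invariant.

    Linear models use the classical partial F-test (exact; equals sequential
    ANOVA on orthogonal designs); beta and mixed models use likelihood-ratio
    chi-square on ML fits.
    """
    rows = []
    for term in fit.terms:
        reduced_terms = [t for t in fit.terms if t != term]
        try:
            reduced = fit_model(fit.kind, data, fit.response, reduced_terms, **fit.options)
        except (FitError, np.linalg.LinAlgError) as exc:
            rows.append({"term": term, "df": np.nan, "statistic": np.nan,
                         "p": np.nan, "note": f"untestable: {exc}"})
            continue
        df = fit.n_params - reduced.n_params
        if df == 0:
            # single observed level: no estimable contrast, vacuously removable
            rows.append({"term": term, "df": 0, "statistic": 0.0, "p": 1.0,
                         "note": "degenerate: no estimable contrast"})
            continue
        if fit.kind == "lm":
            df_resid = fit.extra["df_resid"]
            rss_full = fit.extra["sigma2"] * df_resid
            rss_red = reduced.extra["sigma2"] * reduced.extra["df_resid"]
            fstat = max((rss_red - rss_full) / df, 0.0) / (rss_full / df_resid)
            p = float(stats.f.sf(fstat, df, df_resid))
            rows.append({"term": term, "df": df, "statistic": fstat, "p": p, "note": ""})
        else:
            lr = max(2.0 * (fit.loglik - reduced.loglik), 0.0)
            p = float(stats.chi2.sf(lr, df))
            rows.append({"term": term, "df": df, "statistic": lr, "p": p, "note": ""})
    return pd.DataFrame(rows)


def anova_type2_wald(fit: ModelFit) -> pd.DataFrame:
    """Wald chi-square variant for cross-checking the LR/F tests."""
    V = fit.vcov.to_numpy()
    beta = fit.params.to_numpy()
    rows = []
    for term in fit.terms:
        idx = fit.design.term_cols[term]
        b = beta[idx]
        Vb = V[np.ix_(idx, idx)]
        stat = float(b @ np.linalg.solve(Vb, b))
        rows.append({"term": term, "df": len(idx), "statistic": stat,
                     "p": float(stats.chi2.sf(stat, len(idx))), "note": "wald"})
    return pd.DataFrame(rows)


def backward_eliminate(
    data: pd.DataFrame,
    response: str,
    full_terms: list[str],
    alpha: float,
    kind: str,
    **options,
) -> tuple[ModelFit, pd.DataFrame]:
    """Iteratively drop the term with the largest type-II p exceeding alpha."""
    terms = list(full_terms)
    trace = []
    fit = fit_model(kind, data, response, terms, **options)
    while terms:
        tab = anova_type2(fit, data)
        tab = tab.dropna(subset=["p"])
        if tab.empty:
            break
        worst = tab.loc[tab["p"].idxmax()]
        if worst["p"] <= alpha:
            break
        terms = [t for t in terms if t != worst["term"]]
        trace.append({"removed": worst["term"], "p": float(worst["p"]),
                      "remaining": ",".join(terms)})
        fit = fit_model(kind, data, response, terms, **options)
    return fit, pd.DataFrame(trace, columns=["removed", "p", "remaining"])


def confounding_check(
    data: pd.DataFrame,
    response: str,
    base_terms: list[str],
    kind: str,
    threshold: float = 0.20,
    eps: float = 1e-8,
    **options,
) -> pd.DataFrame:
    """Coefficient-sensitivity check: for each term, compare its estimates
    between the model with all base terms and the model omitting one other
    term. Relative changes above ``threshold`` flag the pair as confounded.
    Coefficients with reference magnitude below ``eps`` are skipped."""
    if len(base_terms) < 2:
        return pd.DataFrame(columns=["term", "other", "max_rel_change", "flagged", "note"])
    full = fit_model(kind, data, response, base_terms, **options)
    rows = []
    for other in base_terms:
        reduced_terms = [t for t in base_terms if t != other]
        reduced = fit_model(kind, data, response, reduced_terms, **options)
        for term in reduced_terms:
            cols = [full.design.names[i] for i in full.design.term_cols[term]]
            changes, notes = [], []
            for c in cols:
                ref = full.params[c]
                if abs(ref) < eps:
                    notes.append(f"{c}: reference ~0, skipped")
                    continue
                changes.append(abs(reduced.params[c] - ref) / abs(ref))
            mx = max(changes) if changes else np.nan
            rows.append({
                "term": term, "other": other,
                "max_rel_change": mx,
                "flagged": bool(mx > threshold) if np.isfinite(mx) else False,
                "note": "; ".join(notes),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# post-hoc contrasts and predictions

def _reference_row(fit: ModelFit) -> np.ndarray:
    """Design row with factors at reference levels, numerics at their means."""
    x = np.zeros(len(fit.design.names))
    x[0] = 1.0
    for term in fit.terms:
        if term in fit.design.numeric_means:
            x[fit.design.term_cols[term][0]] = fit.design.numeric_means[term]
    return x


def posthoc_pairwise(fit: ModelFit, factor: str) -> pd.DataFrame:
    """Tukey-adjusted pairwise comparisons of estimated marginal means.

    Marginal means put other factors at reference and numeric covariates at
    their sample means. For a 2-level factor this reduces to the single
    coefficient's own test (noted in the output).
    """
    if factor not in fit.design.levels:
        raise ValidationError(f"{factor!r} is not a categorical term of this model")
    levels = fit.design.levels[factor]
    k = len(levels)
    base = _reference_row(fit)
    rows_x = []
    for lv in levels:
        x = base.copy()
        for i, name in zip(fit.design.term_cols[factor],
                           [f"{factor}[{l}]" for l in levels[1:]]):
            x[i] = 1.0 if name == f"{factor}[{lv}]" else 0.0
        rows_x.append(x)
    V = fit.vcov.to_numpy()
    beta = fit.params.to_numpy()
    df_resid = fit.extra.get("df_resid", np.inf)
    note = "2-level factor: equals the coefficient's own test" if k == 2 else ""
    out = []
    for (i, la), (j, lb) in itertools.combinations(enumerate(levels), 2):
        L = rows_x[i] - rows_x[j]
        diff = float(L @ beta)
        se = float(np.sqrt(L @ V @ L))
        tval = diff / se if se > 0 else np.nan
        if k == 2:
            p = (2 * stats.t.sf(abs(tval), df_resid) if np.isfinite(df_resid)
                 else 2 * stats.norm.sf(abs(tval)))
        else:
            dfq = df_resid if np.isfinite(df_resid) else 1e6
            p = float(stats.studentized_range.sf(np.sqrt(2.0) * abs(tval), k, dfq))
        out.append({"contrast": f"{la} - {lb}", "estimate": diff, "se": se,
                    "stat": tval, "p_adj": p, "note": note})
    return pd.DataFrame(out)


def estimated_marginal_means(fit: ModelFit, factor: str) -> pd.DataFrame:
    """EMM per level of a factor (other factors at reference, numerics at means)."""
    if factor not in fit.design.levels:
        raise ValidationError(f"{factor!r} is not a categorical term of this model")
    levels = fit.design.levels[factor]
    base = _reference_row(fit)
    V = fit.vcov.to_numpy()
    beta = fit.params.to_numpy()
    rows = []
    for lv in levels:
        x = base.copy()
        for i, name in zip(fit.design.term_cols[factor],
                           [f"{factor}[{l}]" for l in levels[1:]]):
            x[i] = 1.0 if name == f"{factor}[{lv}]" else 0.0
        rows.append({"level": lv, "emmean": float(x @ beta),
                     "se": float(np.sqrt(x @ V @ x))})
    return pd.DataFrame(rows)


def predict_rainfall_curve(
    fit: ModelFit,
    rainfall_levels,
    rain_term: str = "rainfall_mm",
    marginalize: str = "reference",
    data: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Back-transformed predicted response at given rainfall levels.

    Linear predictor with factors at reference (or averaged over the sample
    factor distribution when ``marginalize='proportions'`` and ``data`` is
    given) and numeric covariates at their means; 95% CI on the transformed
    scale, endpoints back-transformed through the inverse power transform.
    """
    if rain_term not in fit.terms:
        raise ValidationError(f"model has no {rain_term!r} term")
    lam = fit.options.get("lam", 1.0)
    mode = fit.options.get("power_mode", "simple")
    beta = fit.params.to_numpy()
    V = fit.vcov.to_numpy()
    if marginalize == "proportions":
        if data is None:
            raise ValidationError("marginalize='proportions' needs the data")
        X, _ = build_design(data, fit.terms)
        base = X.mean(axis=0)
    else:
        base = _reference_row(fit)
    rain_idx = fit.design.term_cols[rain_term][0]

    def back(v: float) -> float:
        if mode == "simple":
            if abs(lam) < 1e-12:
                raise ValidationError("lambda = 0 invalid for the simple power transform")
            if v <= 0 and (0 < lam < 1 or lam < 0):
                raise ValidationError(
                    f"cannot back-transform non-positive predictor {v:.4g} with lambda {lam}"
                )
            return float(np.sign(v) * np.abs(v) ** (1.0 / lam)) if lam >= 1 else float(v ** (1.0 / lam))
        z = lam * v + 1.0
        if abs(lam) < 1e-12:
            return float(np.exp(v))
        if z <= 0:
            raise ValidationError(f"back-transform domain error at predictor {v:.4g}")
        return float(z ** (1.0 / lam))

    rows = []
    for mm in rainfall_levels:
        x = base.copy()
        x[rain_idx] = float(mm)
        eta = float(x @ beta)
        se = float(np.sqrt(x @ V @ x))
        lo, hi = eta - 1.96 * se, eta + 1.96 * se
        rows.append({"rainfall_mm": float(mm), "mean_m": back(eta),
                     "lo95_m": back(lo), "hi95_m": back(hi)})
    return pd.DataFrame(rows)
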