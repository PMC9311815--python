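import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from catmove import inference as inf
from catmove.errors import ValidationError


def _cat_series(values, levels):
    return pd.Categorical(values, categories=levels)


class TestBuildDesign:
    def test_treatment_coding(self):
        df = pd.DataFrame(
            {"g": _cat_series(["a", "b", "c", "a"], ["a", "b", "c"]), "x": [1.0, 2, 3, 4]}
        )
        X, info = inf.build_design(df, ["g", "x"])
        assert info.names == ["(Intercept)", "g[b]", "g[c]", "x"]
        assert X[:, 0].tolist() == [1, 1, 1, 1]
        assert X[1, 1] == 1.0 and X[2, 2] == 1.0
        assert info.numeric_means["x"] == pytest.approx(2.5)

    def test_absent_level_dropped(self):
        df = pd.DataFrame({"g": _cat_series(["a", "b", "a"], ["a", "b", "zzz"])})
        _, info = inf.build_design(df, ["g"])
        assert info.levels["g"] == ["a", "b"]


class TestAssociationScreen:
    def test_duplicated_variable_flagged(self):
        rng = np.random.default_rng(0)
        g = rng.choice(["x", "y", "z"], size=300)
        df = pd.DataFrame({"a": g, "b": g.copy(), "c": rng.choice(["u", "v"], size=300)})
        res = inf.association_screen(df, ["a", "b", "c"])
        pair = res.pairs[(res.pairs.var1 == "a") & (res.pairs.var2 == "b")]
        assert pair.iloc[0]["p"] < 1e-10
        assert pair.iloc[0]["flagged"]
        assert len(res.exclusions) >= 1

    def test_single_covariate_empty(self):
        df = pd.DataFrame({"a": ["x", "y"] * 5})
        res = inf.association_screen(df, ["a"])
        assert res.pairs.empty and res.exclusions == []

    def test_type_one_error_rate(self):
        flags = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(
                {
                    "a": rng.choice(["x", "y", "z"], size=1000),
                    "b": rng.choice(["u", "v"], size=1000),
                }
            )
            res = inf.association_screen(df, ["a", "b"], alpha=0.05)
            flags += int(res.pairs["flagged"].any())
        assert flags / 200 <= 0.07

    def test_sparse_table_monte_carlo(self):
        df = pd.DataFrame(
            {
                "a": ["x"] * 7 + ["y"] * 1 + ["x"] * 2,
                "b": (["u", "v"] * 5),
            }
        )
        res = inf.association_screen(df, ["a", "b"], seed=1)
        assert res.pairs.iloc[0]["method"] == "monte-carlo"


class TestBetaRegression:
    def test_intercept_only_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        y = rng.beta(0.3 * 15, 0.7 * 15, 150)
        df = pd.DataFrame({"y": y})
        fit = inf.fit_beta_regression(df, "y", [])

        def nll(t):
            return -inf.beta_loglik(y, np.full(len(y), t[0]), np.exp(t[1]))

        grid = [
            (nll((m, p)), m, p)
            for m in np.linspace(-3, 3, 61)
            for p in np.linspace(0, 5, 51)
        ]
        _, m0, p0 = min(grid)
        res = optimize.minimize(
            nll, [m0, p0], method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12}
        )
        assert fit.params["(Intercept)"] == pytest.approx(res.x[0], abs=1e-6)
        assert np.log(fit.extra["phi"]) == pytest.approx(res.x[1], abs=1e-6)

    def test_boundary_response_rejected(self):
        df = pd.DataFrame({"y": [0.2, 0.5, 1.0]})
        with pytest.raises(ValidationError, match="boundary adjustment"):
            inf.fit_beta_regression(df, "y", [])

    def test_pseudo_r2_in_unit_interval(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        mu = special.expit(-0.5 + 0.8 * x)
        y = rng.beta(mu * 20, (1 - mu) * 20)
        df = pd.DataFrame({"y": y, "x": x})
        fit = inf.fit_beta_regression(df, "y", ["x"])
        assert 0.0 <= fit.extra["pseudo_r2"] <= 1.0

    def test_coefficient_recovery_small(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=2000)
            mu = special.expit(0.3 + 0.5 * x)
            y = rng.beta(mu * 20, (1 - mu) * 20)
            df = pd.DataFrame({"y": y, "x": x})
            fit = inf.fit_beta_regression(df, "y", ["x"])
            if abs(fit.params["x"] - 0.5) <= 3 * fit.se["x"]:
                hits += 1
        assert hits >= 19


class TestBoxCox:
    def test_lognormal_lambda_near_zero(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=400)
        y = np.exp(1.0 + 0.5 * x + rng.normal(0, 0.5, 400))
        df = pd.DataFrame({"x": x})
        lam = inf.boxcox_lambda(y, df, ["x"])
        assert abs(lam) < 0.1

    def test_normal_lambda_near_one(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 5, 500)
        y = 3.0 + 2.0 * x + rng.normal(0, 1.0, 500)
        assert y.min() > 0
        df = pd.DataFrame({"x": x})
        lam = inf.boxcox_lambda(y, df, ["x"])
        assert abs(lam - 1.0) < 0.2

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            inf.boxcox_lambda(np.array([1.0, -2.0, 3.0]))

    def test_boundary_warns(self):
        rng = np.random.default_rng(6)
        y = np.exp(rng.normal(0, 1, 100))
        with pytest.warns(UserWarning, match="boundary"):
            inf.boxcox_lambda(y, grid=(0.5, 2.0, 0.01))


def _lmm_data(seed, n_cats=30, days=5, tau=0.0, rho=0.0, sigma=1.0, beta_x=0.5):
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_cats):
        b = rng.normal(0, tau)
        e = np.empty(days)
        e[0] = rng.normal(0, sigma)
        for d in range(1, days):
            e[d] = rho * e[d - 1] + rng.normal(0, sigma * np.sqrt(1 - rho**2))
        for d in range(days):
            x = rng.normal()
            rows.append(
                {"cat_id": f"c{c:03d}", "day": d, "x": x, "y": 2.0 + beta_x * x + b + e[d]}
            )
    return pd.DataFrame(rows)


class TestDistanceLMM:
    def test_degenerate_matches_ols(self):
        df = _lmm_data(7)
        fit = inf.fit_distance_lmm(
            df, "y", ["x"], fix_tau2=0.0, fix_rho=0.0, transform_response=False
        )
        X = np.column_stack([np.ones(len(df)), df["x"]])
        ols = np.linalg.lstsq(X, df["y"], rcond=None)[0]
        assert np.abs(fit.params.to_numpy() - ols).max() < 1e-4

    def test_rho_recovery(self):
        df = _lmm_data(8, n_cats=60, tau=0.5, rho=0.6)
        fit = inf.fit_distance_lmm(df, "y", ["x"], transform_response=False)
        assert fit.extra["ar1_rho"] == pytest.approx(0.6, abs=0.2)

    def test_matches_bruteforce_ml(self):
        # independent oracle: coarse grid over variance components + polish
        df = _lmm_data(9, n_cats=12, days=4, tau=0.7, rho=0.3)
        fit = inf.fit_distance_lmm(df, "y", ["x"], transform_response=False)

        X = np.column_stack([np.ones(len(df)), df["x"]])
        y = df["y"].to_numpy()
        cats = df["cat_id"].to_numpy()
        ids = sorted(set(cats))

        def nll(theta):
            s2, t2, rho = np.exp(theta[0]), np.exp(theta[1]), np.tanh(theta[2])
            beta = theta[3:]
            total = 0.0
            for c in ids:
                m = cats == c
                d = df.loc[m, "day"].to_numpy(dtype=float)
                V = s2 * rho ** np.abs(d[:, None] - d[None, :]) + t2
                r = y[m] - X[m] @ beta
                sign, ld = np.linalg.slogdet(V)
                total += 0.5 * (len(r) * np.log(2 * np.pi) + ld + r @ np.linalg.solve(V, r))
            return total

        best = None
        for ls in np.linspace(-1, 1, 5):
            for lt in np.linspace(-2, 1, 5):
                for zr in np.linspace(-0.5, 0.5, 5):
                    th = np.array([ls, lt, zr, fit.params.iloc[0], fit.params.iloc[1]])
                    v = nll(th)
                    if best is None or v < best[0]:
                        best = (v, th)
        res = optimize.minimize(
            nll, best[1], method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 8000, "maxfev": 8000},
        )
        assert -fit.loglik == pytest.approx(res.fun, abs=1e-3)
        assert np.abs(fit.params.to_numpy() - res.x[3:]).max() < 1e-3

    def test_rainfall_slope_sign_recovery(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            rows = []
            for c in range(40):
                b = rng.normal(0, 0.5)
                for d in range(5):
                    rain = rng.exponential(4.0)
                    rows.append(
                        {"cat_id": f"c{c}", "day": d, "rainfall_mm": rain,
                         "y": 10.0 - 0.1 * rain + b + rng.normal(0, 1)}
                    )
            df = pd.DataFrame(rows)
            fit = inf.fit_distance_lmm(df, "y", ["rainfall_mm"], transform_response=False)
            if fit.params["rainfall_mm"] < 0:
                hits += 1
        assert hits >= 19

    def test_gap_days_decay_correlation(self):
        df = _lmm_data(11, n_cats=40, tau=0.3, rho=0.7)
        # knock out day 2 for every cat: lags become {1,1,2,...} on offsets
        df = df[df["day"] != 2]
        fit = inf.fit_distance_lmm(df, "y", ["x"], transform_response=False)
        assert -1 < fit.extra["ar1_rho"] < 1
        assert fit.extra["ar1_rho"] > 0.3


class TestHomerangeLM:
    def test_outlier_threshold(self):
        df = pd.DataFrame(
            {
                "area95_ha": [5.0, 7.0, 100.0, 3.0, 8.0, 6.0],
                "g": _cat_series(list("abbaab"), ["a", "b"]),
            }
        )
        fit, kept = inf.fit_homerange_lm(df, ["g"], outlier_ha=90.0)
        assert fit.extra["n_outliers_dropped"] == 1
        assert len(kept) == 5

    def test_log10_group_offsets_recovered(self):
        rng = np.random.default_rng(12)
        g = rng.choice(["a", "b", "c"], size=400)
        offset = {"a": 0.0, "b": 0.35, "c": -0.2}
        area = 10 ** (0.7 + np.array([offset[x] for x in g]) + rng.normal(0, 0.3, 400))
        df = pd.DataFrame({"area95_ha": area, "g": _cat_series(g, ["a", "b", "c"])})
        fit, _ = inf.fit_homerange_lm(df, ["g"], outlier_ha=1e9)
        assert abs(fit.params["g[b]"] - 0.35) <= 3 * fit.se["g[b]"]
        assert abs(fit.params["g[c]"] + 0.2) <= 3 * fit.se["g[c]"]

    def test_shapiro_reported(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame(
            {"area95_ha": np.exp(rng.normal(1, 0.4, 50)),
             "g": _cat_series(rng.choice(["a", "b"], 50), ["a", "b"])}
        )
        fit, _ = inf.fit_homerange_lm(df, ["g"])
        assert 0.0 < fit.extra["shapiro"] <= 1.0


class TestAnovaType2:
    def _orthogonal_df(self, seed=0, n=80):
        rng = np.random.default_rng(seed)
        a = np.tile(["a1", "a2"], n // 2)
        b = np.repeat(["b1", "b2"], n // 2)
        y = (
            1.0
            + 0.5 * (a == "a2")
            + 0.8 * (b == "b2")
            + rng.normal(0, 1, n)
        )
        return pd.DataFrame(
            {"y": y, "A": _cat_series(a, ["a1", "a2"]), "B": _cat_series(b, ["b1", "b2"])}
        )

    def test_orthogonal_equals_sequential(self):
        df = self._orthogonal_df()
        fit = inf.fit_model("lm", df, "y", ["A", "B"])
        t2 = inf.anova_type2(fit, df)
        # sequential ANOVA oracle: SS reductions in fitting order, F against
        # the full model's residual mean square
        def rss(terms):
            f = inf.fit_model("lm", df, "y", terms)
            return f.extra["sigma2"] * f.extra["df_resid"]

        rss0, rssA, rssAB = rss([]), rss(["A"]), rss(["A", "B"])
        df_resid = fit.extra["df_resid"]
        ms = rssAB / df_resid
        seq = {
            "A": float(stats.f.sf((rss0 - rssA) / ms, 1, df_resid)),
            "B": float(stats.f.sf((rssA - rssAB) / ms, 1, df_resid)),
        }
        for _, row in t2.iterrows():
            assert row["p"] == pytest.approx(seq[row["term"]], abs=1e-6)

    def test_order_invariance(self):
        df = self._orthogonal_df(seed=3)
        p1 = inf.anova_type2(inf.fit_model("lm", df, "y", ["A", "B"]), df).set_index("term")["p"]
        p2 = inf.anova_type2(inf.fit_model("lm", df, "y", ["B", "A"]), df).set_index("term")["p"]
        assert p1["A"] == pytest.approx(p2["A"], abs=1e-10)
        assert p1["B"] == pytest.approx(p2["B"], abs=1e-10)

    def test_single_term_reduces_to_intercept_only(self):
        df = self._orthogonal_df(seed=4)
        fit = inf.fit_model("lm", df, "y", ["A"])
        t2 = inf.anova_type2(fit, df)
        f0 = inf.fit_model("lm", df, "y", [])
        rss0 = f0.extra["sigma2"] * f0.extra["df_resid"]
        rssA = fit.extra["sigma2"] * fit.extra["df_resid"]
        f_oracle = (rss0 - rssA) / (rssA / fit.extra["df_resid"])
        assert t2.iloc[0]["statistic"] == pytest.approx(f_oracle, abs=1e-9)


class TestBackwardElimination:
    def test_strong_effects_no_removal(self):
        rng = np.random.default_rng(14)
        x1, x2 = rng.normal(size=(2, 300))
        df = pd.DataFrame({"y": 1 + 2 * x1 - 3 * x2 + rng.normal(0, 1, 300), "x1": x1, "x2": x2})
        fit, trace = inf.backward_eliminate(df, "y", ["x1", "x2"], 0.05, "lm")
        assert trace.empty
        assert fit.terms == ["x1", "x2"]

    def test_noise_term_removed_first(self):
        removed_first = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x1, x2, noise = rng.normal(size=(3, 200))
            df = pd.DataFrame(
                {"y": 1 + 1.5 * x1 - 1.2 * x2 + rng.normal(0, 1, 200),
                 "x1": x1, "x2": x2, "noise": noise}
            )
            _, trace = inf.backward_eliminate(df, "y", ["x1", "x2", "noise"], 0.05, "lm")
            if len(trace) and trace.iloc[0]["removed"] == "noise":
                removed_first += 1
        assert removed_first >= 90

    def test_alpha_one_keeps_full_model(self):
        rng = np.random.default_rng(15)
        df = pd.DataFrame({"y": rng.normal(size=50), "x": rng.normal(size=50)})
        fit, trace = inf.backward_eliminate(df, "y", ["x"], 1.0, "lm")
        assert fit.terms == ["x"] and trace.empty


class TestConfounding:
    def test_duplicated_covariate_flagged(self):
        rng = np.random.default_rng(16)
        x = rng.normal(size=300)
        x_dup = x + rng.normal(0, 0.05, 300)
        df = pd.DataFrame({"y": 1 + x + rng.normal(0, 1, 300), "x": x, "x_dup": x_dup})
        rep = inf.confounding_check(df, "y", ["x", "x_dup"], "lm")
        assert rep["flagged"].any()

    def test_orthogonal_no_flags(self):
        clean = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x1, x2 = rng.normal(size=(2, 5000))
            df = pd.DataFrame({"y": 1 + x1 + x2 + rng.normal(0, 1, 5000), "x1": x1, "x2": x2})
            rep = inf.confounding_check(df, "y", ["x1", "x2"], "lm")
            clean += int(not rep["flagged"].any())
        assert clean >= 9

    def test_single_term_empty(self):
        df = pd.DataFrame({"y": [1.0, 2, 3], "x": [0.1, 0.2, 0.3]})
        rep = inf.confounding_check(df, "y", ["x"], "lm")
        assert rep.empty


class TestPosthoc:
    def _fit_three_level(self, seed=17, offsets=(0.0, 0.5, 1.0), n=240):
        rng = np.random.default_rng(seed)
        g = np.tile(["a", "b", "c"], n // 3)
        y = np.array([offsets["abc".index(x)] for x in g]) + rng.normal(0, 1, n)
        df = pd.DataFrame({"y": y, "g": _cat_series(g, ["a", "b", "c"])})
        return inf.fit_model("lm", df, "y", ["g"]), df

    def test_marginal_means_equal_coefficients(self):
        fit, _ = self._fit_three_level()
        emm = inf.estimated_marginal_means(fit, "g").set_index("level")["emmean"]
        assert emm["b"] - emm["a"] == pytest.approx(fit.params["g[b]"], abs=1e-10)
        assert emm["c"] - emm["a"] == pytest.approx(fit.params["g[c]"], abs=1e-10)

    def test_antisymmetry(self):
        fit, _ = self._fit_three_level()
        tab = inf.posthoc_pairwise(fit, "g").set_index("contrast")
        # a-b estimate must equal the negated b-a difference via EMMs
        emm = inf.estimated_marginal_means(fit, "g").set_index("level")["emmean"]
        assert tab.loc["a - b", "estimate"] == pytest.approx(-(emm["b"] - emm["a"]), abs=1e-10)

    def test_familywise_error(self):
        false_pos = 0
        for seed in range(200):
            fit, _ = self._fit_three_level(seed=seed, offsets=(0.0, 0.0, 0.0), n=90)
            tab = inf.posthoc_pairwise(fit, "g")
            if (tab["p_adj"] < 0.05).any():
                false_pos += 1
        assert false_pos / 200 <= 0.07

    def test_two_level_factor_noted(self):
        rng = np.random.default_rng(19)
        g = np.tile(["a", "b"], 50)
        df = pd.DataFrame(
            {"y": rng.normal(size=100), "g": _cat_series(g, ["a", "b"])}
        )
        fit = inf.fit_model("lm", df, "y", ["g"])
        tab = inf.posthoc_pairwise(fit, "g")
        assert len(tab) == 1
        assert "coefficient" in tab.iloc[0]["note"]


class TestRainfallPrediction:
    def _manual_fit(self, lam=0.34, intercept=16.59, slope=-0.045):
        names = ["(Intercept)", "rainfall_mm"]
        design = inf.DesignInfo(
            terms=["rainfall_mm"], names=names,
            term_cols={"rainfall_mm": [1]}, levels={}, numeric_means={"rainfall_mm": 0.0},
        )
        return inf.ModelFit(
            kind="lmm_ar1", response="distance_m", terms=["rainfall_mm"],
            params=pd.Series([intercept, slope], index=names),
            se=pd.Series([0.673, 0.018], index=names),
            vcov=pd.DataFrame(np.diag([0.673**2, 0.018**2]), index=names, columns=names),
            loglik=0.0, n=100, design=design,
            options={"lam": lam, "power_mode": "simple"},
        )

    def test_handset_coefficients_scale(self):
        fit = self._manual_fit()
        pred = inf.predict_rainfall_curve(fit, [0.0])
        # 16.59 ** (1/0.34) ~ 3.88 km on the metres scale
        assert pred.iloc[0]["mean_m"] == pytest.approx(16.59 ** (1 / 0.34), rel=1e-9)
        assert 3500 < pred.iloc[0]["mean_m"] < 4300

    def test_negative_slope_monotone_decreasing(self):
        fit = self._manual_fit()
        pred = inf.predict_rainfall_curve(fit, [0, 5, 10, 20, 45])
        assert (np.diff(pred["mean_m"]) < 0).all()
        assert (pred["lo95_m"] <= pred["mean_m"]).all()
        assert (pred["mean_m"] <= pred["hi95_m"]).all()

    def test_lambda_one_identity(self):
        fit = self._manual_fit(lam=1.0, intercept=3000.0, slope=-20.0)
        pred = inf.predict_rainfall_curve(fit, [0.0, 10.0])
        assert pred.iloc[0]["mean_m"] == pytest.approx(3000.0)
        assert pred.iloc[1]["mean_m"] == pytest.approx(2800.0)

    def test_domain_error(self):
        fit = self._manual_fit(lam=0.34, intercept=0.5, slope=-0.3)
        with pytest.raises(ValidationError):
            inf.predict_rainfall_curve(fit, [100.0])

    def test_missing_term_rejected(self):
        fit = self._manual_fit()
        with pytest.raises(ValidationError):
            inf.predict_rainfall_curve(fit, [0.0], rain_term="snow")
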