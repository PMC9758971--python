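import subprocess
import textwrap

import numpy as np
import pandas as pd
import patsy
import pytest
from scipy import stats

import ecoglmm as eg
from ecoglmm.families import family_by_name
from ecoglmm.fit import (
    DegenerateResponseError,
    _GLMMProblem,
    marginal_loglik,
)

from conftest import make_poisson_glmm_frame


def trapezoid_marginal_loglik(y, eta, groups, family, sigma_b,
                              pi=None, n_grid=2001, half_width=10.0):
    """Brute-force marginal log-likelihood oracle.

    Integrates the random intercept per group on a dense trapezoid grid
    over b in [-10 sigma, 10 sigma]; independent of the quadrature code.
    """
    b_grid = np.linspace(-half_width * sigma_b, half_width * sigma_b, n_grid)
    total = 0.0
    for g in np.unique(groups):
        idx = groups == g
        vals = np.empty(n_grid)
        for i, b in enumerate(b_grid):
            mu = np.exp(eta[idx] + b)
            if pi is None:
                lp = family.log_pmf(y[idx], mu)
            else:
                lp = eg.ZeroInflated(family).log_pmf(y[idx], mu, pi[idx])
            vals[i] = np.sum(lp) + stats.norm.logpdf(b, 0.0, sigma_b)
        total += np.log(np.trapezoid(np.exp(vals - vals.max()), b_grid)) \
            + vals.max()
    return total


class TestLikelihoodOracle:
    """Quadrature vs dense numerical integration on a 3-group toy."""

    @staticmethod
    def toy():
        rng = np.random.default_rng(7)
        groups = np.repeat([0, 1, 2], 4)
        x = rng.normal(0, 1, 12)
        y = np.array([0, 2, 1, 4, 1, 0, 3, 2, 5, 2, 0, 1], dtype=float)
        X = np.column_stack([np.ones(12), x])
        return y, X, groups

    @pytest.mark.parametrize("family_name,disp", [
        ("poisson", {}), ("nbinom2", {"theta": 1.5})])
    @pytest.mark.parametrize("with_zi", [False, True])
    def test_quadrature_matches_trapezoid(self, family_name, disp, with_zi):
        y, X, groups = self.toy()
        family = family_by_name(family_name, **disp)
        beta = np.array([0.4, 0.3])
        sigma_b = 0.6
        eta = X @ beta
        if with_zi:
            Z = X[:, :1]
            gamma = np.array([-1.2])
            pi = 1.0 / (1.0 + np.exp(-(Z @ gamma)))
            got = marginal_loglik(y, X, groups, family, sigma_b, beta,
                                  Z=Z, gamma=gamma)
        else:
            pi = None
            got = marginal_loglik(y, X, groups, family, sigma_b, beta)
        expected = trapezoid_marginal_loglik(y, eta, groups, family,
                                             sigma_b, pi=pi)
        assert got == pytest.approx(expected, abs=1e-4)

    def test_laplace_close_to_15_node(self):
        # high per-group information (large counts, many repeats) is where
        # the Laplace approximation is accurate to ~1e-3 in total loglik
        table = make_poisson_glmm_frame(n_groups=10, n_per=60,
                                        beta=(3.0, 0.5), sigma_b=0.3, seed=0)
        spec = eg.ModelSpec(formula="~ x", family="poisson", taxon="t1")
        m = eg.fit(spec, table)
        design = m._design
        args = (design["y"], design["X"], design["groups"],
                m.family, m.sigma_b, m.beta)
        ll1 = marginal_loglik(*args, n_nodes=1)
        ll15 = marginal_loglik(*args, n_nodes=15)
        assert ll1 == pytest.approx(ll15, abs=1e-3)
        # and the fitted 7-node value sits between the refinements' spread
        assert m.loglik == pytest.approx(ll15, abs=1e-3)


class TestGLMReduction:
    """sigma_b = 0 must reproduce ordinary ML GLM estimates."""

    @staticmethod
    def simulate(family_name, seed):
        rng = np.random.default_rng(seed)
        n = 400
        x1, x2 = rng.normal(0, 1, (2, n))
        mu = np.exp(0.8 + 0.5 * x1 - 0.3 * x2)
        fam = {"poisson": eg.Poisson(), "nbinom1": eg.NB1(phi=2.5),
               "nbinom2": eg.NB2(theta=1.2)}[family_name]
        y = fam.simulate(mu, rng)
        return pd.DataFrame({
            "site": "s0", "night": np.arange(n), "taxon": "t",
            "count": y, "x1": x1, "x2": x2,
        })

    @pytest.mark.parametrize("family_name", ["poisson", "nbinom1", "nbinom2"])
    def test_matches_statsmodels_irls(self, family_name):
        import statsmodels.api as sm
        from statsmodels.discrete.discrete_model import NegativeBinomial

        df = self.simulate(family_name, seed=21)
        spec = eg.ModelSpec(formula="~ x1 + x2", family=family_name,
                            group=None)
        m = eg.fit(spec, df)
        X = np.asarray(patsy.dmatrix("~ x1 + x2", df))
        y = df["count"].to_numpy(float)
        if family_name == "poisson":
            oracle = sm.GLM(y, X, family=sm.families.Poisson()).fit(tol=1e-12)
            ref = oracle.params
        else:
            kind = "nb1" if family_name == "nbinom1" else "nb2"
            oracle = NegativeBinomial(y, X, loglike_method=kind).fit(
                disp=False, maxiter=200, gtol=1e-10)
            ref = oracle.params[:-1]
        np.testing.assert_allclose(m.beta, ref, atol=1e-6)

    def test_intercept_only_closed_form(self):
        df = self.simulate("poisson", seed=3)
        spec = eg.ModelSpec(formula="~ 1", family="poisson", group=None)
        m = eg.fit(spec, df)
        assert m.beta[0] == pytest.approx(np.log(df["count"].mean()),
                                          abs=1e-9)


class TestAIC:
    def test_formula(self, small_glmm_table):
        spec = eg.ModelSpec(formula="~ x", family="poisson", taxon="t1")
        m = eg.fit(spec, small_glmm_table)
        assert eg.aic(m) == pytest.approx(2 * m.k - 2 * m.loglik)
        assert m.k == 3  # intercept, slope, sigma_b

    def test_nb2_has_one_more_parameter(self, small_glmm_table):
        m_p = eg.fit(eg.ModelSpec(formula="~ x", family="poisson",
                                  taxon="t1"), small_glmm_table)
        m_nb = eg.fit(eg.ModelSpec(formula="~ x", family="nbinom2",
                                   taxon="t1"), small_glmm_table)
        assert m_nb.k == m_p.k + 1

    def test_unconverged_model_refused(self, small_glmm_table):
        spec = eg.ModelSpec(formula="~ x", family="poisson", taxon="t1")
        m = eg.fit(spec, small_glmm_table)
        m.converged = False
        from ecoglmm.fit import ConvergenceError

        with pytest.raises(ConvergenceError):
            eg.aic(m)

    def test_overdispersed_data_prefers_nb2(self):
        rng = np.random.default_rng(9)
        n = 500
        x = rng.normal(0, 1, n)
        mu = np.exp(1.2 + 0.4 * x)
        y = eg.NB2(theta=0.8).simulate(mu, rng)
        df = pd.DataFrame({"site": np.repeat([f"s{i}" for i in range(10)],
                                             n // 10),
                           "night": np.arange(n), "taxon": "t",
                           "count": y, "x": x})
        table = eg.CountTable(df)
        m_p = eg.fit(eg.ModelSpec(formula="~ x", family="poisson",
                                  taxon="t"), table)
        m_nb = eg.fit(eg.ModelSpec(formula="~ x", family="nbinom2",
                                   taxon="t"), table)
        assert m_nb.aic < m_p.aic


class TestWaldCI:
    @pytest.fixture(scope="class")
    def model(self):
        table = make_poisson_glmm_frame(seed=4)
        return eg.fit(eg.ModelSpec(formula="~ x", family="poisson",
                                   taxon="t1"), table)

    def test_z_quantiles(self, model):
        ci95 = eg.wald_ci(model, 0.95)
        ci85 = eg.wald_ci(model, 0.85)
        j = model.coef_names.index("x")
        b, se = model.beta[j], model.se_beta[j]
        assert ci95.loc["x", "upper"] == pytest.approx(b + 1.959964 * se,
                                                       abs=1e-5)
        assert ci85.loc["x", "upper"] == pytest.approx(b + 1.439531 * se,
                                                       abs=1e-5)

    def test_nesting(self, model):
        ci95 = eg.wald_ci(model, 0.95)
        ci85 = eg.wald_ci(model, 0.85)
        assert (ci95["lower"] <= ci85["lower"]).all()
        assert (ci85["upper"] <= ci95["upper"]).all()

    def test_level_domain(self, model):
        with pytest.raises(ValueError):
            eg.wald_ci(model, 1.2)


class TestVIF:
    @staticmethod
    def table_with_predictors(x2_from_x1=None, seed=0):
        rng = np.random.default_rng(seed)
        n = 300
        x1 = rng.normal(0, 1, n)
        x1 = (x1 - x1.mean()) / x1.std(ddof=1)
        raw = rng.normal(0, 1, n)
        raw = raw - raw.mean()
        # orthogonalize against x1, then mix to hit an exact correlation
        orth = raw - (raw @ x1) / (x1 @ x1) * x1
        orth = orth / orth.std(ddof=1)
        if x2_from_x1 is None:
            x2 = orth
        else:
            r = x2_from_x1
            x2 = r * x1 + np.sqrt(1 - r * r) * orth
        y = np.maximum(0, rng.poisson(np.exp(1.0 + 0.2 * x1)))
        df = pd.DataFrame({"site": "s0", "night": np.arange(n), "taxon": "t",
                           "count": y, "x1": x1, "x2": x2})
        return df

    def test_orthogonal_predictors_unit_vif(self):
        df = self.table_with_predictors(None)
        m = eg.fit(eg.ModelSpec(formula="~ x1 + x2", family="poisson",
                                group=None), df)
        v = eg.vif(m)
        np.testing.assert_allclose(v.values, 1.0, atol=1e-8)

    def test_correlation_09_gives_5_263(self):
        df = self.table_with_predictors(0.9)
        m = eg.fit(eg.ModelSpec(formula="~ x1 + x2", family="poisson",
                                group=None), df)
        v = eg.vif(m)
        assert v["x1"] == pytest.approx(1 / (1 - 0.81), abs=1e-6)

    def test_duplicated_column_rejected_at_fit(self):
        df = self.table_with_predictors(None)
        df["x3"] = df["x1"]
        with pytest.raises(np.linalg.LinAlgError, match="x3|x1"):
            eg.fit(eg.ModelSpec(formula="~ x1 + x2 + x3", family="poisson",
                                group=None), df)


class TestPredictResponse:
    def test_intercept_only_constant_mean(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"site": "s0", "night": np.arange(200),
                           "taxon": "t", "count": rng.poisson(5.0, 200),
                           "x": rng.normal(0, 1, 200)})
        m = eg.fit(eg.ModelSpec(formula="~ 1", family="poisson", group=None),
                   df)
        pred = eg.predict_response(m, {}, vary="x", grid=[-1.0, 0.0, 2.0])
        np.testing.assert_allclose(pred["mean"],
                                   np.exp(m.beta[0]), rtol=1e-10)

    def test_monotone_in_positive_coefficient(self, small_glmm_table):
        m = eg.fit(eg.ModelSpec(formula="~ x", family="poisson",
                                taxon="t1"), small_glmm_table)
        assert m.beta[1] > 0
        pred = eg.predict_response(m, {"x": 0.0}, vary="x",
                                   grid=np.linspace(-1, 1, 9))
        assert (np.diff(pred["mean"]) > 0).all()
        assert (pred["lower"] <= pred["mean"]).all()
        assert (pred["mean"] <= pred["upper"]).all()

    def test_unknown_predictor_errors(self, small_glmm_table):
        m = eg.fit(eg.ModelSpec(formula="~ x", family="poisson",
                                taxon="t1"), small_glmm_table)
        with pytest.raises(KeyError):
            eg.predict_response(m, {}, vary="nope", grid=[0.0])

    def test_prediction_at_standardized_zero_is_exp_intercept(self):
        table = make_poisson_glmm_frame(seed=8)
        m = eg.fit(eg.ModelSpec(formula="~ x", family="poisson", taxon="t1",
                                standardize=("x",)), table)
        center = m.records["x"].mean
        pred = eg.predict_response(m, {"x": center}, vary="x", grid=[center])
        assert pred["mean"][0] == pytest.approx(np.exp(m.beta[0]), rel=1e-9)


class TestGuards:
    def test_all_zero_response(self):
        df = pd.DataFrame({"site": list("aabb"), "night": [1, 2, 1, 2],
                           "taxon": "t", "count": 0, "x": [0.0, 1, 2, 3]})
        with pytest.raises(DegenerateResponseError):
            eg.fit(eg.ModelSpec(formula="~ x", family="poisson", taxon="t"),
                   eg.CountTable(df))

    def test_single_group_level_rejected(self):
        df = pd.DataFrame({"site": "a", "night": range(6), "taxon": "t",
                           "count": [1, 2, 0, 3, 1, 2],
                           "x": np.arange(6.0)})
        with pytest.raises(ValueError, match="levels"):
            eg.fit(eg.ModelSpec(formula="~ x", family="poisson", taxon="t"),
                   df)

    def test_zi_guard_on_sparse_zeros(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"site": np.repeat(list("abcd"), 25),
                           "night": range(100), "taxon": "t",
                           "count": rng.poisson(30.0, 100),
                           "x": rng.normal(0, 1, 100)})
        spec = eg.ModelSpec(formula="~ x", family="poisson", taxon="t",
                            zi_formula="~ 1")
        with pytest.raises(ValueError, match="zero"):
            eg.fit(spec, eg.CountTable(df))
        # the override flag lets a forced fit proceed
        m = eg.fit(spec, eg.CountTable(df), allow_sparse_zeros=True)
        assert m.gamma is not None


class TestSerialization:
    def test_json_round_trip(self, small_glmm_table, tmp_path):
        m = eg.fit(eg.ModelSpec(formula="~ x", family="nbinom2", taxon="t1",
                                standardize=("x",)), small_glmm_table)
        path = tmp_path / "model.json"
        m.to_json(path)
        back = eg.FittedModel.from_json(path)
        np.testing.assert_allclose(back.beta, m.beta)
        np.testing.assert_allclose(back.se_beta, m.se_beta)
        assert back.dispersion == pytest.approx(m.dispersion)
        assert back.records["x"] == m.records["x"]
        assert back.aic == pytest.approx(m.aic)


class TestSeedIndependence:
    def test_fit_is_deterministic(self, small_glmm_table):
        spec = eg.ModelSpec(formula="~ x", family="nbinom2", taxon="t1")
        m1 = eg.fit(spec, small_glmm_table)
        m2 = eg.fit(spec, small_glmm_table)
        np.testing.assert_array_equal(m1.beta, m2.beta)
        assert m1.loglik == m2.loglik


@pytest.mark.parametrize("n_nodes", [7])
def test_glmmtmb_cross_check(tmp_path, n_nodes):
    """Independent engine check: Laplace NB2 GLMM vs glmmTMB (R).

    Both use the Laplace approximation (1 quadrature node here) so the
    objective is identical up to optimizer precision.
    """
    rng = np.random.default_rng(13)
    n_groups, n_per = 15, 25
    x = rng.normal(0, 1, n_groups * n_per)
    groups = np.repeat(np.arange(n_groups), n_per)
    b = rng.normal(0, 0.5, n_groups)
    mu = np.exp(1.0 + 0.6 * x + b[groups])
    y = eg.NB2(theta=1.5).simulate(mu, rng)
    table = eg.CountTable(pd.DataFrame({
        "site": [f"s{g:02d}" for g in groups],
        "night": [f"n{i:04d}" for i in range(len(x))],
        "taxon": "t1", "count": y, "x": x}))
    spec = eg.ModelSpec(formula="~ x", family="nbinom2", taxon="t1")
    m = eg.fit(spec, table, n_nodes=1)
    csv = tmp_path / "dat.csv"
    table.df.to_csv(csv, index=False)
    out = tmp_path / "res.txt"
    rscript = textwrap.dedent(f"""
        suppressMessages(library(glmmTMB))
        d <- read.csv("{csv}")
        fit <- glmmTMB(count ~ x + (1 | site), data = d, family = nbinom2)
        est <- fixef(fit)$cond
        res <- c(est, sigma(fit), sqrt(VarCorr(fit)$cond$site[1]),
                 as.numeric(logLik(fit)))
        writeLines(paste(res, collapse = ","), "{out}")
    """)
    proc = subprocess.run(["Rscript", "-e", rscript],
                          capture_output=True, text=True, timeout=300)
    assert proc.returncode == 0, proc.stderr
    vals = np.array([float(v) for v in out.read_text().split(",")])
    np.testing.assert_allclose(m.beta, vals[:2], atol=2e-3)
    assert m.dispersion["theta"] == pytest.approx(vals[2], abs=2e-2)
    assert m.sigma_b == pytest.approx(vals[3], abs=2e-2)
    assert m.loglik == pytest.approx(vals[4], abs=1e-3)
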