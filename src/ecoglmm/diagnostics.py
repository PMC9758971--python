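"""Simulation-based residual diagnostics for fitted count GLMMs.

An observation's *scaled quantile residual* is its randomized
probability-integral-transform position among ``n_sim`` responses simulated
from the fitted model: if the model is correct, the residuals are iid
Uniform(0, 1) regardless of the error distribution.  Formal checks built on
the simulations:

* Kolmogorov-Smirnov test of residual uniformity;
* a dispersion test comparing the variance of scaled observed deviations
  against its simulated null distribution;
* an outlier test counting observations that fall outside the entire
  simulated range.

Simulation is *unconditional* by default (fresh random intercepts drawn
from N(0, sigma_b^2) each replicate), which is the stricter check because
group-level misfit is not absorbed into conditioned-on intercepts; pass
``conditional=True`` to hold the estimated conditional modes fixed.

Reproducibility: every observation owns a substream keyed by
(seed, site, night, taxon) and every group's intercept stream is keyed by
(seed, site), so residuals are invariant to row order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit

from .families import ZeroInflated
from .fit import FittedModel

__all__ = ["ResidualSet", "simulate_residuals", "dispersion_test", "residual_plots"]


def _stream(seed: int, *tokens) -> np.random.Generator:
    keys = [seed & 0x7FFFFFFF] + [
        zlib.crc32(str(t).encode()) & 0x7FFFFFFF for t in tokens
    ]
    return np.random.default_rng(keys)


@dataclass
class ResidualSet:
    u: np.ndarray               # scaled residuals in (0, 1)
    y: np.ndarray
    simulations: np.ndarray     # n_obs x n_sim simulated responses
    predicted: np.ndarray       # population-level fitted means
    n_sim: int
    seed: int
    tests: dict

    @property
    def n_obs(self) -> int:
        return len(self.u)


def simulate_residuals(model: FittedModel, data=None, n_sim: int = 250,
                       seed: int = 0, conditional: bool = False) -> ResidualSet:
    """Scaled quantile residuals from ``n_sim`` model simulations."""
    if not model.converged:
        raise ValueError("model did not converge; residuals would be "
                         "meaningless")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100 for stable residual ranks")
    design = model._design
    if "X" not in design:
        raise ValueError("design matrices unavailable; refit the model")
    y = design["y"].astype(int)
    X = design["X"]
    Z = design["Z"]
    groups = design["groups"]
    df = design["df"]

    eta = X @ model.beta
    pi = None
    if Z is not None and model.gamma is not None:
        pi = np.clip(expit(Z @ model.gamma), 0.0, 1.0 - 1e-12)

    n_obs = len(y)
    sims = np.empty((n_obs, n_sim), dtype=np.int64)

    # group intercept draws, keyed by site identity
    if groups is not None and model.sigma_b > 0:
        levels = model.group_levels
        if conditional:
            b_mat = {g: np.full(n_sim, model.b_hat[g])
                     for g in range(len(levels))}
        else:
            b_mat = {
                g: _stream(seed, "b", levels[g]).normal(0.0, model.sigma_b, n_sim)
                for g in range(len(levels))
            }
    else:
        b_mat = None

    taxon = model.spec.taxon
    sites = df["site"].to_numpy() if "site" in df else np.zeros(n_obs)
    nights = df["night"].to_numpy() if "night" in df else np.arange(n_obs)
    u = np.empty(n_obs)
    fam = model.family
    for i in range(n_obs):
        rng_i = _stream(seed, "y", sites[i], nights[i], taxon)
        b_i = b_mat[groups[i]] if b_mat is not None else 0.0
        mu_i = np.exp(np.clip(eta[i] + b_i, -700, 700))
        mu_i = np.maximum(np.broadcast_to(mu_i, (n_sim,)), 1e-300)
        if pi is None:
            sims[i] = fam.simulate(mu_i, rng_i)
        else:
            sims[i] = ZeroInflated(fam).simulate(
                mu_i, np.full(n_sim, pi[i]), rng_i)
        n_below = int(np.sum(sims[i] < y[i]))
        n_equal = int(np.sum(sims[i] == y[i]))
        u[i] = (n_below + rng_i.random() * (n_equal + 1)) / (n_sim + 1)

    predicted = np.exp(eta)
    rs = ResidualSet(u=u, y=y, simulations=sims, predicted=predicted,
                     n_sim=n_sim, seed=seed, tests={})
    rs.tests["uniformity"] = _ks_uniformity(u)
    rs.tests["dispersion"] = dispersion_test(rs)
    rs.tests["outliers"] = _outlier_test(rs)
    return rs


def _ks_uniformity(u) -> dict:
    res = stats.kstest(u, "uniform")
    return {"statistic": float(res.statistic), "p": float(res.pvalue)}


def dispersion_test(resid: ResidualSet) -> dict:
    """Simulation-based over/under-dispersion test.

    The statistic is the variance of observed deviations scaled by the
    per-observation simulation mean and SD; its null distribution comes
    from applying the same statistic to each simulated replicate.  A ratio
    well above 1 signals overdispersion relative to the fitted model.
    """
    sims = resid.simulations.astype(float)
    m = sims.mean(axis=1)
    s = sims.std(axis=1, ddof=1)
    s = np.maximum(s, 1e-8)
    t_obs = float(np.var((resid.y - m) / s, ddof=1))
    t_sim = np.var((sims - m[:, None]) / s[:, None], axis=0, ddof=1)
    ratio = t_obs / float(np.mean(t_sim))
    n = len(t_sim)
    p_hi = (1 + np.sum(t_sim >= t_obs)) / (n + 1)
    p_lo = (1 + np.sum(t_sim <= t_obs)) / (n + 1)
    p = min(1.0, 2.0 * min(p_hi, p_lo))
    return {"ratio": float(ratio), "p": float(p)}


def _outlier_test(resid: ResidualSet) -> dict:
    """Observations outside the whole simulated range vs binomial law."""
    lo = resid.simulations.min(axis=1)
    hi = resid.simulations.max(axis=1)
    n_out = int(np.sum((resid.y < lo) | (resid.y > hi)))
    p_expect = 2.0 / (resid.n_sim + 1)
    test = stats.binomtest(n_out, resid.n_obs, p_expect)
    return {"count": n_out,
            "expected": resid.n_obs * p_expect,
            "p": float(test.pvalue)}


def residual_plots(resid: ResidualSet, model: FittedModel, path=None) -> dict:
    """QQ-uniform plot and residual-vs-predicted plot.

    Returns the underlying plot arrays for assertion; optionally writes a
    two-panel figure to ``path``.
    """
    n = resid.n_obs
    u_sorted = np.sort(resid.u)
    theoretical = (np.arange(1, n + 1) - 0.5) / n
    pred_rank = stats.rankdata(resid.predicted) / n
    plot_data = {
        "qq_theoretical": theoretical,
        "qq_observed": u_sorted,
        "pred_rank": pred_rank,
        "residual": resid.u,
    }
    if path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        axes[0].plot(theoretical, u_sorted, ".", ms=3)
        axes[0].plot([0, 1], [0, 1], "k--", lw=1)
        axes[0].set_xlabel("expected uniform quantile")
        axes[0].set_ylabel("observed residual")
        ks = resid.tests["uniformity"]
        axes[0].set_title(f"QQ uniform (KS p = {ks['p']:.3f})", fontsize=9)
        axes[1].plot(pred_rank, resid.u, ".", ms=3)
        for q in (0.25, 0.5, 0.75):
            axes[1].axhline(q, color="k", lw=0.5, ls=":")
        axes[1].set_xlabel("rank-transformed predicted mean")
        axes[1].set_ylabel("scaled residual")
        disp = resid.tests["dispersion"]
        axes[1].set_title(
            f"dispersion ratio = {disp['ratio']:.2f} (p = {disp['p']:.3f})",
            fontsize=9,
        )
        fig.suptitle(model.spec.label(), fontsize=10)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return plot_data
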