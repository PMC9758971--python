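"""Interpretation layer: real-world effect sizes and coefficient plots.

A log-link model fitted on scale2-standardized predictors has coefficients
on the "per two raw SDs" scale.  The multiplicative change in the expected
count for a raw-unit change ``delta_x`` in predictor x is

    factor = (exp(beta / (2 * sigma))) ** delta_x,

where sigma is the raw sample SD of x.  The percent change is
(factor - 1) * 100.  Confidence bounds come from pushing the Wald interval
beta +/- z * SE through the same back-transformation (endpoint
transformation), the standard construction for log-link effects; note the
resulting percent interval is asymmetric around the point estimate.

Predictors that entered the model unstandardized (e.g. a binary year
indicator) use the pass-through record with 2*sigma = 1, so one code path
serves both cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fit import FittedModel

__all__ = [
    "EffectQuery",
    "RealEffect",
    "real_effect",
    "real_effect_text",
    "real_effect_table",
    "effects_plot",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EffectQuery:
    """One back-transformation request.

    beta/se are on the standardized (scale2) coefficient scale; sigma is
    the raw-unit SD of the predictor; delta_x the raw-unit change of
    interest.
    """

    beta: float
    sigma: float
    delta_x: float
    se: float | None = None
    level: float = 0.95
    predictor: str = "the predictor"

    def __post_init__(self):
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError("sigma must be a positive finite raw-unit SD")
        if not np.isfinite(self.delta_x):
            raise ValueError("delta_x must be finite")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")


@dataclass(frozen=True)
class RealEffect:
    percent: float
    factor: float
    ci_percent: tuple | None
    level: float
    delta_x: float
    predictor: str

    def format_cell(self) -> str:
        """Table-cell string, e.g. '+82.30% (40.79%/123.81%)'."""
        cell = f"{self.percent:+.2f}%"
        if self.ci_percent is not None:
            cell += f" ({self.ci_percent[0]:.2f}%/{self.ci_percent[1]:.2f}%)"
        return cell


def _factor(beta: float, sigma: float, delta_x: float) -> float:
    return float(np.exp(beta / (2.0 * sigma)) ** delta_x)


def real_effect(q: EffectQuery) -> RealEffect:
    """Back-transform one standardized coefficient to a percent change."""
    factor = _factor(q.beta, q.sigma, q.delta_x)
    ci = None
    if q.se is not None:
        if not (np.isfinite(q.se) and q.se >= 0):
            raise ValueError("se must be a non-negative finite number")
        z = stats.norm.ppf(0.5 + q.level / 2.0)
        lo = _factor(q.beta - z * q.se, q.sigma, q.delta_x)
        hi = _factor(q.beta + z * q.se, q.sigma, q.delta_x)
        if lo > hi:  # delta_x < 0 flips the endpoints
            lo, hi = hi, lo
        ci = ((lo - 1.0) * 100.0, (hi - 1.0) * 100.0)
    return RealEffect(
        percent=(factor - 1.0) * 100.0,
        factor=factor,
        ci_percent=ci,
        level=q.level,
        delta_x=q.delta_x,
        predictor=q.predictor,
    )


def real_effect_text(q: EffectQuery) -> str:
    """Human-readable sentence for one effect."""
    eff = real_effect(q)
    verb = "increases" if eff.percent >= 0 else "decreases"
    sentence = (
        f"the response variable {verb} {abs(eff.percent):.2f}%"
    )
    if eff.ci_percent is not None:
        sentence += (
            f" ({eff.level:.0%} CI: {eff.ci_percent[0]:.2f}%/"
            f"{eff.ci_percent[1]:.2f}%)"
        )
    sentence += (
        f" for every {q.delta_x:g} unit increase in {q.predictor}"
    )
    return sentence


def _query_from_model(model: FittedModel, predictor: str, delta_x: float,
                      level: float) -> EffectQuery:
    if predictor not in model.coef_names:
        raise KeyError(predictor)
    j = model.coef_names.index(predictor)
    rec = model.records.get(predictor)
    sigma = rec.sd if rec is not None else 0.5  # 2*sigma = 1 pass-through
    se = None if model.se_beta is None else float(model.se_beta[j])
    return EffectQuery(
        beta=float(model.beta[j]), sigma=sigma, delta_x=delta_x,
        se=se, level=level, predictor=predictor,
    )


def real_effect_table(models: dict, predictors: list[str],
                      deltas: list[float], level: float = 0.95
                      ) -> pd.DataFrame:
    """Taxon x predictor grid of formatted real effects.

    ``models`` maps taxon -> FittedModel; ``deltas`` aligns with
    ``predictors`` (raw-unit change per predictor).  A predictor missing
    from a model yields an empty cell rather than aborting the table.
    """
    if len(predictors) != len(deltas):
        raise ValueError("predictors and deltas must align")
    rows = []
    for predictor, dx in zip(predictors, deltas):
        row = {"predictor": predictor, "unit_increase": dx}
        for taxon, model in models.items():
            try:
                eff = real_effect(_query_from_model(model, predictor, dx, level))
                row[taxon] = eff.format_cell()
            except KeyError:
                log.warning("predictor %r absent from model for taxon %r",
                            predictor, taxon)
                row[taxon] = ""
        rows.append(row)
    return pd.DataFrame(rows)


def effects_plot(models: dict, levels=(0.85, 0.95), path=None) -> dict:
    """Forest plots of standardized coefficients with nested intervals.

    ``levels`` is 1-3 strictly increasing confidence levels; the returned
    dict maps taxon -> DataFrame of plot data (coef, and lower/upper per
    level).  When ``path`` is given a multi-panel figure is written.
    """
    levels = tuple(levels)
    if not 1 <= len(levels) <= 3:
        raise ValueError("between 1 and 3 confidence levels are supported")
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise ValueError("levels must be strictly increasing")
    if any(not 0 < lv < 1 for lv in levels):
        raise ValueError("levels must be in (0, 1)")

    plot_data = {}
    for taxon, model in models.items():
        names = [n for n in model.coef_names if n != "Intercept"]
        idx = [model.coef_names.index(n) for n in names]
        data = {"coef": model.beta[idx]}
        for lv in levels:
            z = stats.norm.ppf(0.5 + lv / 2.0)
            se = model.se_beta[idx] if model.se_beta is not None else np.nan
            data[f"lower_{lv:g}"] = model.beta[idx] - z * se
            data[f"upper_{lv:g}"] = model.beta[idx] + z * se
        plot_data[taxon] = pd.DataFrame(data, index=names)

    if path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        n_panel = len(plot_data)
        ncol = min(3, n_panel)
        nrow = int(np.ceil(n_panel / ncol))
        fig, axes = plt.subplots(
            nrow, ncol, figsize=(4 * ncol, 3.2 * nrow), squeeze=False
        )
        widths = {lv: 2.5 - 0.8 * i for i, lv in enumerate(levels)}
        for ax, (taxon, pdata) in zip(axes.ravel(), plot_data.items()):
            ypos = np.arange(len(pdata))[::-1]
            for lv in levels:
                ax.hlines(ypos, pdata[f"lower_{lv:g}"], pdata[f"upper_{lv:g}"],
                          lw=widths[lv], alpha=0.8,
                          label=f"{lv:.0%} CI")
            ax.plot(pdata["coef"], ypos, "o", ms=4, color="k")
            ax.axvline(0.0, color="grey", lw=0.8, ls="--")
            ax.set_yticks(ypos)
            ax.set_yticklabels(pdata.index, fontsize=7)
            ax.set_title(str(taxon), fontsize=9)
        for ax in axes.ravel()[n_panel:]:
            ax.set_visible(False)
        handles, labels = axes.ravel()[0].get_legend_handles_labels()
        fig.legend(handles, labels, loc="lower right", fontsize=8)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return plot_data
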