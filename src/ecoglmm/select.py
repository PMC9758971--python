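"""Candidate-model comparison and mean-variance diagnostics.

Two non-exclusive lines of evidence for choosing the count family and the
need for a zero-inflation submodel:

* :func:`model_compare` ranks each taxon's candidates by AIC;
* :func:`distfit` aggregates the raw counts into groups, plots per-group
  (mean, variance) points, and overlays the three families' variance
  curves with dispersion summarized by weighted least squares.

The curve with the lowest weighted SSE is this package's operationalization
of "the line that best fits the scatter"; a simpler family within 5%
relative SSE of the minimum is preferred, since curves that close are
visually indistinguishable.  The two methods usually agree; on conflict the
workflow's convention is to trust the mean-variance plot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CountTable
from .fit import FittedModel

__all__ = ["model_compare", "distfit", "ComparisonTable", "MeanVarianceDiagnostic"]

log = logging.getLogger(__name__)

#: simplicity order used for AIC ties and the distfit parsimony rule
_FAMILY_ORDER = {"poisson": 0, "nbinom1": 1, "nbinom2": 2}


@dataclass
class ComparisonTable:
    table: pd.DataFrame
    best: dict  # taxon -> FittedModel
    failed_taxa: list = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _candidate_sort_key(m: FittedModel):
    # AIC, then fewest parameters, then Poisson < NB1 < NB2, then non-ZI
    return (
        m.aic,
        m.k,
        _FAMILY_ORDER.get(m.family.name, 99),
        0 if m.spec.zi_formula is None else 1,
    )


def model_compare(candidates: list[FittedModel]) -> ComparisonTable:
    """Rank candidate models per taxon by AIC.

    Unconverged candidates are listed (delta-AIC blank) but never
    selected; a taxon with no converged candidate is reported in
    ``failed_taxa`` and omitted from the best-model map.
    """
    if not candidates:
        raise ValueError("no candidate models supplied")
    rows = []
    by_taxon: dict = {}
    for m in candidates:
        by_taxon.setdefault(m.spec.taxon, []).append(m)
    best: dict = {}
    failed = []
    for taxon, models in by_taxon.items():
        ok = [m for m in models if m.converged]
        if not ok:
            failed.append(taxon)
            log.warning("taxon %r: no converged candidate", taxon)
        else:
            chosen = min(ok, key=_candidate_sort_key)
            best[taxon] = chosen
            best_aic = min(m.aic for m in ok)
        for m in models:
            rows.append({
                "taxon": taxon,
                "model": m.spec.label(),
                "family": m.family.name,
                "zero_inflated": m.spec.zi_formula is not None,
                "k": m.k,
                "loglik": m.loglik,
                "AIC": m.aic,
                "dAIC": (m.aic - best_aic) if (ok and m.converged) else np.nan,
                "converged": m.converged,
                "best": ok and m is best.get(taxon),
            })
    table = pd.DataFrame(rows).sort_values(["taxon", "AIC"]).reset_index(drop=True)
    return ComparisonTable(table=table, best=best, failed_taxa=failed)


@dataclass
class MeanVarianceDiagnostic:
    points: pd.DataFrame            # columns: mean, variance, n
    phi_hat: float                  # NB1 linear slope, clamped >= 1
    theta_hat: float                # NB2 quadratic shape, > 0
    sse: dict                       # family -> weighted SSE of its curve
    best_family: str
    n_excluded: int

    def curve(self, family: str, m) -> np.ndarray:
        m = np.asarray(m, dtype=float)
        if family == "poisson":
            return m
        if family == "nbinom1":
            return self.phi_hat * m
        if family == "nbinom2":
            return m + m * m / self.theta_hat
        raise ValueError(family)

    def plot(self, path=None, ax=None):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4.5))
        pts = self.points
        ax.scatter(pts["mean"], pts["variance"], s=10 + 2 * pts["n"],
                   alpha=0.6, label="group (mean, variance)")
        grid = np.linspace(pts["mean"].min(), pts["mean"].max(), 200)
        labels = {
            "poisson": "Poisson: $s^2 = m$",
            "nbinom1": rf"NB1: $s^2 = {self.phi_hat:.2f}\,m$",
            "nbinom2": rf"NB2: $s^2 = m + m^2/{self.theta_hat:.2f}$",
        }
        for fam, lab in labels.items():
            ax.plot(grid, self.curve(fam, grid), label=lab)
        ax.set_xlabel("group mean")
        ax.set_ylabel("group variance")
        ax.legend(fontsize=8)
        if path is not None:
            ax.figure.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(ax.figure)
        return ax


def distfit(data: CountTable, taxon, group_by: list[str],
            parsimony_tol: float = 0.05) -> MeanVarianceDiagnostic:
    """Mean-variance diagnostic for one taxon.

    Counts are aggregated by the exact value combinations of ``group_by``
    (continuous covariates must be pre-binned by the caller); groups of
    size < 2 are dropped.  Dispersion summaries:

    * phi_hat: WLS slope of variance on mean through the origin
      (weights = group sizes), clamped at >= 1;
    * theta_hat: from WLS of (variance - mean) on mean^2, inverse slope
      clamped to positive.
    """
    df = data.for_taxon(taxon)
    grouped = df.groupby(group_by, observed=True)["count"]
    stats_df = grouped.agg(mean="mean", variance="var", n="size").reset_index()
    n_excluded = int((stats_df["n"] < 2).sum())
    if n_excluded:
        log.info("distfit: excluding %d singleton group(s)", n_excluded)
    pts = stats_df[stats_df["n"] >= 2].reset_index(drop=True)
    if len(pts) < 3:
        raise ValueError(
            f"only {len(pts)} usable groups after excluding singletons; "
            "aggregate more coarsely"
        )
    m = pts["mean"].to_numpy(dtype=float)
    s2 = pts["variance"].to_numpy(dtype=float)
    w = pts["n"].to_numpy(dtype=float)

    phi_hat = float(np.sum(w * s2 * m) / np.sum(w * m * m))
    phi_hat = max(phi_hat, 1.0)
    num = float(np.sum(w * (s2 - m) * m * m))
    den = float(np.sum(w * m ** 4))
    inv_theta = max(num / den, 1e-8)
    theta_hat = 1.0 / inv_theta

    sse = {}
    for fam, pred in (
        ("poisson", m),
        ("nbinom1", phi_hat * m),
        ("nbinom2", m + m * m / theta_hat),
    ):
        sse[fam] = float(np.sum(w * (s2 - pred) ** 2))
    min_sse = min(sse.values())
    # parsimony: simplest family whose SSE is within tolerance of the best
    best_family = min(
        (f for f in sse if sse[f] <= min_sse * (1.0 + parsimony_tol)),
        key=lambda f: _FAMILY_ORDER[f],
    )
    return MeanVarianceDiagnostic(
        points=pts[group_by + ["mean", "variance", "n"]],
        phi_hat=phi_hat,
        theta_hat=theta_hat,
        sse=sse,
        best_family=best_family,
        n_excluded=n_excluded,
    )
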