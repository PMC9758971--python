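"""End-to-end analysis pipeline with a reproducible artifact manifest.

Stages, in order: read & standardize -> fit every candidate model (families
x zero-inflation, per taxon) -> AIC comparison + mean-variance diagnostics
-> simulated-residual checks on each taxon's best model -> effects plots
and real-effect tables.  Every artifact lands in the output directory and
is listed, with a SHA-256 checksum for data-bearing files, in
``manifest.json`` together with the exact configuration and seed used.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import data as dm
from . import diagnostics as dg
from . import effects as ef
from . import select as sel
from .fit import ModelSpec, fit

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage, message):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Parsed pipeline configuration.

    See :meth:`from_yaml` for the file layout.  ``candidates`` defaults to
    the full six-model grid ({poisson, nbinom1, nbinom2} x {ZI, no ZI})
    whenever a ``zi_formula`` is given, and to the three non-ZI families
    otherwise.
    """

    input: str
    formula: str
    form: str = "long"                     # long | wide
    taxon_columns: list = field(default_factory=list)   # wide form only
    column_map: dict = field(default_factory=dict)
    group: str = "site"
    zi_formula: str | None = None
    standardize: list = field(default_factory=list)
    families: list = field(default_factory=lambda: ["poisson", "nbinom1", "nbinom2"])
    zero_inflation: list = field(default_factory=lambda: [False, True])
    taxa: list | None = None
    distfit_group_by: list = field(default_factory=lambda: ["site"])
    out_dir: str = "ecoglmm_out"
    seed: int = 0
    ci_levels: list = field(default_factory=lambda: [0.85, 0.95])
    n_sim: int = 250
    effect_predictors: list = field(default_factory=list)
    effect_deltas: list = field(default_factory=list)

    def __post_init__(self):
        from .families import FAMILY_NAMES

        for f in self.families:
            if f not in FAMILY_NAMES:
                raise ValueError(f"unknown family {f!r}")
        if self.form not in ("long", "wide"):
            raise ValueError("form must be 'long' or 'wide'")
        if not 1 <= len(self.ci_levels) <= 3 or any(
            not 0 < lv < 1 for lv in self.ci_levels
        ):
            raise ValueError("ci_levels must be 1-3 probabilities in (0, 1)")
        if True in self.zero_inflation and not self.zi_formula:
            self.zero_inflation = [False]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow; returns the output directory.

    Any stage failure raises :class:`PipelineError` naming the stage;
    artifacts already written are kept next to a ``FAILED`` marker.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.__dict__.copy(), "seed": config.seed,
                "artifacts": [], "checksums": {}}

    def record(path: Path, data_bearing=True):
        manifest["artifacts"].append(str(path.relative_to(out)))
        if data_bearing:
            manifest["checksums"][str(path.relative_to(out))] = _sha256(path)

    stage = "read"
    try:
        if config.form == "long":
            table = dm.read_long(config.input, config.column_map)
        else:
            import pandas as pd

            table = dm.wide_to_long(
                pd.read_csv(config.input), config.taxon_columns)
        taxa = config.taxa or table.taxa
        if config.standardize:
            table = table.drop_missing(list(config.standardize))

        stage = "fit"
        candidates = []
        for taxon in taxa:
            for fam in config.families:
                for zi in config.zero_inflation:
                    spec = ModelSpec(
                        formula=config.formula,
                        family=fam,
                        taxon=taxon,
                        group=config.group,
                        zi_formula=config.zi_formula if zi else None,
                        standardize=tuple(config.standardize),
                    )
                    try:
                        candidates.append(fit(spec, table))
                    except Exception as exc:
                        log.warning("candidate %s failed: %s",
                                    spec.label(), exc)
        if not candidates:
            raise PipelineError(stage, "no candidate model could be fitted")
        models_dir = out / "models"
        models_dir.mkdir(exist_ok=True)
        for m in candidates:
            p = models_dir / f"{m.spec.label()}.json"
            m.to_json(p)
            record(p)
        if config.standardize and candidates:
            p = out / "standardization.json"
            dm.records_to_json(candidates[0].records, p)
            record(p)

        stage = "compare"
        comparison = sel.model_compare(candidates)
        p = out / "model_comparison.csv"
        comparison.to_csv(p)
        record(p)
        for taxon in taxa:
            try:
                diag = sel.distfit(table, taxon, config.distfit_group_by)
                pp = out / f"distfit_{taxon}.png"
                diag.plot(pp)
                record(pp, data_bearing=False)
            except ValueError as exc:
                log.warning("distfit skipped for %r: %s", taxon, exc)

        stage = "diagnostics"
        resid_reports = {}
        for taxon, model in comparison.best.items():
            rs = dg.simulate_residuals(model, n_sim=config.n_sim,
                                       seed=config.seed)
            pp = out / f"residuals_{taxon}.png"
            dg.residual_plots(rs, model, path=pp)
            record(pp, data_bearing=False)
            resid_reports[str(taxon)] = rs.tests
        p = out / "residual_tests.json"
        p.write_text(json.dumps(resid_reports, indent=2))
        record(p)

        stage = "effects"
        if comparison.best:
            pp = out / "effects_plot.png"
            ef.effects_plot(comparison.best, levels=tuple(config.ci_levels),
                            path=pp)
            record(pp, data_bearing=False)
            if config.effect_predictors:
                tab = ef.real_effect_table(
                    comparison.best, config.effect_predictors,
                    config.effect_deltas, level=max(config.ci_levels),
                )
                p = out / "real_effects.csv"
                tab.to_csv(p, index=False)
                record(p)
    except PipelineError:
        (out / "FAILED").write_text(stage)
        raise
    except Exception as exc:
        (out / "FAILED").write_text(f"{stage}: {exc}")
        raise PipelineError(stage, str(exc)) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return out
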