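"""Count-table ingestion, validation, reshaping and 2-SD standardization.

The universal internal representation is a tidy long-form
:class:`pandas.DataFrame` with one row per site x night x taxon, a
non-negative integer ``count`` column, and arbitrary covariate columns.
Site-night is the observational unit: a single detector-night of monitoring
at one site.

Continuous predictors are standardized by *two* sample standard deviations,

    x_std = (x - mean(x)) / (2 * sd(x)),

so that a one-unit change on the standardized scale spans the bulk of the
predictor's range and — because a balanced binary 0/1 covariate has sample
SD 0.5 — standardized continuous coefficients are directly comparable with
raw binary-predictor coefficients.  The (mean, sd) pair of every predictor
is kept in a :class:`StandardizationRecord` so effects can later be
back-transformed to raw units.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "StandardizationRecord",
    "read_long",
    "wide_to_long",
    "long_to_wide",
    "scale2",
    "SchemaError",
    "ValidationError",
]

log = logging.getLogger(__name__)

KEY_COLUMNS = ("site", "night", "taxon")


class SchemaError(ValueError):
    """A required column is missing or mis-declared."""


class ValidationError(ValueError):
    """The data violate a count-table invariant."""


@dataclass(frozen=True)
class StandardizationRecord:
    """Raw-unit mean and SD used to standardize one predictor.

    ``sd`` is the sample (n-1 denominator) standard deviation.  A record
    with ``sd`` such that 2*sd == 1 marks a predictor that passed through
    unstandardized (e.g. a binary year indicator), keeping a single
    back-transformation code path.
    """

    predictor: str
    mean: float
    sd: float

    def __post_init__(self):
        if not (np.isfinite(self.sd) and self.sd > 0):
            raise ValidationError(
                f"standardization of {self.predictor!r}: sd must be > 0"
            )

    def apply(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / (2.0 * self.sd)

    def invert(self, z):
        return np.asarray(z, dtype=float) * 2.0 * self.sd + self.mean

    @classmethod
    def identity(cls, predictor: str) -> "StandardizationRecord":
        """Pass-through record: scale factor 2*sd = 1, mean 0."""
        return cls(predictor=predictor, mean=0.0, sd=0.5)


def records_to_json(records: dict[str, StandardizationRecord], path) -> None:
    Path(path).write_text(
        json.dumps({k: asdict(v) for k, v in records.items()}, indent=2)
    )


def records_from_json(path) -> dict[str, StandardizationRecord]:
    raw = json.loads(Path(path).read_text())
    return {k: StandardizationRecord(**v) for k, v in raw.items()}


class CountTable:
    """Validated long-form multi-taxa count data.

    Thin wrapper around a DataFrame with columns ``site``, ``night``,
    ``taxon``, ``count`` plus covariates.  Invariants enforced on
    construction:

    * counts are integers >= 0;
    * (site, night, taxon) combinations are unique;
    * every taxon has at least one row.
    """

    def __init__(self, df: pd.DataFrame, site_night_covariates: list[str] | None = None):
        df = df.copy()
        for col in KEY_COLUMNS + ("count",):
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r}")
        counts = df["count"]
        if counts.isna().any():
            bad = counts[counts.isna()].index[0]
            raise ValidationError(f"missing count at row {bad}")
        as_num = pd.to_numeric(counts, errors="coerce")
        if as_num.isna().any() or not np.allclose(as_num, np.round(as_num)):
            bad = df.index[(as_num.isna()) | (as_num != np.round(as_num))][0]
            raise ValidationError(f"non-integer count at row {bad}")
        if (as_num < 0).any():
            bad = df.index[as_num < 0][0]
            raise ValidationError(f"negative count at row {bad}")
        df["count"] = as_num.astype(np.int64)

        dup = df.duplicated(subset=list(KEY_COLUMNS))
        if dup.any():
            key = df.loc[dup.idxmax(), list(KEY_COLUMNS)].tolist()
            raise ValidationError(
                f"duplicated (site, night, taxon) key {tuple(key)}"
            )
        if site_night_covariates:
            grp = df.groupby(["site", "night"], observed=True)
            for cov in site_night_covariates:
                if cov not in df.columns:
                    raise SchemaError(f"declared covariate {cov!r} not present")
                if (grp[cov].nunique(dropna=False) > 1).any():
                    raise ValidationError(
                        f"covariate {cov!r} varies within a site-night pair"
                    )
        self.df = df.reset_index(drop=True)

    # ------------------------------------------------------------------
    @property
    def taxa(self) -> list:
        return sorted(self.df["taxon"].unique().tolist())

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in KEY_COLUMNS + ("count",)]

    def for_taxon(self, taxon) -> pd.DataFrame:
        sub = self.df[self.df["taxon"] == taxon]
        if sub.empty:
            raise KeyError(f"no rows for taxon {taxon!r}")
        return sub.reset_index(drop=True)

    def drop_missing(self, covariates: list[str]) -> "CountTable":
        """Drop rows with any missing value among the model covariates."""
        mask = self.df[covariates].notna().all(axis=1)
        n_drop = int((~mask).sum())
        if n_drop:
            log.warning("dropping %d rows with missing covariates", n_drop)
        return CountTable(self.df[mask])

    def standardize(
        self, predictors: list[str]
    ) -> tuple["CountTable", dict[str, StandardizationRecord]]:
        """scale2 the named predictors; returns (new table, records).

        A predictor is standardized on the distinct site-night values when
        it is constant within site-nights, so that repeating rows across
        taxa does not distort the mean/SD.
        """
        df = self.df.copy()
        records: dict[str, StandardizationRecord] = {}
        sn = df.drop_duplicates(subset=["site", "night"])
        for name in predictors:
            if name not in df.columns:
                raise SchemaError(f"unknown predictor {name!r}")
            per_sn = sn.groupby(["site", "night"], observed=True)[name].nunique()
            base = sn[name] if (per_sn <= 1).all() else df[name]
            _, rec = scale2(base.to_numpy(dtype=float), name=name)
            df[name] = rec.apply(df[name])
            records[name] = rec
        return CountTable(df), records

    def __len__(self):
        return len(self.df)

    def __repr__(self):
        return (
            f"CountTable({len(self.df)} rows, {len(self.taxa)} taxa, "
            f"{self.df['site'].nunique()} sites)"
        )


def read_long(path, column_map: dict[str, str] | None = None) -> CountTable:
    """Read a long-form CSV into a validated :class:`CountTable`.

    Parameters
    ----------
    path
        CSV file with one row per site x night x taxon.
    column_map
        Mapping from required names (``site``, ``night``, ``taxon``,
        ``count``) to the column names actually present in the file.
        Unmapped columns pass through as covariates.
    """
    df = pd.read_csv(path)
    column_map = column_map or {}
    rename = {}
    for canonical in KEY_COLUMNS + ("count",):
        src = column_map.get(canonical, canonical)
        if src not in df.columns:
            raise SchemaError(
                f"column {src!r} (mapped to {canonical!r}) not found in {path}"
            )
        rename[src] = canonical
    return CountTable(df.rename(columns=rename))


def wide_to_long(
    df: pd.DataFrame, taxon_columns: list[str]
) -> CountTable:
    """Melt a wide table (one count column per taxon) into a CountTable."""
    if not taxon_columns:
        raise ValidationError("taxon_columns must not be empty")
    for col in taxon_columns:
        if col not in df.columns:
            raise SchemaError(f"taxon column {col!r} not found")
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or not np.allclose(vals, np.round(vals)):
            raise ValidationError(f"taxon column {col!r} is not integer-valued")
    id_vars = [c for c in df.columns if c not in taxon_columns]
    long = df.melt(
        id_vars=id_vars, value_vars=taxon_columns,
        var_name="taxon", value_name="count",
    )
    return CountTable(long)


def long_to_wide(table: CountTable) -> pd.DataFrame:
    """Pivot back to one count column per taxon (inverse of wide_to_long)."""
    df = table.df
    covs = table.covariate_columns
    idx = ["site", "night"] + covs
    wide = df.pivot_table(
        index=idx, columns="taxon", values="count", aggfunc="first",
        observed=True,
    ).reset_index()
    wide.columns.name = None
    return wide


def scale2(x, name: str = "x") -> tuple[np.ndarray, StandardizationRecord]:
    """Standardize a vector by two sample standard deviations.

    Returns the standardized vector (mean 0, sample SD 0.5) and the
    :class:`StandardizationRecord` needed to undo the transform.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValidationError(f"scale2({name!r}): need at least 2 values")
    mean = float(np.mean(x))
    centered = x - mean
    # compensated second pass: large offsets otherwise leave O(eps * |mean|)
    # residual mean that a small SD amplifies
    centered = centered - centered.mean()
    sd = float(np.std(centered, ddof=1))
    if not sd > 0:
        raise ValidationError(f"scale2({name!r}): predictor is constant (sd = 0)")
    rec = StandardizationRecord(predictor=name, mean=mean, sd=sd)
    return centered / (2.0 * sd), rec
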