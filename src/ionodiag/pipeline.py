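"""Ingest, filter and prepare foliar ionome survey tables.

The working container is a :class:`pandas.DataFrame` with one row per leaf
sample. Canonical columns::

    trial_id, year, cultivar, maturity_class, off_stage,
    yield_mg_ha, N, P, K, Mg, Ca          # nutrient mass fractions of DM

Processing adds ``Fv`` (filling value), the six ``clr_*`` columns and, after
discretization, ``yield_class`` in {"high", "low"}.

The pipeline mirrors a survey-data workflow: drop samples collected off the
diagnostic growth stage (first mature leaf at the beginning of flowering),
drop samples with three or more of the five nutrients unquantified, build
6-part compositions with the filling value, split yields into high/low per
cultivar at the 65th percentile, and screen multivariate outliers in clr
space with a chi-square cut on the Mahalanobis distance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coda import NUTRIENTS, PARTS

__all__ = [
    "CANONICAL_COLUMNS",
    "CLR_COLUMNS",
    "SchemaError",
    "FilterReport",
    "OutlierReport",
    "read_ionome_table",
    "compute_composition",
    "add_compositions",
    "filter_records",
    "discretize_yield",
    "clr_matrix",
    "remove_outliers",
    "preprocess",
]

CANONICAL_COLUMNS: tuple[str, ...] = (
    "trial_id", "year", "cultivar", "maturity_class", "off_stage",
    "yield_mg_ha", "N", "P", "K", "Mg", "Ca",
)

CLR_COLUMNS: tuple[str, ...] = tuple(f"clr_{p}" for p in PARTS)

_NUMERIC = ("year", "yield_mg_ha") + NUTRIENTS

#: Unit of the nutrient columns in the source file -> factor to mass fraction.
_UNIT_FACTORS = {"fraction": 1.0, "g_kg": 1e-3, "percent": 1e-2}


class SchemaError(ValueError):
    """Raised when a source table lacks mandatory columns."""


@dataclass
class FilterReport:
    """Row counts removed by each record-level filter rule."""

    n_input: int = 0
    removed_off_stage: int = 0
    removed_missing_nutrients: int = 0
    n_retained: int = 0

    def asdict(self) -> dict:
        return asdict(self)


@dataclass
class OutlierReport:
    """Summary of multivariate outlier screening."""

    n_input: int = 0
    n_flagged: int = 0
    alpha: float = 0.01
    df: int = 0
    cutoff: float = 0.0
    singular_covariance: bool = False

    def asdict(self) -> dict:
        return asdict(self)


def read_ionome_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    nutrient_unit: str = "fraction",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a delimited ionome survey table into the canonical frame.

    Parameters
    ----------
    path : str or Path
        CSV file with a header row.
    schema : mapping, optional
        Maps canonical column names to the file's column names; identity
        for names not listed. ``off_stage`` may be absent in the source, in
        which case every record is assumed on-stage.
    nutrient_unit : {"fraction", "g_kg", "percent"}
        Unit of the nutrient columns; values are converted to mass
        fractions of 1 internally.

    Returns
    -------
    (data, rejects)
        ``data`` holds the typed records; ``rejects`` the rows whose yield
        or nutrient cells failed numeric parsing, with a ``reject_reason``
        column. Missing nutrient cells are kept as NaN, never as zero.
    """
    if nutrient_unit not in _UNIT_FACTORS:
        raise ValueError(f"unknown nutrient_unit {nutrient_unit!r}")
    schema = dict(schema or {})
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    rename = {schema.get(c, c): c for c in CANONICAL_COLUMNS
              if schema.get(c, c) in raw.columns}
    raw = raw.rename(columns=rename)

    mandatory = [c for c in CANONICAL_COLUMNS if c != "off_stage"]
    missing = [c for c in mandatory if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    if "off_stage" not in raw.columns:
        raw["off_stage"] = "False"

    df = raw.loc[:, list(CANONICAL_COLUMNS)].copy()

    def _parse(v):  # exact float round-trip; pd.to_numeric is not bit-exact
        if v is None:
            return np.nan
        s = str(v).strip()
        if s == "" or s.lower() in ("nan", "na"):
            return np.nan
        try:
            return float(s)
        except ValueError:
            return np.nan

    for col in _NUMERIC:
        df[col] = df[col].map(_parse).astype(float)
    df["off_stage"] = (
        df["off_stage"].astype(str).str.strip().str.lower()
        .isin(("1", "true", "yes", "t"))
    )

    # yield is mandatory per record; nutrient cells may legitimately be
    # missing, but a cell that was present yet unparseable rejects the row.
    bad_yield = df["yield_mg_ha"].isna() & raw["yield_mg_ha"].notna()
    bad_nutrient = pd.Series(False, index=df.index)
    for n in NUTRIENTS:
        bad_nutrient |= df[n].isna() & raw[n].notna() & (raw[n].str.strip() != "")
    bad = bad_yield | bad_nutrient
    rejects = raw.loc[bad].copy()
    rejects["reject_reason"] = np.where(
        bad_yield[bad], "unparseable yield", "unparseable nutrient")
    df = df.loc[~bad].reset_index(drop=True)

    factor = _UNIT_FACTORS[nutrient_unit]
    if factor != 1.0:
        df[list(NUTRIENTS)] = df[list(NUTRIENTS)] * factor
    return df, rejects.reset_index(drop=True)


def compute_composition(nutrients: Mapping[str, float]) -> dict[str, float]:
    """Build the 6-part composition of one record from its nutrient fractions.

    The filling value Fv = 1 − ΣNutrients amalgamates the unquantified dry
    matter. All five nutrients must be present and positive, and their sum
    strictly below 1 so that Fv > 0.
    """
    vals = []
    for n in NUTRIENTS:
        v = nutrients.get(n)
        if v is None or not np.isfinite(v):
            raise ValueError(f"nutrient {n} missing; cannot build composition")
        if v <= 0:
            raise ValueError(f"nutrient {n} must be positive, got {v}")
        vals.append(float(v))
    total = sum(vals)
    if total >= 1.0:
        raise ValueError(
            f"nutrient fractions sum to {total:.4g} >= 1; filling value "
            "would be non-positive")
    comp = dict(zip(NUTRIENTS, vals))
    comp["Fv"] = 1.0 - total
    return comp


def add_compositions(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Add ``Fv`` and clr columns for every record with a complete ionome.

    Records with any nutrient missing or with ΣNutrients ≥ 1 cannot carry a
    composition; they are returned separately so the caller can report them.
    """
    nut = df.loc[:, list(NUTRIENTS)]
    complete = nut.notna().all(axis=1) & (nut > 0).all(axis=1)
    total = nut.sum(axis=1)
    usable = complete & (total < 1.0)

    out = df.loc[usable].copy()
    out["Fv"] = 1.0 - total[usable]
    mat = out.loc[:, list(PARTS)].to_numpy(dtype=float)
    logs = np.log(mat)
    clr = logs - logs.mean(axis=1, keepdims=True)
    for j, col in enumerate(CLR_COLUMNS):
        out[col] = clr[:, j]
    unusable = df.loc[~usable].copy()
    return out.reset_index(drop=True), unusable.reset_index(drop=True)


def filter_records(
    df: pd.DataFrame,
    max_missing_nutrients: int = 2,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the record-level survey filters.

    Removes samples flagged as collected off the diagnostic growth stage
    and samples where three or more of the five nutrients were not
    quantified (i.e. more than ``max_missing_nutrients`` missing).
    Idempotent.
    """
    report = FilterReport(n_input=len(df))
    off = df["off_stage"].fillna(False).astype(bool)
    report.removed_off_stage = int(off.sum())
    kept = df.loc[~off]

    n_missing = kept.loc[:, list(NUTRIENTS)].isna().sum(axis=1)
    too_sparse = n_missing > max_missing_nutrients
    report.removed_missing_nutrients = int(too_sparse.sum())
    kept = kept.loc[~too_sparse].reset_index(drop=True)
    report.n_retained = len(kept)
    return kept, report


def discretize_yield(
    df: pd.DataFrame,
    percentile: float = 65.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split marketable yield into high/low classes per cultivar.

    Each cultivar gets its own cut-off — the ``percentile``-th percentile
    of its marketable yields (linear interpolation between order
    statistics). Records strictly above the cut-off are labelled ``high``,
    the rest ``low``, so a cultivar with continuous yields ends up with
    roughly 35 % high-yielders. Cultivars with a single record are left
    unlabelled (NaN class) and excluded from the cut-off table.

    Returns the labelled frame and a cut-off table with columns
    ``cultivar, n, cutoff``.
    """
    df = df.copy()
    df["yield_class"] = pd.Series(pd.NA, index=df.index, dtype="string")
    rows = []
    for cultivar, grp in df.groupby("cultivar", sort=True):
        if len(grp) < 2:
            continue
        cutoff = float(np.percentile(grp["yield_mg_ha"].to_numpy(), percentile))
        df.loc[grp.index, "yield_class"] = np.where(
            grp["yield_mg_ha"] > cutoff, "high", "low")
        rows.append({"cultivar": cultivar, "n": len(grp), "cutoff": cutoff})
    cutoffs = pd.DataFrame(rows, columns=["cultivar", "n", "cutoff"])
    return df, cutoffs


def clr_matrix(df: pd.DataFrame, drop_part: str | None = None) -> np.ndarray:
    """Extract the clr design matrix, optionally dropping one coordinate.

    The six clr values are linearly dependent (they sum to zero); dropping
    one coordinate yields a full-rank matrix for covariance-based methods.
    """
    cols = list(CLR_COLUMNS)
    if drop_part is not None:
        cols.remove(f"clr_{drop_part}")
    return df.loc[:, cols].to_numpy(dtype=float)


def remove_outliers(
    clr: np.ndarray,
    alpha: float = 0.01,
) -> tuple[np.ndarray, OutlierReport]:
    """Flag multivariate outliers in clr space by Mahalanobis distance.

    Squared Mahalanobis distances from the sample mean are compared with
    the chi-square quantile at 1 − ``alpha`` (df = effective rank of the
    covariance). Rows exceeding the quantile are flagged. The clr
    constraint (columns summing to zero) makes the full 6-column covariance
    singular; callers normally pass a matrix with one coordinate dropped
    (see :func:`clr_matrix`), but a pseudo-inverse fallback keeps degenerate
    inputs from crashing.

    Returns a boolean mask of retained rows and a report.
    """
    clr = np.asarray(clr, dtype=float)
    n, d = clr.shape
    if n < d + 1:
        raise ValueError(f"need at least {d + 1} rows for a {d}-column covariance")
    centred = clr - clr.mean(axis=0)
    cov = np.cov(centred, rowvar=False)
    rank = int(np.linalg.matrix_rank(cov))
    singular = rank < d
    if singular:
        prec = np.linalg.pinv(cov)
        dof = max(rank, 1)
    else:
        prec = np.linalg.inv(cov)
        dof = d
    d2 = np.einsum("ij,jk,ik->i", centred, prec, centred)
    cutoff = float(stats.chi2.ppf(1.0 - alpha, df=dof))
    keep = d2 <= cutoff
    report = OutlierReport(
        n_input=n, n_flagged=int((~keep).sum()), alpha=alpha,
        df=dof, cutoff=cutoff, singular_covariance=singular,
    )
    return keep, report


def preprocess(
    path: str | Path,
    outdir: str | Path | None = None,
    schema: Mapping[str, str] | None = None,
    nutrient_unit: str = "fraction",
    percentile: float = 65.0,
    alpha: float = 0.01,
    drop_part: str = "Fv",
) -> dict:
    """Run the full preprocessing chain on a survey CSV.

    Read → filter → compositions → per-cultivar yield discretization →
    clr-space outlier screening (on the high-yield subset, which feeds the
    clustering and the reference bank). When ``outdir`` is given, writes
    ``processed.csv``, ``cutoffs.csv`` and ``reports.json`` there.

    Returns a dict with the processed frame and all reports.
    """
    data, rejects = read_ionome_table(path, schema, nutrient_unit)
    filtered, filter_report = filter_records(data)
    composed, unusable = add_compositions(filtered)
    labelled, cutoffs = discretize_yield(composed, percentile)

    high = labelled.loc[labelled["yield_class"] == "high"]
    keep_mask, outlier_report = remove_outliers(
        clr_matrix(high, drop_part=drop_part), alpha=alpha)
    outlier_idx = high.index[~keep_mask]
    processed = labelled.drop(index=outlier_idx).reset_index(drop=True)

    result = {
        "processed": processed,
        "cutoffs": cutoffs,
        "rejects": rejects,
        "unusable": unusable,
        "filter_report": filter_report,
        "outlier_report": outlier_report,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        processed.to_csv(outdir / "processed.csv", index=False)
        cutoffs.to_csv(outdir / "cutoffs.csv", index=False)
        with open(outdir / "reports.json", "w") as fh:
            json.dump({
                "filter": filter_report.asdict(),
                "outliers": outlier_report.asdict(),
                "n_rejected_rows": len(rejects),
                "n_unusable_compositions": len(unusable),
            }, fh, indent=2)
    return result
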