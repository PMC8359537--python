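"""Cohort data model, delimited-text I/O and pre-analysis screening.

A cohort is one row per subject with an opaque id, age, daily energy
intake, a single biallelic SNP genotype (AA/AG/GG) and the metabolic /
body-composition measurements the downstream scoring needs.  This module
reads and validates such tables, writes them back, screens variables for
normality (Kolmogorov-Smirnov, advisory only) and removes univariate
z-score outliers in a single non-iterative pass.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.diagnostic import lilliefors

from .exceptions import (
    ConfigurationError,
    DegenerateDataError,
    InputError,
    ValidationError,
)
from .genetics import GENOTYPES

MANDATORY_COLUMNS: Tuple[str, ...] = (
    "subject_id",
    "age",
    "energy_intake",
    "genotype",
    "sbp",
    "dbp",
    "wc",
    "fbs",
    "hdl",
    "tg",
    "vfl",
    "tbf",
)
OPTIONAL_COLUMNS: Tuple[str, ...] = ("bmi", "weight", "height", "whr", "ffm", "smm", "bf_pct")

#: columns that must be strictly positive when present
POSITIVE_COLUMNS: Tuple[str, ...] = (
    "age",
    "sbp",
    "dbp",
    "wc",
    "fbs",
    "hdl",
    "tg",
    "vfl",
    "tbf",
) + OPTIONAL_COLUMNS

NUMERIC_COLUMNS: Tuple[str, ...] = tuple(
    c for c in MANDATORY_COLUMNS + OPTIONAL_COLUMNS if c not in ("subject_id", "genotype")
)

#: default header aliases (applied after lower-casing and ``[ -]`` -> ``_``)
DEFAULT_COLUMN_ALIASES: Dict[str, str] = {
    "id": "subject_id",
    "subject": "subject_id",
    "hdl_c": "hdl",
    "hdlc": "hdl",
    "tgs": "tg",
    "triglycerides": "tg",
    "energy": "energy_intake",
    "kcal": "energy_intake",
    "bfm": "tbf",
    "body_fat_mass": "tbf",
    "fbg": "fbs",
    "glucose": "fbs",
    "bf%": "bf_pct",
    "%bf": "bf_pct",
    "waist": "wc",
    "visceral_fat_level": "vfl",
    "snp": "genotype",
    "rs3807992": "genotype",
}

#: default genotype-label aliases (applied after upper-casing)
DEFAULT_GENOTYPE_ALIASES: Dict[str, str] = {"GA": "AG"}


@dataclass(frozen=True)
class SubjectRecord:
    """One validated subject row."""

    subject_id: str
    age: float
    energy_intake: float
    genotype: str
    sbp: float
    dbp: float
    wc: float
    fbs: float
    hdl: float
    tg: float
    vfl: float
    tbf: float
    extras: dict = field(default_factory=dict)


@dataclass(frozen=True)
class RowError:
    """Row-level rejection diagnostic emitted by :func:`read_cohort`."""

    row: int
    subject_id: Optional[str]
    reason: str


@dataclass(frozen=True)
class CohortTable:
    """An ordered, validated collection of subject rows.

    ``df`` holds one row per subject with at least the mandatory columns;
    unknown extra columns are carried through untouched.
    """

    df: pd.DataFrame
    provenance: str = "in-memory"
    row_errors: Tuple[RowError, ...] = ()

    def __post_init__(self) -> None:
        ids = self.df["subject_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique().tolist())
            raise ValidationError(f"duplicate subject_id values: {dupes[:5]}")

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def records(self) -> Tuple[SubjectRecord, ...]:
        base = set(MANDATORY_COLUMNS)
        out = []
        for _, row in self.df.iterrows():
            extras = {c: row[c] for c in self.df.columns if c not in base}
            out.append(
                SubjectRecord(
                    subject_id=str(row["subject_id"]),
                    age=float(row["age"]),
                    energy_intake=float(row["energy_intake"]),
                    genotype=str(row["genotype"]),
                    sbp=float(row["sbp"]),
                    dbp=float(row["dbp"]),
                    wc=float(row["wc"]),
                    fbs=float(row["fbs"]),
                    hdl=float(row["hdl"]),
                    tg=float(row["tg"]),
                    vfl=float(row["vfl"]),
                    tbf=float(row["tbf"]),
                    extras=extras,
                )
            )
        return tuple(out)


@dataclass
class ValidationReport:
    """Accounting of a screening or filtering step.

    Always satisfies ``n_retained = n_read - len(removed)``.
    """

    n_read: int
    n_retained: int
    missingness: Dict[str, int] = field(default_factory=dict)
    normality: Dict[str, dict] = field(default_factory=dict)
    removed: List[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_retained != self.n_read - len(self.removed):
            raise ValidationError("report accounting broken: retained != read - removed")

    def to_dict(self) -> dict:
        return {
            "n_read": self.n_read,
            "n_retained": self.n_retained,
            "missingness": self.missingness,
            "normality": self.normality,
            "removed": self.removed,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _normalize_header(name: str) -> str:
    return name.strip().lower().replace("-", "_").replace(" ", "_")


def _validate_frame(df: pd.DataFrame, genotype_aliases: Dict[str, str]) -> Tuple[pd.DataFrame, List[RowError]]:
    """Vectorized row validation; returns (valid rows, row-level errors)."""
    errors: List[RowError] = []
    df = df.copy()
    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        fresh = mask & (reasons == "")
        reasons[fresh] = reason

    # numeric coercion: non-null cells that fail to parse are row errors
    for col in NUMERIC_COLUMNS:
        if col not in df.columns:
            continue
        raw = df[col]
        coerced = pd.to_numeric(raw, errors="coerce")
        bad = raw.notna() & coerced.isna()
        flag(bad, f"unparseable numeric value in column '{col}'")
        df[col] = coerced.astype(float)

    # genotype normalization + membership
    geno = df["genotype"].astype(str).str.strip().str.upper().replace(genotype_aliases)
    df["genotype"] = geno
    flag(~geno.isin(GENOTYPES), "unknown genotype label")

    # missing mandatory cells
    for col in MANDATORY_COLUMNS:
        flag(df[col].isna() if col != "subject_id" else df[col].isna(), f"missing value in mandatory column '{col}'")

    # positivity (only on non-null cells)
    for col in POSITIVE_COLUMNS:
        if col in df.columns:
            flag(df[col].notna() & (df[col] <= 0), f"non-positive value in column '{col}'")

    flag(df["sbp"].notna() & df["dbp"].notna() & (df["sbp"] <= df["dbp"]), "sbp <= dbp")

    dup = df["subject_id"].duplicated(keep="first")
    flag(dup, "duplicate subject_id")

    bad_mask = reasons != ""
    for idx in df.index[bad_mask]:
        sid = df.at[idx, "subject_id"]
        errors.append(RowError(row=int(idx), subject_id=None if pd.isna(sid) else str(sid), reason=reasons[idx]))
    valid = df.loc[~bad_mask].reset_index(drop=True)
    valid["subject_id"] = valid["subject_id"].astype(str)
    return valid, errors


def read_cohort(
    path,
    delimiter: Optional[str] = None,
    column_aliases: Optional[Dict[str, str]] = None,
    genotype_aliases: Optional[Dict[str, str]] = None,
) -> CohortTable:
    """Read a delimited cohort table (comma default, tab accepted).

    Header names are matched case-insensitively through a configurable alias
    map; rows violating record invariants are rejected with row-level
    diagnostics available as ``CohortTable.row_errors``.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"cohort file not found: {path}")
    if path.stat().st_size == 0:
        raise InputError(f"cohort file is empty: {path}")
    try:
        if delimiter is None:
            df = pd.read_csv(path, sep=None, engine="python")
        else:
            df = pd.read_csv(path, sep=delimiter)
    except pd.errors.EmptyDataError:
        raise InputError(f"cohort file is empty: {path}") from None
    if df.empty:
        raise InputError(f"cohort file has a header but no rows: {path}")

    aliases = dict(DEFAULT_COLUMN_ALIASES)
    if column_aliases:
        aliases.update({_normalize_header(k): v for k, v in column_aliases.items()})
    renamed = {}
    for col in df.columns:
        norm = _normalize_header(str(col))
        renamed[col] = aliases.get(norm, norm)
    df = df.rename(columns=renamed)

    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing mandatory column(s): {missing}")

    g_aliases = dict(DEFAULT_GENOTYPE_ALIASES)
    if genotype_aliases:
        g_aliases.update({k.upper(): v for k, v in genotype_aliases.items()})

    valid, errors = _validate_frame(df, g_aliases)
    return CohortTable(df=valid, provenance=str(path), row_errors=tuple(errors))


def write_cohort(cohort: CohortTable, path, delimiter: str = ",") -> None:
    """Write a cohort back to delimited text (UTF-8, header row)."""
    cohort.df.to_csv(path, sep=delimiter, index=False)


def as_cohort(data, provenance: str = "in-memory") -> CohortTable:
    """Coerce a DataFrame (or pass through a CohortTable) without re-validation."""
    if isinstance(data, CohortTable):
        return data
    return CohortTable(df=pd.DataFrame(data).reset_index(drop=True), provenance=provenance)


def screen_normality(
    cohort: CohortTable,
    variables: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> ValidationReport:
    """Kolmogorov-Smirnov normality screening (advisory; removes nothing).

    For each variable the one-sample KS statistic against a normal with the
    sample's own mean/SD is reported together with a Lilliefors-corrected
    p-value (the naive KS p is anti-conservative when the parameters are
    estimated).  Zero-variance columns are flagged degenerate rather than
    tested.
    """
    cohort = as_cohort(cohort)
    if variables is None:
        variables = [c for c in NUMERIC_COLUMNS if c in cohort.df.columns]
    df = cohort.df
    for v in variables:
        if v not in df.columns:
            raise ConfigurationError(f"variable '{v}' not in cohort")
        if not pd.api.types.is_numeric_dtype(df[v]):
            raise ConfigurationError(f"variable '{v}' is not numeric")
    if cohort.n < 8:
        raise DegenerateDataError("insufficient sample for normality screening (n < 8)")

    normality: Dict[str, dict] = {}
    missingness: Dict[str, int] = {}
    for v in variables:
        vals = df[v].dropna().to_numpy(dtype=float)
        missingness[v] = int(df[v].isna().sum())
        if vals.size < 8:
            normality[v] = {"statistic": None, "p_value": None, "lilliefors_p": None,
                            "flag": "insufficient non-missing values"}
            continue
        sd = vals.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            normality[v] = {"statistic": None, "p_value": 0.0, "lilliefors_p": 0.0,
                            "flag": "degenerate (zero variance)"}
            continue
        stat, p = stats.kstest(vals, "norm", args=(vals.mean(), sd))
        _, lp = lilliefors(vals, dist="norm")
        flag = "non-normal" if lp < alpha else "ok"
        normality[v] = {"statistic": float(stat), "p_value": float(p),
                        "lilliefors_p": float(lp), "flag": flag}
    return ValidationReport(
        n_read=cohort.n, n_retained=cohort.n, missingness=missingness, normality=normality
    )


class ZScoreOutlierFilter(BaseEstimator, TransformerMixin):
    """Single-pass univariate z-score outlier filter.

    A subject is removed when ``|(x - mean) / SD| > z_threshold`` in ANY of
    the listed variables; means and SDs come from the data seen at
    :meth:`fit` and are NOT recomputed, so transforming the already-filtered
    cohort again removes nothing.

    Parameters
    ----------
    variables : sequence of str or None
        Columns to screen; ``None`` means every standard numeric column
        present at fit time.
    z_threshold : float, default 3.0
        Strictly positive cut-off on the absolute z-score.
    """

    def __init__(self, variables: Optional[Sequence[str]] = None, z_threshold: float = 3.0):
        self.variables = variables
        self.z_threshold = z_threshold

    def fit(self, X, y=None):
        if not (isinstance(self.z_threshold, (int, float)) and self.z_threshold > 0):
            raise ConfigurationError(f"z_threshold must be > 0, got {self.z_threshold!r}")
        cohort = as_cohort(X)
        df = cohort.df
        variables = self.variables
        if variables is None:
            variables = [c for c in NUMERIC_COLUMNS if c in df.columns]
        for v in variables:
            if v not in df.columns:
                raise ConfigurationError(f"variable '{v}' not in cohort")
        self.variables_ = list(variables)
        self.means_ = {}
        self.sds_ = {}
        for v in self.variables_:
            vals = df[v].dropna().to_numpy(dtype=float)
            sd = vals.std(ddof=1) if vals.size > 1 else 0.0
            if not math.isfinite(self.z_threshold):
                # vacuous filter: stats are irrelevant but kept well-defined
                sd = sd if sd > 0 else 1.0
            elif sd <= 0:
                raise DegenerateDataError(f"variable '{v}' has zero variance; cannot screen outliers")
            self.means_[v] = float(vals.mean())
            self.sds_[v] = float(sd)
        return self

    def transform(self, X) -> Tuple[CohortTable, ValidationReport]:
        cohort = as_cohort(X)
        df = cohort.df
        removed: List[dict] = []
        keep = pd.Series(True, index=df.index)
        for idx in df.index:
            offending = []
            for v in self.variables_:
                x = df.at[idx, v]
                if pd.isna(x):
                    continue
                z = (float(x) - self.means_[v]) / self.sds_[v]
                if abs(z) > self.z_threshold:
                    offending.append((v, z))
            if offending:
                keep[idx] = False
                removed.append(
                    {
                        "subject_id": str(df.at[idx, "subject_id"]),
                        "reason": "; ".join(f"|z({v})| = {abs(z):.2f} > {self.z_threshold}" for v, z in offending),
                        "variables": [v for v, _ in offending],
                    }
                )
        out = CohortTable(
            df=df.loc[keep].reset_index(drop=True),
            provenance=cohort.provenance,
            row_errors=cohort.row_errors,
        )
        report = ValidationReport(n_read=len(df), n_retained=int(keep.sum()), removed=removed)
        self.report_ = report
        return out, report


def remove_outliers(
    cohort: CohortTable,
    variables: Optional[Sequence[str]] = None,
    z_threshold: float = 3.0,
) -> Tuple[CohortTable, ValidationReport]:
    """One-pass z-score outlier removal (fit and filter on the same cohort)."""
    filt = ZScoreOutlierFilter(variables=variables, z_threshold=z_threshold)
    return filt.fit(cohort).transform(cohort)
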