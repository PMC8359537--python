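"""Genotype-group descriptive tables and hypothesis tests.

Reproduces the shape of the usual cohort-paper tables: per-variable means
and SDs under three genotype groupings (codominant: AA/AG/GG; dominant:
carriers vs GG; recessive: AA vs AG+GG), with a crude test (one-way ANOVA
for three groups, Student's t for two) and an age-adjusted ANCOVA p-value
per row.  P-values are reported unadjusted for multiplicity, with an
optional Benjamini-Hochberg column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cmets import CMetSResult, Z_COLUMNS
from .exceptions import CollinearDesignError, ConfigurationError, DegenerateDataError
from .genetics import encode_genotypes
from .io_model import as_cohort

#: default body-composition / baseline variables for the Table-1-like summary
BASELINE_VARIABLES = ("age", "bmi", "wc", "whr", "tbf", "ffm", "smm", "bf_pct", "vfl")

GROUPINGS = ("codominant", "dominant", "recessive")


def anova_oneway(values, groups) -> Tuple[float, float]:
    """Classic one-way fixed-effects ANOVA; returns (F, p)."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    samples = [v[g == level] for level in pd.unique(g)]
    samples = [s for s in samples if s.size > 0]
    if len(samples) < 2:
        raise DegenerateDataError("ANOVA needs at least 2 non-empty groups")
    if all(s.std(ddof=0) == 0 for s in samples):
        raise DegenerateDataError("zero within-group variance everywhere")
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)


def t_test_two_group(values, groups, welch: bool = False) -> Tuple[float, float]:
    """Two-sided independent-samples t-test (pooled variance by default)."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    levels = np.unique(g)  # deterministic order: swapping labels flips t's sign
    if len(levels) != 2:
        raise DegenerateDataError(f"t-test needs exactly 2 groups, got {len(levels)}")
    s1, s2 = v[g == levels[0]], v[g == levels[1]]
    if min(s1.size, s2.size) < 2:
        raise DegenerateDataError("each group needs at least 2 observations")
    if s1.std(ddof=1) == 0 and s2.std(ddof=1) == 0:
        if np.allclose(s1.mean(), s2.mean()):
            return 0.0, 1.0
        raise DegenerateDataError("degenerate groups with zero variance")
    t, p = stats.ttest_ind(s1, s2, equal_var=not welch)
    return float(t), float(p)


def ancova_adjusted_p(values, groups, covariates) -> float:
    """Group effect tested in a linear model with covariates (partial F).

    Fits value ~ group dummies + covariates against value ~ covariates and
    returns the partial-F p-value for the group term.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    n = v.size
    sds = cov.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        raise CollinearDesignError(f"zero-variance covariate column(s): {np.flatnonzero(sds <= 0).tolist()}")
    cov = (cov - cov.mean(axis=0)) / sds

    levels = pd.unique(g)
    if len(levels) < 2:
        raise DegenerateDataError("ANCOVA needs at least 2 groups")
    dummies = np.column_stack([(g == lev).astype(float) for lev in levels[1:]])
    X_full = np.column_stack([np.ones(n), dummies, cov])
    X_red = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise CollinearDesignError("collinear design in ANCOVA (group dummies vs covariates)")

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, v, rcond=None)
        r = v - X @ beta
        return float(r @ r)

    rss_full, rss_red = rss(X_full), rss(X_red)
    df_num = dummies.shape[1]
    df_den = n - X_full.shape[1]
    if df_den <= 0:
        raise DegenerateDataError("not enough observations for ANCOVA")
    f = ((rss_red - rss_full) / df_num) / (rss_full / df_den)
    return float(stats.f.sf(f, df_num, df_den))


@dataclass
class GroupSummaryTable:
    """Per-variable, per-grouping summary: group means/SDs, ns and p-values."""

    frame: pd.DataFrame
    groupings: Tuple[str, ...] = GROUPINGS

    def to_text(self) -> str:
        return self.frame.to_string(index=False, float_format=lambda v: f"{v:.4g}")

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.frame.to_dict(orient="records"), **kwargs)


def _group_labels(genotypes: np.ndarray, scheme: str, risk_allele: str) -> np.ndarray:
    codes = encode_genotypes(genotypes, scheme, risk_allele)
    if scheme == "codominant":
        return genotypes.astype(str)
    if scheme == "dominant":
        return np.where(codes == 1, "carrier", "non-carrier")
    return np.where(codes == 1, "risk-hom", "other")


def build_tables(
    cohort,
    cmets: Optional[CMetSResult] = None,
    variables: Optional[Sequence[str]] = None,
    covariates: Sequence[str] = ("age",),
    risk_allele: str = "A",
    bh_adjust: bool = False,
) -> Dict[str, GroupSummaryTable]:
    """Summary tables by genotype grouping, crude and age-adjusted.

    Returns ``{"baseline": ..., "cmets": ...}``; the cmets table is present
    only when a scored :class:`~cmetspipe.cmets.CMetSResult` is supplied.
    Each variable is summarized under all three groupings on its complete
    cases.
    """
    cohort = as_cohort(cohort)
    df = cohort.df
    out: Dict[str, GroupSummaryTable] = {}

    if variables is None:
        variables = [v for v in BASELINE_VARIABLES if v in df.columns]

    def summarize(frame: pd.DataFrame, var_list: Sequence[str]) -> GroupSummaryTable:
        rows: List[dict] = []
        for var in var_list:
            if var not in frame.columns:
                raise ConfigurationError(f"variable '{var}' not in table")
            sub = frame.dropna(subset=[var] + [c for c in covariates if c != var])
            values = sub[var].to_numpy(dtype=float)
            genos = sub["genotype"].to_numpy(dtype=object)
            cov = sub[[c for c in covariates if c != var]].to_numpy(dtype=float)
            for scheme in GROUPINGS:
                labels = _group_labels(genos, scheme, risk_allele)
                row = {"variable": var, "grouping": scheme}
                for lev in pd.unique(labels):
                    sel = values[labels == lev]
                    row[f"mean[{lev}]"] = float(sel.mean())
                    row[f"sd[{lev}]"] = float(sel.std(ddof=1)) if sel.size > 1 else float("nan")
                    row[f"n[{lev}]"] = int(sel.size)
                try:
                    if scheme == "codominant":
                        stat, p = anova_oneway(values, labels)
                        row["test"] = "one-way ANOVA"
                    else:
                        stat, p = t_test_two_group(values, labels)
                        row["test"] = "Student t"
                    row["statistic"] = stat
                    row["p_crude"] = p
                    row["p_adjusted"] = (
                        ancova_adjusted_p(values, labels, cov) if cov.shape[1] else float("nan")
                    )
                except DegenerateDataError as exc:
                    row["test"] = f"skipped ({exc})"
                    row["statistic"] = row["p_crude"] = row["p_adjusted"] = float("nan")
                rows.append(row)
        table = pd.DataFrame(rows)
        if bh_adjust and "p_crude" in table:
            mask = table["p_crude"].notna()
            adj = np.full(len(table), np.nan)
            if mask.any():
                adj[mask.to_numpy()] = multipletests(table.loc[mask, "p_crude"], method="fdr_bh")[1]
            table["p_bh"] = adj
        return GroupSummaryTable(frame=table)

    out["baseline"] = summarize(df, list(variables))

    if cmets is not None:
        scored = df.merge(cmets.frame, on="subject_id", how="inner")
        out["cmets"] = summarize(scored, list(Z_COLUMNS))
    return out
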