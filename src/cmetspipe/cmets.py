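"""Continuous metabolic-syndrome severity (cMetS) score.

The score is the sum of five age-adjusted standardized residuals: for each
component (waist circumference, mean arterial pressure, fasting blood
sugar, HDL cholesterol, triglycerides) the component is regressed on age by
ordinary least squares, the residual is divided by a scale (the residual
sample SD by default) and, because higher HDL means LOWER risk, the HDL
z-score is multiplied by -1 after standardization.  Mean arterial pressure
is derived from the measured pressures as ``(SBP - DBP)/3 + DBP``.

On the cohort the transformation was fitted on, every unflipped component
z-score has exactly zero mean and zero correlation with age, and the total
is exactly the sum of the five components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ConfigurationError, DegenerateDataError, ValidationError
from .io_model import CohortTable, as_cohort

#: the five score components, in reporting order
COMPONENTS = ("wc", "map", "fbs", "hdl", "tg")
#: raw columns the scorer needs
REQUIRED_COLUMNS = ("age", "wc", "sbp", "dbp", "fbs", "hdl", "tg")
#: component -> sign applied AFTER standardization
COMPONENT_SIGNS = {"wc": 1.0, "map": 1.0, "fbs": 1.0, "hdl": -1.0, "tg": 1.0}

Z_COLUMNS = ("z_wc", "z_map", "z_fbs", "z_hdl", "z_tg", "z_total")


def mean_arterial_pressure(sbp, dbp):
    """Mean arterial pressure in mmHg: ``(SBP - DBP)/3 + DBP``.

    Accepts scalars or arrays; requires ``sbp > dbp > 0`` elementwise.
    """
    sbp_arr = np.asarray(sbp, dtype=float)
    dbp_arr = np.asarray(dbp, dtype=float)
    if np.any(dbp_arr <= 0):
        raise ValidationError("dbp must be strictly positive")
    if np.any(sbp_arr <= dbp_arr):
        raise ValidationError("sbp must exceed dbp for every subject")
    out = (sbp_arr - dbp_arr) / 3.0 + dbp_arr
    return float(out) if np.isscalar(sbp) and np.isscalar(dbp) else out


@dataclass(frozen=True)
class ComponentFit:
    """Fitted age-regression for one component: value ~ intercept + slope*age."""

    slope: float
    intercept: float
    resid_sd: float
    scale: float  # divisor actually applied to the residuals
    sign: float


def age_adjusted_z(values, age, standardize_by: str = "residual_sd"):
    """Age-adjusted standardized residuals of one component.

    OLS of ``values`` on ``age`` (intercept + slope); residuals are divided
    by the residual sample SD (``n-1`` denominator), or by the raw
    component SD when ``standardize_by='component_sd'``.

    Returns ``(z, ComponentFit)``.  Raises :class:`DegenerateDataError` when
    either input has (residual) zero variance.
    """
    v = np.asarray(values, dtype=float)
    a = np.asarray(age, dtype=float)
    if v.shape != a.shape or v.ndim != 1:
        raise ConfigurationError("values and age must be 1-D vectors of equal length")
    n = v.size
    if n < 3:
        raise DegenerateDataError("need at least 3 subjects for age adjustment")
    if standardize_by not in ("residual_sd", "component_sd"):
        raise ConfigurationError(f"unknown standardize_by {standardize_by!r}")

    a_c = a - a.mean()
    var_age = float(a_c @ a_c)
    if var_age <= 0:
        raise DegenerateDataError("age has zero variance")
    v_sd = v.std(ddof=1)
    if v_sd <= 0:
        raise DegenerateDataError("degenerate component (zero variance)")

    slope = float((a_c @ (v - v.mean())) / var_age)
    intercept = float(v.mean() - slope * a.mean())
    resid = v - (intercept + slope * a)
    resid_sd = float(resid.std(ddof=1))
    if resid_sd <= v_sd * 1e-12:
        raise DegenerateDataError("degenerate component (zero residual variance)")
    scale = resid_sd if standardize_by == "residual_sd" else float(v_sd)
    fit = ComponentFit(slope=slope, intercept=intercept, resid_sd=resid_sd, scale=scale, sign=1.0)
    return resid / scale, fit


@dataclass
class CMetSResult:
    """Per-subject z components plus the fitted cohort-level transformation."""

    frame: pd.DataFrame  # subject_id + z_wc ... z_total
    fits: Dict[str, ComponentFit]
    standardize_by: str
    n_used: int

    def to_dict(self) -> dict:
        return {
            "standardize_by": self.standardize_by,
            "n_used": self.n_used,
            "fits": {
                k: {"slope": f.slope, "intercept": f.intercept,
                    "resid_sd": f.resid_sd, "scale": f.scale, "sign": f.sign}
                for k, f in self.fits.items()
            },
        }


class CMetSScorer(BaseEstimator, TransformerMixin):
    """Fit the age-adjusted cMetS transformation on a cohort and apply it.

    ``fit`` learns, per component, the OLS age-regression and residual
    scale; ``transform`` appends ``z_wc, z_map, z_fbs, z_hdl, z_tg,
    z_total`` to a copy of the input table.  Held-out subjects can be
    scored against the fitting cohort's transformation.

    Parameters
    ----------
    standardize_by : {'residual_sd', 'component_sd'}
        Scale for the residuals.  The default makes every component exactly
        mean-0 / SD-1 on the fitting cohort.
    """

    def __init__(self, standardize_by: str = "residual_sd"):
        self.standardize_by = standardize_by

    def _component_values(self, df: pd.DataFrame) -> Dict[str, np.ndarray]:
        values = {
            "wc": df["wc"].to_numpy(dtype=float),
            "map": mean_arterial_pressure(df["sbp"].to_numpy(dtype=float), df["dbp"].to_numpy(dtype=float)),
            "fbs": df["fbs"].to_numpy(dtype=float),
            "hdl": df["hdl"].to_numpy(dtype=float),
            "tg": df["tg"].to_numpy(dtype=float),
        }
        return values

    def fit(self, X, y=None):
        cohort = as_cohort(X)
        missing = [c for c in REQUIRED_COLUMNS if c not in cohort.df.columns]
        if missing:
            raise ConfigurationError(f"missing component column(s): {missing}")
        df = cohort.df.dropna(subset=list(REQUIRED_COLUMNS))
        if len(df) < 10:
            raise DegenerateDataError(f"need at least 10 complete subjects to fit cMetS, got {len(df)}")
        age = df["age"].to_numpy(dtype=float)
        fits: Dict[str, ComponentFit] = {}
        for comp, vals in self._component_values(df).items():
            _, fit = age_adjusted_z(vals, age, standardize_by=self.standardize_by)
            fits[comp] = ComponentFit(
                slope=fit.slope, intercept=fit.intercept, resid_sd=fit.resid_sd,
                scale=fit.scale, sign=COMPONENT_SIGNS[comp],
            )
        self.fits_ = fits
        self.n_fit_ = len(df)
        return self

    def transform(self, X) -> pd.DataFrame:
        cohort = as_cohort(X)
        df = cohort.df.copy()
        age = df["age"].to_numpy(dtype=float)
        values = self._component_values(df)
        total = np.zeros(len(df))
        for comp in COMPONENTS:
            f = self.fits_[comp]
            z = f.sign * (values[comp] - (f.intercept + f.slope * age)) / f.scale
            df[f"z_{comp}"] = z
            total = total + z
        df["z_total"] = total
        return df

    def score_result(self, X) -> CMetSResult:
        """Transform and package as a :class:`CMetSResult`."""
        scored = self.transform(X)
        cols = ["subject_id"] + list(Z_COLUMNS) if "subject_id" in scored.columns else list(Z_COLUMNS)
        return CMetSResult(
            frame=scored[cols].copy(),
            fits=dict(self.fits_),
            standardize_by=self.standardize_by,
            n_used=self.n_fit_,
        )


def cmets_score(cohort: CohortTable, standardize_by: str = "residual_sd") -> CMetSResult:
    """Fit and apply the cMetS transformation on one cohort.

    Subjects with a missing component value are excluded from both the fit
    and the returned result (complete-case analysis).
    """
    cohort = as_cohort(cohort)
    df = cohort.df.dropna(subset=[c for c in REQUIRED_COLUMNS if c in cohort.df.columns]).reset_index(drop=True)
    complete = CohortTable(df=df, provenance=cohort.provenance)
    scorer = CMetSScorer(standardize_by=standardize_by).fit(complete)
    return scorer.score_result(complete)
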