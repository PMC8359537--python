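"""Single-mediator path analysis with bootstrap confidence intervals.

Classic three-regression mediation (Baron & Kenny / Hayes model 4) for a
binary or numeric exposure X, one mediator M, an outcome Y and optional
covariates C:

* ``a``  — coefficient of X in OLS of M on (1, X, C)
* ``b``, ``c'`` — coefficients of M and X in OLS of Y on (1, X, M, C)
* ``c``  — coefficient of X in OLS of Y on (1, X, C)

The specific indirect effect is ``a*b`` and, because all three fits are OLS
with identical covariate sets, the decomposition ``c = c' + a*b`` holds to
machine precision.  Significance of the indirect effect is judged by a
case-resampling bootstrap: percentile intervals or bias-corrected (BC)
intervals whose quantile positions are shifted by
``z0 = Phi^-1(fraction of bootstrap estimates below the point estimate)``.

The reported scale follows the partial-standardization convention common
for a binary exposure: mediator and outcome are z-scored, the exposure
stays on its 0/1 coding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .cmets import cmets_score
from .exceptions import (
    CollinearDesignError,
    ConfigurationError,
    DegenerateDataError,
    UnstableBootstrapError,
)
from .genetics import encode_genotypes
from .io_model import as_cohort

_RCOND = 1e-10  # eigenvalue-ratio threshold below which a design is singular


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class PathEstimates:
    """OLS path coefficients for one single-mediator model."""

    a: float
    b: float
    c: float
    c_prime: float
    standardized: bool = False
    covariate_names: Tuple[str, ...] = ()
    n: int = 0

    @property
    def indirect(self) -> float:
        return self.a * self.b


@dataclass(frozen=True)
class BootstrapCI:
    """Bootstrap confidence interval for the indirect effect."""

    lower: float
    upper: float
    level: float = 0.95
    n_boot: int = 5000
    method: str = "bias_corrected"
    seed: Optional[int] = None
    n_degenerate: int = 0
    z0: Optional[float] = None

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("bootstrap CI has lower > upper")

    @property
    def significant(self) -> bool:
        return self.lower > 0 or self.upper < 0


@dataclass(frozen=True)
class ProportionMediated:
    """indirect / total effect, with a validity status.

    ``status`` is ``'ok'`` when the proportion is a meaningful fraction,
    ``'undefined'`` when the total effect is ~0, and ``'inconsistent'``
    when indirect and total effects have opposite signs (value outside
    [0, 1]).
    """

    value: Optional[float]
    status: str


@dataclass(frozen=True)
class MediationResult:
    """Full output of one single-mediator analysis."""

    paths: PathEstimates            # raw scale
    paths_std: PathEstimates        # partially standardized scale
    ci: BootstrapCI                 # CI for the (standardized) indirect effect
    proportion: ProportionMediated
    mediator: str
    outcome: str
    exposure: str = "genotype"
    coding: str = "dominant"
    n_used: int = 0

    def to_dict(self) -> dict:
        return {
            "mediator": self.mediator,
            "outcome": self.outcome,
            "exposure": self.exposure,
            "coding": self.coding,
            "n_used": self.n_used,
            "paths_raw": {"a": self.paths.a, "b": self.paths.b, "c": self.paths.c,
                          "c_prime": self.paths.c_prime, "indirect": self.paths.indirect},
            "paths_standardized": {"a": self.paths_std.a, "b": self.paths_std.b,
                                   "c": self.paths_std.c, "c_prime": self.paths_std.c_prime,
                                   "indirect": self.paths_std.indirect},
            "indirect_ci": {"lower": self.ci.lower, "upper": self.ci.upper,
                            "level": self.ci.level, "n_boot": self.ci.n_boot,
                            "method": self.ci.method, "significant": self.ci.significant},
            "proportion_mediated": {"value": self.proportion.value, "status": self.proportion.status},
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def summary(self) -> str:
        """Text path-diagram summary in the usual a/b/c/c' annotation."""
        p, s, ci = self.paths, self.paths_std, self.ci
        star = "significant" if ci.significant else "not significant"
        prop = ("undefined" if self.proportion.value is None
                else f"{100 * self.proportion.value:.1f}% ({self.proportion.status})")
        return "\n".join([
            f"Single-mediator model: {self.exposure} ({self.coding}) -> {self.mediator} -> {self.outcome}",
            f"  n = {self.n_used}",
            f"  a  (X -> M)            : {p.a:+.4f}   [std {s.a:+.4f}]",
            f"  b  (M -> Y | X)        : {p.b:+.4f}   [std {s.b:+.4f}]",
            f"  c  (total effect)      : {p.c:+.4f}   [std {s.c:+.4f}]",
            f"  c' (direct effect)     : {p.c_prime:+.4f}   [std {s.c_prime:+.4f}]",
            f"  a*b (indirect, std)    : {s.indirect:+.4f}  "
            f"{ci.level:.0%} {ci.method} CI [{ci.lower:+.4f}, {ci.upper:+.4f}]  -> {star}",
            f"  proportion mediated    : {prop}",
        ])


# ---------------------------------------------------------------------------
# core numerics


def _as_matrix(covariates, n: int) -> Optional[np.ndarray]:
    if covariates is None:
        return None
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if cov.shape[0] != n:
        raise ConfigurationError("covariate matrix row count does not match data length")
    return cov


def _scale_covariates(cov: Optional[np.ndarray], names: Sequence[str]) -> Optional[np.ndarray]:
    """Z-score covariate columns for conditioning; coefficients on X and M
    are unchanged by affine transforms of the covariates."""
    if cov is None:
        return None
    sd = cov.std(axis=0, ddof=1)
    bad = [names[j] if j < len(names) else f"cov{j}" for j in np.flatnonzero(sd <= 0)]
    if bad:
        raise CollinearDesignError(f"zero-variance covariate column(s): {bad}")
    return (cov - cov.mean(axis=0)) / sd


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # point at the columns loading on the null space
        _, _, vt = np.linalg.svd(X, full_matrices=False)
        loadings = np.abs(vt[-1])
        offending = [names[j] for j in np.flatnonzero(loadings > 0.3) if j < len(names)]
        raise CollinearDesignError(f"collinear design; offending column(s): {offending or names}")


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(X, y, rcond=None)[0]


def fit_paths(
    exposure,
    mediator,
    outcome,
    covariates=None,
    covariate_names: Sequence[str] = (),
    standardized: bool = False,
) -> PathEstimates:
    """Estimate a, b, c and c' by three OLS fits with a shared covariate set."""
    x = np.asarray(exposure, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n = x.size
    if not (m.size == n and y.size == n):
        raise ConfigurationError("exposure, mediator and outcome must have equal length")
    cov = _as_matrix(covariates, n)
    k = 0 if cov is None else cov.shape[1]
    if n <= k + 3:
        raise DegenerateDataError(f"n={n} too small for mediation with {k} covariate(s)")
    names = list(covariate_names) or [f"cov{j}" for j in range(k)]
    cov = _scale_covariates(cov, names)

    ones = np.ones(n)
    cols_a = [ones, x] + ([cov[:, j] for j in range(k)] if cov is not None else [])
    Xa = np.column_stack(cols_a)
    _check_rank(Xa, ["intercept", "exposure"] + names)
    cols_b = [ones, x, m] + ([cov[:, j] for j in range(k)] if cov is not None else [])
    Xb = np.column_stack(cols_b)
    _check_rank(Xb, ["intercept", "exposure", "mediator"] + names)

    a = float(_ols(Xa, m)[1])
    beta_b = _ols(Xb, y)
    c_prime, b = float(beta_b[1]), float(beta_b[2])
    c = float(_ols(Xa, y)[1])
    return PathEstimates(a=a, b=b, c=c, c_prime=c_prime, standardized=standardized,
                         covariate_names=tuple(names), n=n)


def standardize_for_paths(exposure, mediator, outcome, covariates=None):
    """Partial standardization: M and Y z-scored, exposure left as-is.

    Returns ``(x, m_z, y_z, covariates)``; raises on zero variance.
    """
    x = np.asarray(exposure, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(outcome, dtype=float)

    def _z(v, label):
        sd = v.std(ddof=1)
        if sd <= 0:
            raise DegenerateDataError(f"zero variance in {label}; cannot standardize")
        return (v - v.mean()) / sd

    return x, _z(m, "mediator"), _z(y, "outcome"), covariates


def standardize_paths(paths: PathEstimates, sd_mediator: float, sd_outcome: float) -> PathEstimates:
    """Convert raw path estimates to the partially standardized scale."""
    if sd_mediator <= 0 or sd_outcome <= 0:
        raise DegenerateDataError("standard deviations must be positive")
    return PathEstimates(
        a=paths.a / sd_mediator,
        b=paths.b * sd_mediator / sd_outcome,
        c=paths.c / sd_outcome,
        c_prime=paths.c_prime / sd_outcome,
        standardized=True,
        covariate_names=paths.covariate_names,
        n=paths.n,
    )


def _batched_coef(X: np.ndarray, y: np.ndarray, coef_index: int):
    """Batched OLS coefficient extraction with singularity detection.

    ``X``: (B, n, p); ``y``: (B, n).  Returns (coef, ok_mask).
    """
    XtX = np.einsum("bni,bnj->bij", X, X)
    Xty = np.einsum("bni,bn->bi", X, y)
    w = np.linalg.eigvalsh(XtX)
    ok = (w[:, 0] > w[:, -1] * _RCOND) & (w[:, -1] > 0)
    coef = np.full(X.shape[0], np.nan)
    if ok.any():
        beta = np.linalg.solve(XtX[ok], Xty[ok][..., None])[..., 0]
        coef[ok] = beta[:, coef_index]
    return coef, ok


def _bootstrap_draws(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    cov: Optional[np.ndarray],
    n_boot: int,
    rng: np.random.Generator,
    standardized: bool,
    max_degenerate_frac: float = 0.1,
    chunk: int = 1024,
) -> Tuple[np.ndarray, int]:
    """Case-resampling bootstrap distribution of the indirect effect."""
    n = x.size
    k = 0 if cov is None else cov.shape[1]
    draws = np.empty(n_boot)
    filled = 0
    n_degenerate = 0
    max_degenerate = int(max_degenerate_frac * n_boot)
    while filled < n_boot:
        bsz = min(chunk, n_boot - filled)
        idx = rng.integers(0, n, size=(bsz, n))
        xb, mb, yb = x[idx], m[idx], y[idx]
        ones = np.ones_like(xb)
        layers_a = [ones, xb]
        if cov is not None:
            covb = cov[idx]  # (bsz, n, k)
            layers_a += [covb[..., j] for j in range(k)]
        Xa = np.stack(layers_a, axis=-1)
        a, ok_a = _batched_coef(Xa, mb, 1)
        Xb = np.stack(layers_a[:2] + [mb] + layers_a[2:], axis=-1)
        b, ok_b = _batched_coef(Xb, yb, 2)
        ind = a * b
        if standardized:
            sd_y = yb.std(axis=1, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                ind = np.where(sd_y > 0, ind / sd_y, np.nan)
        ok = ok_a & ok_b & np.isfinite(ind)
        n_degenerate += int(bsz - ok.sum())
        if n_degenerate > max_degenerate:
            raise UnstableBootstrapError(
                f"more than {max_degenerate_frac:.0%} of bootstrap resamples were "
                "degenerate (quasi-separation or tiny n)"
            )
        good = ind[ok]
        draws[filled:filled + good.size] = good
        filled += good.size
    return draws, n_degenerate


def bootstrap_indirect(
    exposure,
    mediator,
    outcome,
    covariates=None,
    n_boot: int = 5000,
    level: float = 0.95,
    method: str = "bias_corrected",
    seed: Optional[Union[int, np.random.SeedSequence, np.random.Generator]] = None,
    standardized: bool = False,
) -> BootstrapCI:
    """Bootstrap CI for the specific indirect effect ``a*b``.

    Subjects (rows) are resampled with replacement ``n_boot`` times and the
    indirect effect is re-estimated on each resample; with
    ``standardized=True`` each resample's estimate is divided by that
    resample's outcome SD.  ``method='percentile'`` takes the plain
    empirical quantiles (linear interpolation between order statistics);
    ``'bias_corrected'`` shifts the quantile positions by the BC ``z0``
    term and reduces exactly to the percentile interval when ``z0 = 0``.
    Rank-deficient resamples are redrawn and counted; more than 10%
    degenerate draws raises :class:`UnstableBootstrapError`.
    """
    if n_boot < 200:
        raise ConfigurationError(f"n_boot must be >= 200, got {n_boot}")
    if not 0 < level < 1:
        raise ConfigurationError(f"level must be in (0, 1), got {level}")
    if method not in ("percentile", "bias_corrected"):
        raise ConfigurationError(f"unknown bootstrap method {method!r}")

    x = np.asarray(exposure, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(outcome, dtype=float)
    cov = _as_matrix(covariates, x.size)
    if cov is not None:
        cov = _scale_covariates(cov, [f"cov{j}" for j in range(cov.shape[1])])

    point_paths = fit_paths(x, m, y, cov)
    point = point_paths.indirect
    if standardized:
        point = point / y.std(ddof=1)

    if isinstance(seed, np.random.Generator):
        rng = seed
        seed_out = None
    else:
        rng = np.random.default_rng(seed)
        seed_out = seed if isinstance(seed, int) else None
    draws, n_degen = _bootstrap_draws(x, m, y, cov, n_boot, rng, standardized)

    if np.ptp(draws) == 0:
        # degenerate bootstrap distribution: interval collapses to the point
        return BootstrapCI(lower=float(draws[0]), upper=float(draws[0]), level=level,
                           n_boot=n_boot, method=method, seed=seed_out,
                           n_degenerate=n_degen, z0=0.0)

    alpha = 1.0 - level
    if method == "percentile":
        lo, hi = np.quantile(draws, [alpha / 2, 1 - alpha / 2])
        z0 = None
    else:
        prop_below = np.mean(draws < point)
        # guard the probit against empty/full tails
        prop_below = float(np.clip(prop_below, 1.0 / (n_boot + 1), n_boot / (n_boot + 1)))
        z0 = float(norm.ppf(prop_below))
        z_crit = norm.ppf(1 - alpha / 2)
        q_lo = float(norm.cdf(2 * z0 - z_crit))
        q_hi = float(norm.cdf(2 * z0 + z_crit))
        lo, hi = np.quantile(draws, [q_lo, q_hi])
    return BootstrapCI(lower=float(lo), upper=float(hi), level=level, n_boot=n_boot,
                       method=method, seed=seed_out, n_degenerate=n_degen, z0=z0)


def proportion_mediated(paths: PathEstimates, tol: float = 1e-8) -> ProportionMediated:
    """Proportion of the total effect carried by the mediator: ``a*b / c``.

    Undefined when ``|c|`` is below tolerance; flagged inconsistent when
    indirect and total effect have opposite signs (value outside [0, 1]).
    """
    if abs(paths.c) <= tol:
        return ProportionMediated(value=None, status="undefined: total effect ~ 0")
    value = paths.indirect / paths.c
    if paths.indirect != 0 and np.sign(paths.indirect) != np.sign(paths.c):
        return ProportionMediated(value=float(value), status="inconsistent mediation (proportion outside [0, 1])")
    return ProportionMediated(value=float(value), status="ok")


# ---------------------------------------------------------------------------
# estimator / orchestration


class SingleMediatorModel(BaseEstimator):
    """One exposure -> mediator -> outcome mediation model on a cohort table.

    ``fit`` encodes the genotype exposure, builds the outcome (computing the
    cMetS score when ``outcome='cmets_total'``), fits the three OLS path
    regressions on complete cases, bootstraps the indirect effect and
    derives the proportion mediated.  Fitted attributes follow sklearn
    conventions (``paths_``, ``ci_``, ``result_``...).

    Parameters
    ----------
    mediator : str
        Cohort column acting as the mediator (e.g. ``'vfl'`` or ``'tbf'``).
    outcome : str
        ``'cmets_total'`` (score computed on the fly) or any numeric column.
    coding : {'dominant', 'recessive', 'codominant'}
        Genotype coding of the exposure; dominant = risk-allele carriers vs
        non-carriers.
    covariates : sequence of str
        Confounders entered in all three regressions.
    n_boot, level, method, seed
        Bootstrap settings (see :func:`bootstrap_indirect`).
    standardized : bool
        Report the indirect-effect CI on the partially standardized scale.
    risk_allele : str
        Allele counted by the coding (default ``'A'``).
    """

    def __init__(
        self,
        mediator: str = "vfl",
        outcome: str = "cmets_total",
        exposure: str = "genotype",
        coding: str = "dominant",
        covariates: Sequence[str] = ("age", "energy_intake"),
        n_boot: int = 5000,
        level: float = 0.95,
        method: str = "bias_corrected",
        seed: Optional[int] = None,
        standardized: bool = True,
        risk_allele: str = "A",
    ):
        self.mediator = mediator
        self.outcome = outcome
        self.exposure = exposure
        self.coding = coding
        self.covariates = covariates
        self.n_boot = n_boot
        self.level = level
        self.method = method
        self.seed = seed
        self.standardized = standardized
        self.risk_allele = risk_allele

    def fit(self, X, y=None):
        cohort = as_cohort(X)
        covariates = list(self.covariates or ())
        if self.mediator in covariates:
            raise ConfigurationError(f"mediator '{self.mediator}' also listed as covariate")

        df = cohort.df
        needed = [self.exposure, self.mediator] + covariates
        if self.outcome != "cmets_total":
            needed.append(self.outcome)
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise ConfigurationError(f"missing column(s): {missing}")

        if self.outcome == "cmets_total":
            result = cmets_score(cohort)
            scored = result.frame.set_index("subject_id")["z_total"]
            df = df[df["subject_id"].isin(scored.index)].copy()
            df["cmets_total"] = scored.loc[df["subject_id"]].to_numpy()
        df = df.dropna(subset=[c for c in set(needed + [self.outcome]) if c in df.columns])

        x = encode_genotypes(df[self.exposure].to_numpy(), self.coding, self.risk_allele)
        m = df[self.mediator].to_numpy(dtype=float)
        yv = df[self.outcome].to_numpy(dtype=float)
        cov = df[covariates].to_numpy(dtype=float) if covariates else None

        paths = fit_paths(x, m, yv, cov, covariate_names=covariates)
        sd_m, sd_y = m.std(ddof=1), yv.std(ddof=1)
        paths_std = standardize_paths(paths, sd_m, sd_y)
        ci = bootstrap_indirect(
            x, m, yv, cov, n_boot=self.n_boot, level=self.level, method=self.method,
            seed=self._rng_source(), standardized=self.standardized,
        )
        prop = proportion_mediated(paths)
        self.paths_ = paths
        self.paths_std_ = paths_std
        self.ci_ = ci
        self.proportion_mediated_ = prop
        self.n_used_ = len(df)
        self.result_ = MediationResult(
            paths=paths, paths_std=paths_std, ci=ci, proportion=prop,
            mediator=self.mediator, outcome=self.outcome, exposure=self.exposure,
            coding=self.coding, n_used=len(df),
        )
        return self

    def _rng_source(self):
        if self.seed is None:
            return None
        if isinstance(self.seed, (np.random.SeedSequence, np.random.Generator)):
            return (self.seed if isinstance(self.seed, np.random.Generator)
                    else np.random.default_rng(self.seed))
        return int(self.seed)


def run_mediation(
    cohort,
    mediators: Union[str, Sequence[str]] = "vfl",
    outcome: str = "cmets_total",
    coding: str = "dominant",
    covariates: Sequence[str] = ("age", "energy_intake"),
    n_boot: int = 5000,
    level: float = 0.95,
    method: str = "bias_corrected",
    seed: Optional[int] = None,
    standardized: bool = True,
    risk_allele: str = "A",
) -> Union[MediationResult, list]:
    """Run one single-mediator model per requested mediator.

    A master seed spawns independent per-model random substreams, so adding
    a second mediator never perturbs the first model's interval.  Returns a
    single :class:`MediationResult` when ``mediators`` is a string, else a
    list in request order.
    """
    single = isinstance(mediators, str)
    med_list = [mediators] if single else list(mediators)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(med_list))
    results = []
    for med, child in zip(med_list, children):
        model = SingleMediatorModel(
            mediator=med, outcome=outcome, coding=coding, covariates=covariates,
            n_boot=n_boot, level=level, method=method,
            seed=np.random.default_rng(child), standardized=standardized,
            risk_allele=risk_allele,
        )
        model.fit(cohort)
        results.append(model.result_)
    return results[0] if single else results


def fit_parallel_paths(
    exposure,
    mediators: np.ndarray,
    outcome,
    covariates=None,
) -> list:
    """Joint parallel-mediator fit (sensitivity variant; point estimates only).

    All mediators enter one outcome regression; each mediator keeps its own
    exposure regression.  Returns one :class:`PathEstimates` per mediator
    column; ``c`` is shared, ``c_prime`` is the joint direct effect, and the
    per-mediator ``c = c' + sum_i a_i*b_i`` identity holds across the set.
    """
    x = np.asarray(exposure, dtype=float)
    M = np.asarray(mediators, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    y = np.asarray(outcome, dtype=float)
    n = x.size
    cov = _as_matrix(covariates, n)
    k = 0 if cov is None else cov.shape[1]
    if cov is not None:
        cov = _scale_covariates(cov, [f"cov{j}" for j in range(k)])
    ones = np.ones(n)
    base = [ones, x] + ([cov[:, j] for j in range(k)] if cov is not None else [])
    Xa = np.column_stack(base)
    Xb = np.column_stack(base[:2] + [M[:, i] for i in range(M.shape[1])] + base[2:])
    _check_rank(Xb, ["intercept", "exposure"] + [f"mediator{i}" for i in range(M.shape[1])])
    beta = _ols(Xb, y)
    c_prime = float(beta[1])
    c = float(_ols(Xa, y)[1])
    out = []
    for i in range(M.shape[1]):
        a_i = float(_ols(Xa, M[:, i])[1])
        b_i = float(beta[2 + i])
        out.append(PathEstimates(a=a_i, b=b_i, c=c, c_prime=c_prime, n=n))
    return out
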