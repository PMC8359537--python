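"""Seeded synthetic cohorts with known mediation ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, in an all-female overweight/obese cohort aged 18-55:

* genotypes at one biallelic SNP drawn in Hardy-Weinberg proportions at a
  configurable risk-allele frequency;
* two adiposity mediators (visceral fat level VFL, total body fat TBF)
  linear in the dominant genotype coding and age, with Gaussian noise;
* five metabolic components (WC, MAP, FBS, HDL, TG) linear in the
  mediators, the genotype, and age — HDL with negative mediator
  coefficients (inverse association);
* SBP/DBP constructed from the generated MAP and a positive pulse
  pressure so that ``(SBP-DBP)/3 + DBP`` reproduces MAP exactly.

Because everything is linear-Gaussian, the population path coefficients of
the genotype -> mediator -> cMetS chain have closed forms
(:func:`true_effects`), which is what estimator-recovery and CI-coverage
checks are measured against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .exceptions import ConfigurationError
from .io_model import CohortTable

_COMPONENT_NAMES = ("wc", "map", "fbs", "hdl", "tg")


@dataclass(frozen=True)
class MediatorSpec:
    """Linear model of one mediator: intercept + a*X + gamma_age*age + noise."""

    intercept: float
    a: float            # genotype (dominant coding) -> mediator effect
    gamma_age: float    # age slope, mediator units per year
    noise_sd: float


@dataclass(frozen=True)
class ComponentSpec:
    """Linear model of one MetS component on the mediators, genotype and age."""

    intercept: float
    b_vfl: float
    b_tbf: float
    c_direct: float     # residual genotype effect not through either mediator
    delta_age: float
    noise_sd: float


def _default_components() -> Dict[str, ComponentSpec]:
    # Means sized to a paper-like overweight female cohort (WC ~100 cm,
    # MAP ~90 mmHg, FBS ~90 mg/dL, HDL ~48 mg/dL, TG ~120 mg/dL); HDL's
    # mediator and direct coefficients are negative (protective direction).
    return {
        "wc": ComponentSpec(intercept=81.8, b_vfl=0.80, b_tbf=0.02, c_direct=2.0, delta_age=0.05, noise_sd=6.0),
        "map": ComponentSpec(intercept=73.5, b_vfl=0.60, b_tbf=0.005, c_direct=1.5, delta_age=0.15, noise_sd=8.0),
        "fbs": ComponentSpec(intercept=73.6, b_vfl=0.50, b_tbf=0.005, c_direct=1.0, delta_age=0.20, noise_sd=9.0),
        "hdl": ComponentSpec(intercept=60.8, b_vfl=-0.80, b_tbf=-0.005, c_direct=-1.5, delta_age=0.05, noise_sd=9.0),
        "tg": ComponentSpec(intercept=28.5, b_vfl=4.00, b_tbf=0.02, c_direct=8.0, delta_age=0.50, noise_sd=50.0),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generative-model parameterization.

    The defaults are the "paper-like" preset: n=386 women, risk-allele
    frequency 0.3834, Table-1-like mediator means/SDs, and path effects
    sized so the VFL indirect path is detectable at this sample size while
    the TBF indirect path is essentially null.
    """

    n: int = 386
    p_risk: float = 0.3834
    seed: Optional[int] = None
    age_mean: float = 36.67
    age_sd: float = 9.1
    age_min: float = 18.0
    age_max: float = 55.0
    energy_mean: float = 2200.0
    energy_sd: float = 550.0
    energy_min: float = 800.0
    vfl: MediatorSpec = field(default_factory=lambda: MediatorSpec(intercept=13.7, a=1.2, gamma_age=0.05, noise_sd=2.9))
    tbf: MediatorSpec = field(default_factory=lambda: MediatorSpec(intercept=30.5, a=2.0, gamma_age=0.08, noise_sd=8.5))
    components: Dict[str, ComponentSpec] = field(default_factory=_default_components)
    pp_mean: float = 40.0   # pulse pressure, mmHg
    pp_sd: float = 8.0
    pp_floor: float = 10.0

    def validate(self) -> None:
        if not 0.0 < self.p_risk < 1.0:
            raise ConfigurationError(f"p_risk must be in (0, 1), got {self.p_risk}")
        if self.n < 20:
            raise ConfigurationError(f"n must be >= 20, got {self.n}")
        for name, sd in [("age_sd", self.age_sd), ("energy_sd", self.energy_sd),
                         ("vfl.noise_sd", self.vfl.noise_sd), ("tbf.noise_sd", self.tbf.noise_sd),
                         ("pp_sd", self.pp_sd)]:
            if sd <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {sd}")
        if set(self.components) != set(_COMPONENT_NAMES):
            raise ConfigurationError(f"components must be exactly {_COMPONENT_NAMES}")
        for comp, spec in self.components.items():
            if spec.noise_sd <= 0:
                raise ConfigurationError(f"components[{comp!r}].noise_sd must be > 0")

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticConfig":
        data = dict(data)
        if "vfl" in data and isinstance(data["vfl"], dict):
            data["vfl"] = MediatorSpec(**data["vfl"])
        if "tbf" in data and isinstance(data["tbf"], dict):
            data["tbf"] = MediatorSpec(**data["tbf"])
        if "components" in data:
            data["components"] = {
                k: (ComponentSpec(**v) if isinstance(v, dict) else v)
                for k, v in data["components"].items()
            }
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def paper_like_config(n: int = 386, seed: Optional[int] = None, **overrides) -> SyntheticConfig:
    """The default preset (see :class:`SyntheticConfig`)."""
    return replace(SyntheticConfig(), n=n, seed=seed, **overrides)


def null_config(n: int = 386, seed: Optional[int] = None) -> SyntheticConfig:
    """Preset with every genotype effect removed (a_vfl = a_tbf = c_direct = 0).

    The mediator -> component paths are kept, so this is the classic
    "a = 0, b != 0" null for indirect-effect calibration studies.
    """
    base = SyntheticConfig()
    return replace(
        base,
        n=n,
        seed=seed,
        vfl=replace(base.vfl, a=0.0),
        tbf=replace(base.tbf, a=0.0),
        components={k: replace(v, c_direct=0.0) for k, v in base.components.items()},
    )


# ---------------------------------------------------------------------------
# sampling


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_genotypes(n: int, p_risk: float, seed=None) -> np.ndarray:
    """Draw n genotypes independently in Hardy-Weinberg proportions.

    P(AA) = p^2, P(AG) = 2p(1-p), P(GG) = (1-p)^2 with p the risk-allele
    (A) frequency; reproducible under a fixed seed.
    """
    if not 0.0 < p_risk < 1.0:
        raise ConfigurationError(f"p_risk must be in (0, 1), got {p_risk}")
    rng = _as_rng(seed)
    p = p_risk
    probs = np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
    return rng.choice(np.array(["AA", "AG", "GG"], dtype=object), size=n, p=probs)


def _truncnorm_rvs(rng, mean, sd, lower=-np.inf, upper=np.inf, size=None):
    a = (lower - mean) / sd
    b = (upper - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: SyntheticConfig) -> CohortTable:
    """Sample a full synthetic cohort table under ``config``."""
    config.validate()
    rng = _as_rng(config.seed)
    n = config.n

    age = _truncnorm_rvs(rng, config.age_mean, config.age_sd, config.age_min, config.age_max, n)
    energy = _truncnorm_rvs(rng, config.energy_mean, config.energy_sd, config.energy_min, np.inf, n)
    genotype = generate_genotypes(n, config.p_risk, rng)
    x = np.where(genotype == "GG", 0.0, 1.0)  # dominant risk coding

    vfl = config.vfl.intercept + config.vfl.a * x + config.vfl.gamma_age * age \
        + rng.normal(0.0, config.vfl.noise_sd, n)
    tbf = config.tbf.intercept + config.tbf.a * x + config.tbf.gamma_age * age \
        + rng.normal(0.0, config.tbf.noise_sd, n)
    vfl = np.maximum(vfl, 0.5)
    tbf = np.maximum(tbf, 2.0)

    comp_values = {}
    for comp in _COMPONENT_NAMES:
        spec = config.components[comp]
        val = (spec.intercept + spec.b_vfl * vfl + spec.b_tbf * tbf
               + spec.c_direct * x + spec.delta_age * age
               + rng.normal(0.0, spec.noise_sd, n))
        comp_values[comp] = np.maximum(val, 1.0)

    # blood pressures reconstructed from MAP and a positive pulse pressure
    pp = _truncnorm_rvs(rng, config.pp_mean, config.pp_sd, config.pp_floor, np.inf, n)
    dbp = comp_values["map"] - pp / 3.0
    sbp = dbp + pp

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:05d}" for i in range(n)],
            "age": age,
            "energy_intake": energy,
            "genotype": genotype,
            "sbp": sbp,
            "dbp": dbp,
            "wc": comp_values["wc"],
            "fbs": comp_values["fbs"],
            "hdl": comp_values["hdl"],
            "tg": comp_values["tg"],
            "vfl": vfl,
            "tbf": tbf,
        }
    )
    return CohortTable(df=df, provenance=f"synthetic:seed={config.seed}")


# ---------------------------------------------------------------------------
# analytic ground truth


@dataclass(frozen=True)
class TrueEffects:
    """Closed-form population path coefficients for one mediator.

    Raw coefficients are on the cMetS-sum scale; standardized ones follow
    the partial-standardization convention (mediator and outcome scaled to
    unit SD, binary exposure untouched).
    """

    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    sd_mediator: float
    sd_outcome: float
    a_std: float
    b_std: float
    c_std: float
    indirect_std: float
    proportion_mediated: float


def _age_variance(config: SyntheticConfig) -> float:
    a = (config.age_min - config.age_mean) / config.age_sd
    b = (config.age_max - config.age_mean) / config.age_sd
    return float(truncnorm.var(a, b, loc=config.age_mean, scale=config.age_sd))


def true_effects(config: SyntheticConfig, mediator: str = "vfl") -> TrueEffects:
    """Population path coefficients for the genotype -> mediator -> cMetS chain.

    Derivation: each component's population age-residual is
    ``A_k (X - mu_X) + b_vfl,k e_v + b_tbf,k e_t + e_k`` with
    ``A_k = b_vfl,k a_v + b_tbf,k a_t + c_k``; dividing by its SD and
    summing (HDL negated) makes the score a linear function of X and the
    three independent noise sources, from which every OLS path coefficient
    follows in closed form.
    """
    if mediator not in ("vfl", "tbf"):
        raise ConfigurationError(f"mediator must be 'vfl' or 'tbf', got {mediator!r}")
    config.validate()
    q = 1.0 - (1.0 - config.p_risk) ** 2       # P(risk-allele carrier)
    var_x = q * (1.0 - q)
    var_age = _age_variance(config)
    a_v, s_v = config.vfl.a, config.vfl.noise_sd
    a_t, s_t = config.tbf.a, config.tbf.noise_sd

    w_v = w_t = d_direct = noise_var = 0.0
    for comp in _COMPONENT_NAMES:
        spec = config.components[comp]
        sign = -1.0 if comp == "hdl" else 1.0
        a_k = spec.b_vfl * a_v + spec.b_tbf * a_t + spec.c_direct
        sigma_k = math.sqrt(
            a_k ** 2 * var_x
            + spec.b_vfl ** 2 * s_v ** 2
            + spec.b_tbf ** 2 * s_t ** 2
            + spec.noise_sd ** 2
        )
        w_v += sign * spec.b_vfl / sigma_k
        w_t += sign * spec.b_tbf / sigma_k
        d_direct += sign * spec.c_direct / sigma_k
        noise_var += (spec.noise_sd / sigma_k) ** 2

    c_total = a_v * w_v + a_t * w_t + d_direct
    var_y = c_total ** 2 * var_x + w_v ** 2 * s_v ** 2 + w_t ** 2 * s_t ** 2 + noise_var
    sd_y = math.sqrt(var_y)

    if mediator == "vfl":
        a, b = a_v, w_v
        gamma, s_m = config.vfl.gamma_age, s_v
    else:
        a, b = a_t, w_t
        gamma, s_m = config.tbf.gamma_age, s_t
    sd_m = math.sqrt(a ** 2 * var_x + gamma ** 2 * var_age + s_m ** 2)
    indirect = a * b
    c_prime = c_total - indirect
    return TrueEffects(
        a=a, b=b, c=c_total, c_prime=c_prime, indirect=indirect,
        sd_mediator=sd_m, sd_outcome=sd_y,
        a_std=a / sd_m, b_std=b * sd_m / sd_y, c_std=c_total / sd_y,
        indirect_std=indirect / sd_y,
        proportion_mediated=(indirect / c_total if c_total != 0 else math.nan),
    )


def config_with_true_indirect(
    target: float,
    mediator: str = "vfl",
    base: Optional[SyntheticConfig] = None,
    **overrides,
) -> SyntheticConfig:
    """Scale the mediator's genotype path so the population standardized
    indirect effect equals ``target`` exactly.

    Only the exposure -> mediator coefficient (``a``) of the requested
    mediator is rescaled; with ``target=0`` it is set to zero.
    """
    from scipy.optimize import brentq

    base = base if base is not None else SyntheticConfig()
    if overrides:
        base = replace(base, **overrides)
    if target < 0:
        raise ConfigurationError("target standardized indirect must be >= 0 here")

    def with_scale(t: float) -> SyntheticConfig:
        spec = getattr(base, mediator)
        return replace(base, **{mediator: replace(spec, a=spec.a * t)})

    if target == 0.0:
        return with_scale(0.0)

    def objective(t: float) -> float:
        return true_effects(with_scale(t), mediator).indirect_std - target

    t_star = brentq(objective, 1e-9, 50.0, xtol=1e-12)
    return with_scale(t_star)
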