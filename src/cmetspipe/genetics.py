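"""Single-SNP genetics utilities.

Allele-frequency computation from genotype counts, the exact conditional
Hardy-Weinberg equilibrium (HWE) test, and the three standard numeric
codings of a biallelic genotype (codominant / dominant / recessive) relative
to a designated risk allele.

The SNP is represented throughout as a categorical column with the three
literal labels ``AA``, ``AG``, ``GG``; the risk allele defaults to ``A``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Tuple

import numpy as np
from scipy.special import gammaln, logsumexp

from .exceptions import InputError, ValidationError

GENOTYPES: Tuple[str, str, str] = ("AA", "AG", "GG")
CODING_MODELS: Tuple[str, str, str] = ("codominant", "dominant", "recessive")

# Above this total the exact-integer weights are replaced by log-space
# factorials; the test stays accurate but is no longer bit-exact.
_EXACT_INT_LIMIT = 2000


@dataclass(frozen=True)
class GenotypeCounts:
    """Counts of the three genotype classes at one biallelic locus."""

    n_aa: int
    n_ag: int
    n_gg: int

    def __post_init__(self) -> None:
        for name in ("n_aa", "n_ag", "n_gg"):
            value = getattr(self, name)
            if int(value) != value or value < 0:
                raise InputError(f"genotype count {name}={value!r} must be a non-negative integer")
        if self.total == 0:
            raise InputError("all genotype counts are zero")

    @property
    def total(self) -> int:
        return int(self.n_aa + self.n_ag + self.n_gg)

    @classmethod
    def from_genotypes(cls, genotypes: Iterable[str]) -> "GenotypeCounts":
        labels = list(genotypes)
        unknown = sorted(set(labels) - set(GENOTYPES))
        if unknown:
            raise ValidationError(f"unknown genotype label(s): {unknown}")
        return cls(labels.count("AA"), labels.count("AG"), labels.count("GG"))


def allele_frequencies(counts: GenotypeCounts) -> Tuple[float, float]:
    """Return ``(freq_A, freq_G)`` from genotype counts.

    freq_A = (2*n_AA + n_AG) / (2*total); freq_G is its complement.
    """
    total = counts.total
    freq_a = (2 * counts.n_aa + counts.n_ag) / (2 * total)
    return freq_a, 1.0 - freq_a


def _hwe_support(n: int, n_minor: int) -> range:
    # Heterozygote count shares the parity of the minor-allele count.
    return range(n_minor % 2, n_minor + 1, 2)


def hwe_exact_test(counts: GenotypeCounts, mid_p: bool = False) -> float:
    """Exact conditional test of Hardy-Weinberg equilibrium.

    Conditions on the sample size ``n`` and the minor-allele count and
    enumerates every heterozygote count ``h`` of the right parity; the
    conditional probability of ``h`` is proportional to
    ``n! / (n_hom_rare! * h! * n_hom_common!) * 2**h``.  The two-sided
    p-value sums the probabilities of all outcomes no more probable than
    the observed one, so it always lies in (0, 1].

    With ``mid_p=True`` only half the observed outcome's probability is
    counted (Lancaster mid-p variant).
    """
    n = counts.total
    n_a = 2 * counts.n_aa + counts.n_ag
    n_g = 2 * counts.n_gg + counts.n_ag
    n_minor = min(n_a, n_g)
    if n_minor == 0:
        return 1.0

    h_obs = counts.n_ag
    support = list(_hwe_support(n, n_minor))

    if n <= _EXACT_INT_LIMIT:
        # Exact integer weights: w(h) = n!/(rare! h! common!) * 2^h.
        weights = {}
        for h in support:
            rare = (n_minor - h) // 2
            weights[h] = math.comb(n, h) * math.comb(n - h, rare) * (1 << h)
        w_obs = weights[h_obs]
        total_w = sum(weights.values())
        tail = sum(w for w in weights.values() if w <= w_obs)
        if mid_p:
            p = (tail - 0.5 * w_obs) / total_w
        else:
            p = tail / total_w
        # p is mathematically > 0; keep it so under float underflow
        return max(float(p), 5e-324)

    # Large n: log-space weights, tie comparison with a tiny relative slack.
    hs = np.asarray(support, dtype=np.int64)
    rare = (n_minor - hs) // 2
    common = n - hs - rare
    logw = (
        hs * math.log(2.0)
        + gammaln(n + 1)
        - gammaln(hs + 1)
        - gammaln(rare + 1)
        - gammaln(common + 1)
    )
    log_total = logsumexp(logw)
    logp = logw - log_total
    logp_obs = logp[hs == h_obs][0]
    mask = logp <= logp_obs + 1e-12
    p = float(np.exp(logsumexp(logp[mask])))
    if mid_p:
        p -= 0.5 * float(np.exp(logp_obs))
    return min(max(p, 5e-324), 1.0)


def genotype_coding(model: str, risk_allele: str = "A") -> dict:
    """Genotype -> numeric mapping for one coding model.

    codominant counts copies of the risk allele (0/1/2); dominant contrasts
    carriers against non-carriers (risk-allele default gives GG=0, AG+AA=1);
    recessive contrasts risk homozygotes against everyone else.
    """
    if model not in CODING_MODELS:
        raise ValidationError(f"unknown coding model {model!r}; expected one of {CODING_MODELS}")
    if risk_allele not in ("A", "G"):
        raise ValidationError(f"risk allele must be 'A' or 'G', got {risk_allele!r}")
    mapping = {}
    for g in GENOTYPES:
        n_risk = g.count(risk_allele)
        if model == "codominant":
            mapping[g] = n_risk
        elif model == "dominant":
            mapping[g] = int(n_risk > 0)
        else:
            mapping[g] = int(n_risk == 2)
    return mapping


def encode_genotypes(genotypes, model: str, risk_allele: str = "A") -> np.ndarray:
    """Encode genotype labels numerically under one coding model.

    Raises :class:`ValidationError` naming any label outside {AA, AG, GG}.
    """
    mapping = genotype_coding(model, risk_allele)
    labels = np.asarray(genotypes, dtype=object)
    out = np.empty(labels.shape[0], dtype=float)
    for i, g in enumerate(labels):
        try:
            out[i] = mapping[g]
        except KeyError:
            raise ValidationError(f"unknown genotype label {g!r} at position {i}") from None
    return out
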