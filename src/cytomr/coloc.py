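"""Approximate-Bayes-factor colocalisation of two traits at a locus.

For each variant an approximate Bayes factor against the null is computed
from the association summary statistic (z = beta/se) and a prior effect
variance w: with shrinkage r = w / (w + se²),

    log ABF = 0.5 * (log(1 - r) + r * z²).

The five locus hypotheses are enumerated in log space — H0 no association,
H1/H2 one trait associated, H3 two distinct causal variants, H4 one shared
causal variant — with per-variant priors p1, p2 and p12, and posterior
probabilities by softmax. The decision quantities reported alongside are the
support rule PP_shared + PP_distinct > 0.5 and the ratio rule
PP_shared / (PP_shared + PP_distinct) > 0.5; both passing is read as
evidence for a shared causal variant, a high PP_distinct alone as genetic
confounding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .sumstats import HarmonisedSet, SummaryStats, harmonise

__all__ = ["ColocConfig", "ColocResult", "wakefield_labf", "colocalise"]

HYPOTHESES = ("H0", "H1", "H2", "H3", "H4")


@dataclass
class ColocConfig:
    """Priors for the enumeration.

    p1/p2: prior probability a variant is causal for trait 1/2 only;
    p12: prior probability it is causal for both. w1/w2: prior variance of
    the true effect per trait — ``None`` selects 0.2² for quantitative-scale
    traits and 0.15² on the log-odds scale for binary traits at call time.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    w1: float | None = None
    w2: float | None = None

    W_QUANTITATIVE = 0.2 ** 2
    W_BINARY = 0.15 ** 2

    def __post_init__(self) -> None:
        if not 0 < self.p12 <= min(self.p1, self.p2):
            raise ValueError("need 0 < p12 <= min(p1, p2)")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("per-variant priors must sum below 1")
        for w in (self.w1, self.w2):
            if w is not None and w <= 0:
                raise ValueError("prior effect variances must be > 0")

    @classmethod
    def w_for(cls, trait_type: str) -> float:
        return cls.W_BINARY if trait_type == "binary" else cls.W_QUANTITATIVE


def wakefield_labf(beta, se, w) -> np.ndarray:
    """Log approximate Bayes factor for one association (vectorised).

    With z = beta/se and shrinkage r = w/(w + se²):
    log ABF = 0.5 * (log(1 - r) + r * z²). As w -> 0 the ABF tends to 1.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    if np.any(np.asarray(w) < 0):
        raise ValueError("prior variance w must be >= 0")
    z = beta / se
    r = w / (w + se ** 2)
    return 0.5 * (np.log1p(-r) + r * z ** 2)


def _logdiffexp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)), guarded: returns -inf when the difference
    underflows (b >= a numerically)."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


@dataclass
class ColocResult:
    """Posterior hypothesis probabilities and the shared/distinct decisions."""

    pp: np.ndarray  # PP_H0..PP_H4, sums to 1
    n_variants: int
    degenerate: bool = False  # fewer than 2 shared variants: H3 unsupported
    labf1: np.ndarray | None = field(default=None, repr=False)
    labf2: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.pp = np.asarray(self.pp, dtype=float)
        if self.pp.shape != (5,):
            raise ValueError("pp must hold five hypothesis probabilities")
        if not np.isclose(self.pp.sum(), 1.0, atol=1e-9):
            raise ValueError("posterior probabilities must sum to 1")

    @property
    def pp_shared(self) -> float:
        return float(self.pp[4])

    @property
    def pp_distinct(self) -> float:
        return float(self.pp[3])

    @property
    def passes_support(self) -> bool:
        return self.pp_shared + self.pp_distinct > 0.5

    @property
    def passes_ratio(self) -> bool:
        denom = self.pp_shared + self.pp_distinct
        return denom > 0 and self.pp_shared / denom > 0.5

    @property
    def supported(self) -> bool:
        """The combined evidence rule for colocalising signals."""
        return self.passes_support and self.passes_ratio

    def as_dict(self) -> dict:
        d = {f"PP_{h}": float(v) for h, v in zip(HYPOTHESES, self.pp)}
        d.update(n_variants=self.n_variants,
                 passes_support=self.passes_support,
                 passes_ratio=self.passes_ratio)
        return d


def colocalise(
    trait1,
    trait2,
    config: ColocConfig | None = None,
    trait1_type: str = "quantitative",
    trait2_type: str = "quantitative",
) -> ColocResult:
    """Enumerate the five colocalisation hypotheses over a locus.

    ``trait1``/``trait2`` may be :class:`SummaryStats` restricted to the
    locus (they are intersected and harmonised on the fly) or a prepared
    :class:`HarmonisedSet` passed as ``trait1`` with ``trait2=None``.
    All accumulation is in log space with log-sum-exp; the H3 term
    sum_{i != j} ABF1_i ABF2_j is computed stably as the guarded difference
    exp(S1 + S2) - exp(S12).
    """
    config = config or ColocConfig()
    if isinstance(trait1, HarmonisedSet):
        h = trait1
        t1_type, t2_type = trait1_type, trait2_type
    else:
        if not isinstance(trait1, SummaryStats) or not isinstance(
                trait2, SummaryStats):
            raise TypeError("pass two SummaryStats or one HarmonisedSet")
        t1_type, t2_type = trait1.trait_type, trait2.trait_type
        h = harmonise(trait1, trait2)

    if h.n_snp < 1:
        raise ValueError("colocalise needs at least one shared variant")
    degenerate = h.n_snp < 2
    if degenerate:
        warnings.warn("fewer than 2 shared variants: the distinct-variant "
                      "hypothesis (H3) is unsupported at this locus",
                      stacklevel=2)

    b1, s1, b2, s2 = h.arrays()
    w1 = config.w1 if config.w1 is not None else ColocConfig.w_for(t1_type)
    w2 = config.w2 if config.w2 is not None else ColocConfig.w_for(t2_type)
    l1 = wakefield_labf(b1, s1, w1)
    l2 = wakefield_labf(b2, s2, w2)

    s1_sum = float(logsumexp(l1))
    s2_sum = float(logsumexp(l2))
    s12 = float(logsumexp(l1 + l2))

    lp1, lp2, lp12 = np.log(config.p1), np.log(config.p2), np.log(config.p12)
    L = np.array([
        0.0,
        lp1 + s1_sum,
        lp2 + s2_sum,
        lp1 + lp2 + _logdiffexp(s1_sum + s2_sum, s12),
        lp12 + s12,
    ])
    pp = np.exp(L - logsumexp(L))
    pp /= pp.sum()
    return ColocResult(pp=pp, n_variants=h.n_snp, degenerate=degenerate,
                       labf1=l1, labf2=l2)
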