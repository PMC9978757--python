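"""Synthetic cohorts with known causal structure, and per-SNP GWAS.

Generates individual-level genotype dosages with block-autoregressive LD via
a Gaussian copula, quantitative / binary / expression phenotypes driven by a
configurable causal architecture (per-variant effects, direct pleiotropic
effects, a trait-to-trait causal DAG, per-tissue cis expression effects), and
runs additive-model GWAS — so every downstream stage of the pipeline can be
exercised against known ground truth without external data.

Haplotype model: alleles within an LD block form a first-order binary Markov
chain with adjacent correlation ``ld_rho`` and a block-constant allele
frequency, giving pairwise haplotype (and dosage) correlation exactly
``ld_rho ** distance`` within a block and zero across blocks — correlations
multiply along a two-state Markov chain, and equal within-block frequencies
keep every transition probability valid (binary variables with very
different frequencies cannot be strongly correlated, which is also why real
variants in tight LD have similar frequencies). Two independent haplotypes
sum to a dosage in {0, 1, 2}. ``theoretical_ld`` returns this model LD and
serves as the reference-panel stand-in for clumping.
"""

from __future__ import annotations

import graphlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import GeneLocus, LDMatrix, SummaryStats, RECORD_COLUMNS

__all__ = [
    "TraitSpec",
    "SimConfig",
    "Cohort",
    "simulate_cohort",
    "inverse_normal_transform",
    "run_gwas",
    "theoretical_ld",
]


@dataclass(frozen=True)
class TraitSpec:
    """One simulated trait: kind, residual noise, and prevalence if binary."""

    kind: str = "quantitative"  # cytokine | quantitative | binary
    noise_sd: float = 1.0
    prevalence: float = 0.1  # binary traits: case fraction on the liability scale

    def __post_init__(self) -> None:
        if self.kind not in ("cytokine", "quantitative", "binary"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.kind == "binary" and not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")


@dataclass
class SimConfig:
    """Full specification of a synthetic cohort.

    ``causal_map`` holds per-trait direct genetic effects in SD units of the
    liability; ``pleiotropy_map`` holds additional direct variant->trait
    effects that bypass the exposure (instrument-invalidating horizontal
    pleiotropy); ``trait_dag`` lists (source, target, effect) trait-level
    causal edges in SD units; ``expression_map`` holds per-gene cis effects
    shared across tissues, to which tissue-specific perturbations of SD
    ``tissue_effect_sd`` are added.
    """

    n_individuals: int = 1000
    n_variants: int = 100
    ld_block_size: int = 25
    ld_rho: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    chrom: str = "1"
    pos_start: int = 1_000_000
    pos_spacing: int = 1_000
    gene_loci: list[GeneLocus] = field(default_factory=list)
    traits: dict[str, TraitSpec] = field(default_factory=dict)
    causal_map: dict[str, list[tuple[int, float]]] = field(default_factory=dict)
    pleiotropy_map: dict[str, list[tuple[int, float]]] = field(default_factory=dict)
    trait_dag: list[tuple[str, str, float]] = field(default_factory=list)
    expression_map: dict[str, list[tuple[int, float]]] = field(default_factory=dict)
    n_tissues: int = 0
    tissue_names: list[str] | None = None
    tissue_effect_sd: float = 0.0
    expression_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        for tmap in (self.causal_map, self.pleiotropy_map):
            for trait, effects in tmap.items():
                for idx, _ in effects:
                    if not 0 <= idx < self.n_variants:
                        raise ValueError(
                            f"causal variant index {idx} for trait {trait!r} "
                            f"out of range [0, {self.n_variants})"
                        )
        self.topological_trait_order()  # raises on cycles
        if self.n_tissues and self.tissue_names is None:
            self.tissue_names = ["whole_blood"] + [
                f"tissue{i}" for i in range(2, self.n_tissues + 1)
            ]
        if self.tissue_names is not None and len(self.tissue_names) != self.n_tissues:
            raise ValueError("tissue_names length must equal n_tissues")

    def topological_trait_order(self) -> list[str]:
        """Trait evaluation order; raises on a cyclic trait DAG."""
        ts: graphlib.TopologicalSorter = graphlib.TopologicalSorter()
        for t in self.traits:
            ts.add(t)
        for src, dst, _ in self.trait_dag:
            ts.add(dst, src)
        try:
            return list(ts.static_order())
        except graphlib.CycleError as err:
            raise ValueError(f"trait_dag contains a cycle: {err}") from err

    @property
    def positions(self) -> np.ndarray:
        return self.pos_start + self.pos_spacing * np.arange(self.n_variants)

    @property
    def variant_ids(self) -> list[str]:
        return [f"v{i}" for i in range(self.n_variants)]


def theoretical_ld(config: SimConfig) -> LDMatrix:
    """Model LD: rho^|i-j| within a block, 0 across blocks (exact under the
    haplotype Markov chain).

    Plays the role of an external LD reference panel: deterministic, free of
    the O(1/n) sampling noise of empirical r² that matters at an r² < 0.001
    clumping ceiling.
    """
    k = config.n_variants
    block = config.ld_block_size
    idx = np.arange(k)
    dist = np.abs(idx[:, None] - idx[None, :])
    same_block = (idx[:, None] // block) == (idx[None, :] // block)
    r = np.where(same_block, config.ld_rho ** dist, 0.0)
    np.fill_diagonal(r, 1.0)
    return LDMatrix(config.variant_ids, r)


@dataclass
class Cohort:
    """Simulated individual-level data plus the generating truth."""

    config: SimConfig
    dosages: np.ndarray  # (n_variants, n_individuals), values in {0,1,2}
    mafs: np.ndarray
    phenotypes: dict[str, np.ndarray]
    tissue_expression: dict[tuple[str, str], np.ndarray]  # (gene, tissue) -> vector

    def variant_table(self) -> pd.DataFrame:
        c = self.config
        return pd.DataFrame({
            "variant_id": c.variant_ids,
            "chrom": c.chrom,
            "pos": c.positions,
            "effect_allele": "A",
            "other_allele": "G",
            "maf": self.mafs,
        })

    def truth_table(self) -> pd.DataFrame:
        """Per-(variant, trait) direct true effects, for test harnesses."""
        rows = []
        c = self.config
        for trait, effects in c.causal_map.items():
            for idx, b in effects:
                rows.append((c.variant_ids[idx], trait, b, "causal"))
        for trait, effects in c.pleiotropy_map.items():
            for idx, b in effects:
                rows.append((c.variant_ids[idx], trait, b, "pleiotropy"))
        return pd.DataFrame(rows, columns=["variant_id", "trait", "effect", "kind"])

    def empirical_ld(self) -> LDMatrix:
        return LDMatrix.from_dosages(self.dosages, self.config.variant_ids)


def _block_mafs(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Block-constant allele frequencies drawn uniformly from maf_range."""
    n_blocks = -(-config.n_variants // config.ld_block_size)
    per_block = rng.uniform(*config.maf_range, size=n_blocks)
    return np.repeat(per_block, config.ld_block_size)[: config.n_variants]


def _simulate_haplotypes(config: SimConfig, rng: np.random.Generator,
                         mafs: np.ndarray) -> np.ndarray:
    """(n_variants, 2 * n_individuals) 0/1 haplotypes.

    Within a block the allele sequence is a binary Markov chain with
    adjacent correlation rho and equal marginals, so the correlation at
    distance d is exactly rho**d; block starts are fresh draws.
    """
    k, n2 = config.n_variants, 2 * config.n_individuals
    rho = config.ld_rho
    h = np.empty((k, n2), dtype=np.int8)
    u = rng.random((k, n2))
    for i in range(k):
        p = mafs[i]
        if rho > 0 and i % config.ld_block_size != 0:
            cond = np.where(h[i - 1] == 1, p + rho * (1 - p), p * (1 - rho))
            h[i] = u[i] < cond
        else:
            h[i] = u[i] < p
    return h


def simulate_cohort(config: SimConfig) -> Cohort:
    """Draw one cohort: dosages, phenotypes and tissue expression.

    Quantitative/cytokine traits are built as
    ``sum(causal dosage * effect) + sum(parent trait * DAG effect) + noise``;
    binary traits threshold that liability at its empirical
    (1 - prevalence) quantile. All randomness flows from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    mafs = _block_mafs(config, rng)
    hap = _simulate_haplotypes(config, rng, mafs)
    n = config.n_individuals
    dosages = (hap[:, :n] + hap[:, n:]).astype(np.int8)

    # centred, unit-variance-per-allele genetic contributions keep effect
    # sizes in SD units of the liability
    parents: dict[str, list[tuple[str, float]]] = {t: [] for t in config.traits}
    for src, dst, eff in config.trait_dag:
        parents.setdefault(dst, []).append((src, eff))

    phenotypes: dict[str, np.ndarray] = {}
    for trait in config.topological_trait_order():
        spec = config.traits.get(trait, TraitSpec())
        liability = np.zeros(n)
        for idx, b in config.causal_map.get(trait, []):
            liability += b * dosages[idx]
        for idx, b in config.pleiotropy_map.get(trait, []):
            liability += b * dosages[idx]
        for src, eff in parents.get(trait, []):
            liability = liability + eff * phenotypes[src]
        if spec.noise_sd > 0:
            liability = liability + rng.normal(0.0, spec.noise_sd, size=n)
        if spec.kind == "binary":
            thresh = np.quantile(liability, 1.0 - spec.prevalence)
            phenotypes[trait] = (liability > thresh).astype(float)
        else:
            phenotypes[trait] = liability

    tissue_expression: dict[tuple[str, str], np.ndarray] = {}
    for gene, effects in config.expression_map.items():
        for tissue in config.tissue_names or []:
            expr = np.zeros(n)
            for idx, b in effects:
                if not 0 <= idx < config.n_variants:
                    raise ValueError(
                        f"expression variant index {idx} for gene {gene!r} "
                        f"out of range"
                    )
                b_t = b + (rng.normal(0.0, config.tissue_effect_sd)
                           if config.tissue_effect_sd > 0 else 0.0)
                expr += b_t * dosages[idx]
            expr += rng.normal(0.0, config.expression_noise_sd, size=n)
            tissue_expression[(gene, tissue)] = expr

    return Cohort(config=config, dosages=dosages, mafs=mafs,
                  phenotypes=phenotypes, tissue_expression=tissue_expression)


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset.

    Rank r of m values maps to ``Phi^-1((r - 0.375) / (m + 0.25))``; ties
    share the average rank. Constant input is rejected.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need a 1-d vector of length >= 2")
    if np.ptp(v) == 0:
        raise ValueError("inverse normal transform undefined for constant input")
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - 0.375) / (len(v) + 0.25))


def _ols_gwas(y: np.ndarray, dosages: np.ndarray,
              covariates: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-variant simple/partial OLS: (beta, se) per variant.

    With covariates, both phenotype and dosages are residualised on
    [1, covariates] first (Frisch–Waugh); the error df is n - q - 1.
    """
    n = len(y)
    g = dosages.astype(float)
    if covariates is not None:
        x = np.column_stack([np.ones(n), covariates])
        q = x.shape[1]
        coef_y, *_ = np.linalg.lstsq(x, y, rcond=None)
        y = y - x @ coef_y
        coef_g, *_ = np.linalg.lstsq(x, g.T, rcond=None)
        g = g - (x @ coef_g).T
    else:
        q = 1
        y = y - y.mean()
        g = g - g.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", g, g)
    mono = sxx <= 0
    sxx_safe = np.where(mono, 1.0, sxx)
    beta = (g @ y) / sxx_safe
    rss = np.maximum(y @ y - beta ** 2 * sxx_safe, 0.0)
    df = max(n - q - 1, 1)
    se = np.sqrt(rss / df / sxx_safe)
    beta[mono] = 0.0
    se[mono] = np.inf
    se[se <= 0] = np.inf
    return beta, se


def _logistic_gwas(y: np.ndarray, dosages: np.ndarray,
                   covariates: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    import statsmodels.api as sm

    n = len(y)
    base = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates])
    betas = np.empty(dosages.shape[0])
    ses = np.empty(dosages.shape[0])
    for i, g in enumerate(dosages):
        if g.std() == 0:
            betas[i], ses[i] = 0.0, np.inf
            continue
        x = np.column_stack([base, g.astype(float)])
        try:
            fit = sm.Logit(y, x).fit(disp=0, maxiter=100)
            betas[i] = fit.params[-1]
            ses[i] = fit.bse[-1]
            if not np.isfinite(ses[i]) or ses[i] > 100:  # separation guard
                betas[i], ses[i] = 0.0, np.inf
        except Exception:
            betas[i], ses[i] = 0.0, np.inf
    return betas, ses


def run_gwas(
    cohort: Cohort,
    trait_id: str,
    covariates: np.ndarray | None = None,
    transform: str = "auto",
    gene: str | None = None,
    tissue: str | None = None,
) -> SummaryStats:
    """Per-variant additive-model GWAS for one trait (or one gene x tissue).

    Quantitative and cytokine traits use linear regression of the
    (optionally inverse-normal transformed) phenotype on dosage; binary
    traits use logistic regression; p-values are two-sided normal on the
    Wald statistic. Cytokines are transformed by default (``transform=
    'auto'``); pass ``'none'`` or ``'int'`` to override. Monomorphic
    variants are emitted with beta 0 and se inf so that downstream selection
    drops them.
    """
    cfg = cohort.config
    if gene is not None:
        if tissue is None:
            raise ValueError("expression GWAS needs both gene and tissue")
        y = cohort.tissue_expression[(gene, tissue)]
        kind, trait_type = "quantitative", "expression"
        out_id = gene
    else:
        if trait_id not in cohort.phenotypes:
            raise KeyError(f"trait {trait_id!r} not in cohort")
        y = cohort.phenotypes[trait_id]
        kind = cfg.traits.get(trait_id, TraitSpec()).kind
        trait_type = kind
        out_id = trait_id

    if kind == "binary":
        uniq = np.unique(y)
        if not np.isin(uniq, [0.0, 1.0]).all():
            raise ValueError("binary trait phenotype must be 0/1")
        beta, se = _logistic_gwas(y, cohort.dosages, covariates)
    else:
        do_int = transform == "int" or (transform == "auto" and kind == "cytokine")
        if do_int:
            y = inverse_normal_transform(y)
        beta, se = _ols_gwas(y, cohort.dosages, covariates)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(np.isfinite(se), beta / se, 0.0)
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)
    eaf = cohort.dosages.mean(axis=1) / 2.0

    records = pd.DataFrame({
        "variant_id": cfg.variant_ids,
        "chrom": cfg.chrom,
        "pos": cfg.positions,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": eaf,
        "beta": beta,
        "se": se,
        "p": p,
        "n": len(y),
    })[RECORD_COLUMNS]
    return SummaryStats(trait_id=out_id, trait_type=trait_type,
                        tissue=tissue, records=records)
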