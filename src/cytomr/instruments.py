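"""Genetic instrument selection: greedy LD clumping and the three selection
criteria (trait GWAS threshold, cis-pQTL, cis-eQTL) plus genome-wide cytokine
instruments.

All p-value threshold comparisons are strict (``p < p_max``), matching the
"P<x" convention; the cis window bound is positional and inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .sumstats import GeneLocus, LDMatrix, SummaryStats

__all__ = [
    "InstrumentSet",
    "clump",
    "select_trait_instruments",
    "select_cis_pqtl",
    "select_cis_eqtl",
    "select_genomewide_cytokine",
]

#: columns of an InstrumentSet's variant table
INSTRUMENT_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "p", "n",
]

CRITERIA = ("trait_gwas", "cis_pqtl", "cis_eqtl", "genomewide_cytokine")


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure under one criterion."""

    exposure_id: str
    criterion: str
    variants: pd.DataFrame
    locus: GeneLocus | None = None
    thresholds: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        self.variants = self.variants.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def is_empty(self) -> bool:
        return len(self.variants) == 0

    def validate(self, ld: LDMatrix, r2_max: float = 0.001,
                 window: int = 500_000) -> None:
        """Assert the set's own invariants: pairwise r² below the clump
        ceiling, p below the criterion threshold, cis variants inside the
        extended locus window."""
        ids = self.variants["variant_id"].tolist()
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                r2 = ld.r2(a, b)
                if r2 >= r2_max:
                    raise AssertionError(
                        f"instruments {a}, {b} in LD (r2={r2:.4g} >= {r2_max})")
        p_max = self.thresholds.get("p_max")
        if p_max is not None and len(self.variants):
            if not (self.variants["p"] < p_max).all():
                raise AssertionError("instrument p above criterion threshold")
        if self.criterion in ("cis_pqtl", "cis_eqtl") and self.locus is not None:
            lo, hi = self.locus.window(window)
            ok = (
                (self.variants["chrom"].astype(str) == str(self.locus.chrom))
                & (self.variants["pos"] >= lo)
                & (self.variants["pos"] <= hi)
            )
            if not ok.all():
                raise AssertionError("cis instrument outside the locus window")


def clump(
    records: pd.DataFrame,
    ld: LDMatrix,
    r2_max: float = 0.001,
    p_max: float = 5e-8,
) -> pd.DataFrame:
    """Greedy LD clumping of candidate association records.

    Candidates with p < p_max are sorted ascending by p (ties broken by
    position, then allele strings, for determinism) and accepted in order;
    a candidate is discarded if its r² with any already-accepted variant is
    at or above ``r2_max``. Output order follows acceptance order, so it is
    invariant to input ordering. A candidate absent from the LD matrix is a
    hard error naming the variant.
    """
    if not 0 < r2_max < 1:
        raise ValueError("r2_max must be in (0, 1)")
    se = pd.to_numeric(records["se"])
    finite = (se > 0) & (se < float("inf"))
    cand = records.loc[finite & (records["p"] < p_max)].copy()
    cand = cand.sort_values(
        ["p", "pos", "effect_allele", "other_allele"], kind="mergesort"
    )
    kept_idx: list = []
    kept_ids: list[str] = []
    for row in cand.itertuples():
        vid = row.variant_id
        i = ld.index(vid)  # raises KeyError naming the variant if missing
        if all(ld.r[i, ld.index(k)] ** 2 < r2_max for k in kept_ids):
            kept_idx.append(row.Index)
            kept_ids.append(vid)
    return cand.loc[kept_idx]


def _empty_warning(exposure_id: str, criterion: str) -> None:
    warnings.warn(
        f"no instruments selected for {exposure_id} under {criterion}; "
        f"MR for this exposure will be skipped",
        stacklevel=3,
    )


def select_trait_instruments(
    trait: SummaryStats,
    ld: LDMatrix,
    p_max: float = 5e-8,
) -> InstrumentSet:
    """Genome-wide significant, LD-independent instruments for a trait.

    The default threshold is 5e-8; traits with a bespoke threshold (for
    example 1e-6 for fasting insulin) pass it via ``p_max``.
    """
    variants = clump(trait.records, ld, r2_max=0.001, p_max=p_max)
    if variants.empty:
        _empty_warning(trait.trait_id, "trait_gwas")
    return InstrumentSet(trait.trait_id, "trait_gwas", variants,
                         thresholds={"p_max": p_max, "r2_max": 0.001})


def _window_records(ss: SummaryStats, locus: GeneLocus, window: int
                    ) -> pd.DataFrame:
    lo, hi = locus.window(window)
    sub = ss.subset_window(locus.chrom, lo, hi)
    return sub.records


def select_cis_pqtl(
    cytokine: SummaryStats,
    locus: GeneLocus,
    ld: LDMatrix,
    window: int = 500_000,
    p_max: float = 1e-4,
) -> InstrumentSet:
    """cis-pQTL instruments: variants within +/- ``window`` of the gene body
    associated with the circulating cytokine at p < ``p_max``, clumped."""
    records = _window_records(cytokine, locus, window)
    variants = clump(records, ld, r2_max=0.001, p_max=p_max)
    if variants.empty:
        _empty_warning(cytokine.trait_id, "cis_pqtl")
    return InstrumentSet(cytokine.trait_id, "cis_pqtl", variants, locus=locus,
                         thresholds={"p_max": p_max, "r2_max": 0.001,
                                     "window": window})


def select_cis_eqtl(
    cytokine: SummaryStats,
    agg_expression: SummaryStats,
    locus: GeneLocus,
    ld: LDMatrix,
    window: int = 500_000,
    p_expr_max: float = 1e-4,
    p_cyt_max: float = 0.05,
) -> InstrumentSet:
    """cis-eQTL instruments: variants within the locus window associated with
    cross-tissue gene expression at p < ``p_expr_max`` AND with the
    circulating cytokine at p < ``p_cyt_max``; exposure betas are taken from
    the cytokine summary statistics."""
    cyt = _window_records(cytokine, locus, window)
    expr = _window_records(agg_expression, locus, window)
    eligible_pos = expr.loc[expr["p"] < p_expr_max, ["chrom", "pos"]]
    records = cyt.merge(eligible_pos, on=["chrom", "pos"])
    variants = clump(records, ld, r2_max=0.001, p_max=p_cyt_max)
    if variants.empty:
        _empty_warning(cytokine.trait_id, "cis_eqtl")
    return InstrumentSet(cytokine.trait_id, "cis_eqtl", variants, locus=locus,
                         thresholds={"p_max": p_cyt_max,
                                     "p_expr_max": p_expr_max,
                                     "r2_max": 0.001, "window": window})


def select_genomewide_cytokine(
    cytokine: SummaryStats,
    ld: LDMatrix,
    p_max: float = 5e-8,
) -> InstrumentSet:
    """Secondary criterion: uncorrelated genome-wide significant cytokine
    variants regardless of locus."""
    variants = clump(cytokine.records, ld, r2_max=0.001, p_max=p_max)
    if variants.empty:
        _empty_warning(cytokine.trait_id, "genomewide_cytokine")
    return InstrumentSet(cytokine.trait_id, "genomewide_cytokine", variants,
                         thresholds={"p_max": p_max, "r2_max": 0.001})
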