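"""Orchestration of the three analysis directions and the cytokine network.

Direction 1: cardiometabolic risk factors -> circulating cytokines, with
genome-wide-significant trait instruments and a Bonferroni family over the
number of cytokine outcomes.

Direction 2: cytokine -> cytokine, with cis-pQTL and cis-eQTL instruments;
significant pairs are colocalised at the exposure gene locus and assembled
into a directed cytokine graph with modularity communities.

Direction 3: cytokines -> cardiometabolic outcomes (cis-pQTL, cis-eQTL and
genome-wide criteria); colocalisation is run for pairs with nominal MR
evidence (main p < 0.05); binary outcomes are additionally reported as odds
ratios per 1 SD of the exposure.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .coloc import ColocConfig, ColocResult, colocalise
from .instruments import (InstrumentSet, select_cis_eqtl, select_cis_pqtl,
                          select_genomewide_cytokine, select_trait_instruments)
from .mr import MRConfig, MRResult, or_from_beta, run_mr
from .sumstats import GeneLocus, LDMatrix, SummaryStats, harmonise

__all__ = [
    "PipelineConfig",
    "bonferroni_threshold",
    "run_direction_1",
    "run_direction_2",
    "run_direction_3",
    "compare_criteria",
    "CytokineGraph",
    "detect_communities",
    "z_matrix",
]

log = logging.getLogger("cytomr")

#: tidy result-table columns (one row per exposure/outcome/criterion/method)
ROW_COLUMNS = [
    "exposure", "outcome", "criterion", "method", "role", "n_snp",
    "beta", "se", "ci_low", "ci_high", "p", "z", "significant",
    "or_", "or_low", "or_high",
    "coloc_pp_shared", "coloc_pp_distinct", "coloc_supported", "extras",
]


@dataclass
class PipelineConfig:
    """Thresholds, windows and priors for a full pipeline run."""

    alpha: float = 0.05
    gwas_p_max: float = 5e-8
    trait_p_overrides: dict = field(default_factory=dict)  # e.g. fasting insulin 1e-6
    cis_window: int = 500_000
    cis_pqtl_p: float = 1e-4
    eqtl_expr_p: float = 1e-4
    eqtl_cyt_p: float = 0.05
    clump_r2: float = 0.001
    palindrome_eaf_limit: float = 0.42
    coloc_nominal_p: float = 0.05
    mr: MRConfig = field(default_factory=MRConfig)
    coloc: ColocConfig = field(default_factory=ColocConfig)


def bonferroni_threshold(alpha: float, n_outcomes: int) -> float:
    """Family-wise threshold alpha / n_outcomes."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_outcomes < 1:
        raise ValueError("n_outcomes must be >= 1")
    return alpha / n_outcomes


def _result_row(exposure: str, outcome: str, criterion: str, res: MRResult,
                threshold: float, binary_outcome: bool = False) -> dict:
    row = {
        "exposure": exposure, "outcome": outcome, "criterion": criterion,
        "method": res.method, "role": res.role, "n_snp": res.n_snp,
        "beta": res.beta, "se": res.se,
        "ci_low": res.ci_low, "ci_high": res.ci_high, "p": res.p,
        "z": res.beta / res.se,
        "significant": (res.role == "main") and (res.p < threshold),
        "or_": np.nan, "or_low": np.nan, "or_high": np.nan,
        "coloc_pp_shared": np.nan, "coloc_pp_distinct": np.nan,
        "coloc_supported": pd.NA,
        "extras": json.dumps(
            {k: v for k, v in res.extras.items()
             if isinstance(v, (int, float, str, list, type(None)))}),
    }
    if binary_outcome:
        row["or_"], row["or_low"], row["or_high"] = or_from_beta(res.beta, res.se)
    return row


def _rows_frame(rows: list[dict]) -> pd.DataFrame:
    if not rows:
        return pd.DataFrame(columns=ROW_COLUMNS)
    return pd.DataFrame(rows)[ROW_COLUMNS]


def _mr_pair(instruments: InstrumentSet, outcome: SummaryStats,
             config: PipelineConfig) -> tuple[list[MRResult], object] | None:
    """Harmonise an instrument table against an outcome and run the suite."""
    exp_ss = SummaryStats(trait_id=instruments.exposure_id,
                          records=instruments.variants)
    try:
        h = harmonise(exp_ss, outcome,
                      palindrome_eaf_limit=config.palindrome_eaf_limit)
    except ValueError as err:
        log.info("skipping %s -> %s: %s", instruments.exposure_id,
                 outcome.trait_id, err)
        return None
    if h.n_snp == 0:
        return None
    return run_mr(h, config.mr), h


def run_direction_1(
    risk_traits: list[SummaryStats],
    cytokines: list[SummaryStats],
    ld: LDMatrix,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Risk factors -> cytokines; Bonferroni over the cytokine outcomes."""
    config = config or PipelineConfig()
    threshold = bonferroni_threshold(config.alpha, len(cytokines))
    rows: list[dict] = []
    for trait in risk_traits:
        p_max = config.trait_p_overrides.get(trait.trait_id, config.gwas_p_max)
        inst = select_trait_instruments(trait, ld, p_max=p_max)
        if inst.is_empty:
            log.info("no instruments for %s; skipped", trait.trait_id)
            continue
        for cyt in cytokines:
            out = _mr_pair(inst, cyt, config)
            if out is None:
                continue
            results, _ = out
            for res in results:
                rows.append(_result_row(trait.trait_id, cyt.trait_id,
                                        "trait_gwas", res, threshold))
    return _rows_frame(rows)


@dataclass
class CytokineGraph:
    """Directed cytokine-to-cytokine causal graph with community labels."""

    graph: nx.MultiDiGraph
    communities: dict = field(default_factory=dict)
    p_threshold: float = np.nan

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, **data}
            for u, v, data in self.graph.edges(data=True)
        ]
        cols = ["source", "target", "beta", "p", "criterion", "coloc_supported"]
        return pd.DataFrame(rows, columns=cols)


def detect_communities(graph: nx.MultiDiGraph) -> dict:
    """Greedy modularity communities on the undirected |beta|-weighted
    projection, with deterministic tie-breaking by node name."""
    und = nx.Graph()
    und.add_nodes_from(sorted(graph.nodes))
    for u, v, data in graph.edges(data=True):
        w = abs(data.get("beta", 1.0))
        if und.has_edge(u, v):
            und[u][v]["weight"] += w
        else:
            und.add_edge(u, v, weight=w)
    labels: dict = {}
    connected = [n for n in und.nodes if und.degree(n) > 0]
    if connected:
        comms = nx.community.greedy_modularity_communities(
            und.subgraph(connected), weight="weight")
        comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
        for i, comm in enumerate(comms):
            for node in comm:
                labels[node] = i
    iso = len(set(labels.values()))
    for n in sorted(und.nodes):
        if n not in labels:
            labels[n] = iso
            iso += 1
    return labels


def _coloc_at_locus(
    exposure_ss: SummaryStats,
    outcome_ss: SummaryStats,
    locus: GeneLocus,
    config: PipelineConfig,
) -> ColocResult | None:
    lo, hi = locus.window(config.cis_window)
    t1 = exposure_ss.subset_window(locus.chrom, lo, hi)
    t2 = outcome_ss.subset_window(locus.chrom, lo, hi)
    if len(t1) == 0 or len(t2) == 0:
        return None
    try:
        return colocalise(t1, t2, config.coloc)
    except ValueError as err:
        log.info("coloc skipped at %s: %s", locus.gene, err)
        return None


def run_direction_2(
    cytokines: list[SummaryStats],
    ld: LDMatrix,
    loci: dict[str, GeneLocus],
    config: PipelineConfig | None = None,
    expression: dict[str, SummaryStats] | None = None,
    n_outcomes: int | None = None,
) -> tuple[pd.DataFrame, CytokineGraph]:
    """Cytokine -> cytokine MR with cis instruments, coloc and the network.

    ``loci`` maps cytokine trait id -> gene locus; ``expression`` maps the
    same ids to cross-tissue aggregated eQTL summary statistics (enables the
    cis-eQTL criterion). The Bonferroni family size defaults to the number of
    outcome cytokines per exposure and can be pinned with ``n_outcomes``.
    """
    config = config or PipelineConfig()
    by_id = {c.trait_id: c for c in cytokines}
    family = n_outcomes if n_outcomes is not None else max(len(cytokines) - 1, 1)
    threshold = bonferroni_threshold(config.alpha, family)
    rows: list[dict] = []
    graph = nx.MultiDiGraph()
    graph.add_nodes_from(sorted(by_id))

    for exp_id, exposure in sorted(by_id.items()):
        locus = loci.get(exp_id)
        if locus is None:
            log.info("no gene locus for %s; skipped as exposure", exp_id)
            continue
        inst_sets = [select_cis_pqtl(exposure, locus, ld,
                                     window=config.cis_window,
                                     p_max=config.cis_pqtl_p)]
        if expression and exp_id in expression:
            inst_sets.append(select_cis_eqtl(
                exposure, expression[exp_id], locus, ld,
                window=config.cis_window, p_expr_max=config.eqtl_expr_p,
                p_cyt_max=config.eqtl_cyt_p))
        for inst in inst_sets:
            if inst.is_empty:
                continue
            for out_id, outcome in sorted(by_id.items()):
                if out_id == exp_id:
                    continue
                out = _mr_pair(inst, outcome, config)
                if out is None:
                    continue
                results, _ = out
                main = results[0]
                significant = main.p < threshold
                coloc_res = None
                if significant:
                    coloc_res = _coloc_at_locus(exposure, outcome, locus, config)
                for res in results:
                    row = _result_row(exp_id, out_id, inst.criterion, res,
                                      threshold)
                    if res.role == "main" and coloc_res is not None:
                        row["coloc_pp_shared"] = coloc_res.pp_shared
                        row["coloc_pp_distinct"] = coloc_res.pp_distinct
                        row["coloc_supported"] = coloc_res.supported
                    rows.append(row)
                if significant:
                    graph.add_edge(
                        exp_id, out_id, beta=main.beta, p=main.p,
                        criterion=inst.criterion,
                        coloc_supported=bool(coloc_res.supported)
                        if coloc_res is not None else False,
                    )
    cg = CytokineGraph(graph=graph, communities=detect_communities(graph),
                       p_threshold=threshold)
    return _rows_frame(rows), cg


def run_direction_3(
    cytokines: list[SummaryStats],
    outcomes: list[SummaryStats],
    ld: LDMatrix,
    loci: dict[str, GeneLocus],
    config: PipelineConfig | None = None,
    expression: dict[str, SummaryStats] | None = None,
) -> pd.DataFrame:
    """Cytokines -> cardiometabolic outcomes under all three criteria.

    The Bonferroni family is the number of outcome phenotypes; coloc runs at
    the exposure locus for pairs with nominal MR evidence (main p < 0.05);
    binary outcomes are also reported as odds ratios per 1 SD.
    """
    config = config or PipelineConfig()
    threshold = bonferroni_threshold(config.alpha, len(outcomes))
    rows: list[dict] = []
    for exposure in cytokines:
        exp_id = exposure.trait_id
        locus = loci.get(exp_id)
        inst_sets: list[InstrumentSet] = []
        if locus is not None:
            inst_sets.append(select_cis_pqtl(
                exposure, locus, ld, window=config.cis_window,
                p_max=config.cis_pqtl_p))
            if expression and exp_id in expression:
                inst_sets.append(select_cis_eqtl(
                    exposure, expression[exp_id], locus, ld,
                    window=config.cis_window, p_expr_max=config.eqtl_expr_p,
                    p_cyt_max=config.eqtl_cyt_p))
        inst_sets.append(select_genomewide_cytokine(exposure, ld,
                                                    p_max=config.gwas_p_max))
        for inst in inst_sets:
            if inst.is_empty:
                continue
            for outcome in outcomes:
                res_h = _mr_pair(inst, outcome, config)
                if res_h is None:
                    continue
                results, _ = res_h
                main = results[0]
                binary = outcome.trait_type == "binary"
                coloc_res = None
                if main.p < config.coloc_nominal_p and locus is not None:
                    coloc_res = _coloc_at_locus(exposure, outcome, locus,
                                                config)
                for res in results:
                    row = _result_row(exp_id, outcome.trait_id, inst.criterion,
                                      res, threshold, binary_outcome=binary)
                    if res.role == "main" and coloc_res is not None:
                        row["coloc_pp_shared"] = coloc_res.pp_shared
                        row["coloc_pp_distinct"] = coloc_res.pp_distinct
                        row["coloc_supported"] = coloc_res.supported
                    rows.append(row)
    return _rows_frame(rows)


def compare_criteria(rows_a: pd.DataFrame, rows_b: pd.DataFrame
                     ) -> tuple[float, int]:
    """Pearson correlation between main-method betas of the exposure/outcome
    pairs present under both instrument criteria."""
    main_a = rows_a.loc[rows_a["role"] == "main",
                        ["exposure", "outcome", "beta"]]
    main_b = rows_b.loc[rows_b["role"] == "main",
                        ["exposure", "outcome", "beta"]]
    merged = main_a.merge(main_b, on=["exposure", "outcome"],
                          suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise ValueError(
            f"need >= 3 shared exposure/outcome pairs, got {len(merged)}")
    r, _ = stats.pearsonr(merged["beta_a"], merged["beta_b"])
    return float(r), len(merged)


def z_matrix(rows: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Exposure x outcome table of z scores with significance asterisks."""
    main = rows.loc[rows["role"] == "main"]
    cell = main.apply(
        lambda r: f"{r['z']:.2f}" + ("*" if r["p"] < threshold else ""),
        axis=1)
    out = main.assign(cell=cell).pivot_table(
        index="exposure", columns="outcome", values="cell", aggfunc="first")
    return out
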