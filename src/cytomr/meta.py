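"""Fixed-effects inverse-variance-weighted meta-analysis of GWAS cohorts,
and cross-tissue aggregation of expression QTL associations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import RECORD_COLUMNS, SummaryStats, align_to_reference

__all__ = ["meta_fixed", "aggregate_tissues", "TissueAggregate"]


def meta_fixed(studies: list[SummaryStats], trait_id: str | None = None
               ) -> SummaryStats:
    """Pool per-cohort associations with inverse-variance fixed-effects weights.

    Per variant, with per-study weights w_i = 1/se_i²:
    beta = sum(w_i * beta_i) / sum(w_i), se = (sum w_i)^(-1/2), and a
    two-sided normal p on beta/se. Studies are oriented to the allele labels
    of the first study carrying each (chrom, pos); variants present in any
    study are emitted (k_studies records how many contributed); variants
    whose alleles cannot be reconciled with the reference orientation are
    dropped and counted in ``.read_report``.
    """
    if not studies:
        raise ValueError("meta_fixed needs at least one study")

    # build the allele reference incrementally: first study wins per position
    ref_frames: list[pd.DataFrame] = []
    seen = pd.DataFrame(columns=["chrom", "pos"])
    for st in studies:
        rec = st.records
        new = rec.merge(seen, on=["chrom", "pos"], how="left", indicator=True)
        new = new.loc[new["_merge"] == "left_only", RECORD_COLUMNS]
        if len(new):
            ref_frames.append(new[["chrom", "pos", "effect_allele", "other_allele"]])
            seen = pd.concat([seen, new[["chrom", "pos"]]], ignore_index=True)
    reference = pd.concat(ref_frames, ignore_index=True)

    n_dropped = 0
    aligned = []
    for i, st in enumerate(studies):
        adf, bad = align_to_reference(st.records[RECORD_COLUMNS], reference)
        n_dropped += bad
        adf = adf.assign(_study=i)
        aligned.append(adf)
    allrec = pd.concat(aligned, ignore_index=True)
    allrec = allrec.loc[np.isfinite(allrec["se"]) & (allrec["se"] > 0)]

    w = 1.0 / allrec["se"] ** 2
    allrec = allrec.assign(_w=w, _wb=w * allrec["beta"])
    grp = allrec.groupby(["chrom", "pos"], sort=True)
    agg = grp.agg(
        variant_id=("variant_id", "first"),
        effect_allele=("effect_allele", "first"),
        other_allele=("other_allele", "first"),
        eaf=("eaf", "mean"),
        n=("n", "sum"),
        k_studies=("_study", "nunique"),
        sum_w=("_w", "sum"),
        sum_wb=("_wb", "sum"),
    ).reset_index()

    beta = agg["sum_wb"] / agg["sum_w"]
    se = 1.0 / np.sqrt(agg["sum_w"])
    z = beta / se
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)

    records = pd.DataFrame({
        "variant_id": agg["variant_id"],
        "chrom": agg["chrom"],
        "pos": agg["pos"],
        "effect_allele": agg["effect_allele"],
        "other_allele": agg["other_allele"],
        "eaf": agg["eaf"],
        "beta": beta,
        "se": se,
        "p": p,
        "n": agg["n"].astype(int),
    })[RECORD_COLUMNS]
    records = records.sort_values(["chrom", "pos"]).reset_index(drop=True)

    first = studies[0]
    out = SummaryStats(
        trait_id=trait_id or first.trait_id,
        trait_type=first.trait_type,
        tissue=first.tissue if first.trait_type == "expression" else None,
        records=records,
    )
    out.read_report = {
        "k_studies": len(studies),
        "n_variants": len(records),
        "n_dropped_irreconcilable": n_dropped,
    }
    out.read_report["k_per_variant"] = agg["k_studies"].to_numpy()
    return out


@dataclass
class TissueAggregate:
    """Cross-tissue pooled eQTL associations plus the z-score comparison table.

    ``z_table`` has one row per variant with the cross-tissue z and, when a
    whole-blood tissue contributed, the blood-only z.
    """

    sumstats: SummaryStats
    z_table: pd.DataFrame = field(repr=False)


def aggregate_tissues(
    eqtls: list[SummaryStats],
    gene: str,
    method: str = "ivw",
    blood_tissue: str = "whole_blood",
) -> TissueAggregate:
    """Aggregate per-tissue eQTL associations for one gene across tissues.

    ``method='ivw'`` (default) pools with the same fixed-effects machinery as
    the cohort meta-analysis; ``method='stouffer'`` combines sample-size
    weighted z scores instead (z = sum(sqrt(n_i) z_i) / sqrt(sum n_i), with
    beta/se back-filled on the pooled-precision scale so the record remains a
    valid association).
    """
    gene_stats = [e for e in eqtls if e.trait_id == gene]
    if not gene_stats:
        raise ValueError(f"gene {gene!r} absent from all tissue eQTL sets")
    for e in gene_stats:
        if e.trait_type != "expression":
            raise ValueError(f"{e.trait_id} is not an expression trait")

    pooled = meta_fixed(gene_stats, trait_id=gene)
    pooled.tissue = "cross_tissue"

    if method == "stouffer":
        frames = []
        for i, e in enumerate(gene_stats):
            f = e.records[["chrom", "pos", "beta", "se", "n"]].copy()
            f["z"] = f["beta"] / f["se"]
            frames.append(f)
        cat = pd.concat(frames, ignore_index=True)
        cat["wz"] = np.sqrt(cat["n"]) * cat["z"]
        g = cat.groupby(["chrom", "pos"], sort=True).agg(
            sum_wz=("wz", "sum"), sum_n=("n", "sum"))
        z_comb = (g["sum_wz"] / np.sqrt(g["sum_n"])).reindex(
            pd.MultiIndex.from_frame(pooled.records[["chrom", "pos"]]))
        se = pooled.records["se"].to_numpy()
        pooled.records["beta"] = z_comb.to_numpy() * se
        pooled.records["p"] = np.clip(
            2.0 * stats.norm.sf(np.abs(z_comb.to_numpy())), np.nextafter(0, 1), 1.0)
    elif method != "ivw":
        raise ValueError(f"unknown aggregation method {method!r}")

    z_table = pooled.records[["variant_id", "chrom", "pos"]].copy()
    z_table["z_cross_tissue"] = pooled.z
    blood = [e for e in gene_stats if e.tissue == blood_tissue]
    if blood:
        b = blood[0].records[["chrom", "pos"]].copy()
        b["z_blood"] = blood[0].z
        z_table = z_table.merge(b, on=["chrom", "pos"], how="left")
    return TissueAggregate(sumstats=pooled, z_table=z_table)
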