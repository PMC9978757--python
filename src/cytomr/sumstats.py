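"""GWAS summary-statistics data model, file I/O and allele harmonisation.

The central containers are :class:`SummaryStats` (one trait's per-variant
association records), :class:`LDMatrix` (pairwise correlation over an ordered
variant list), :class:`GeneLocus` (1-based inclusive gene coordinates) and
:class:`HarmonisedSet` (exposure/outcome effect pairs aligned to a common
effect allele — the input every two-sample MR estimator consumes).

Conventions
-----------
* Coordinates are 1-based inclusive everywhere internally; BED input is
  converted on read.
* Variant identity for joins is ``(chrom, pos)``; alleles are reconciled
  afterwards, because variant-id dialects (rsID vs chr:pos) differ between
  sources.
* Betas are per copy of the effect allele; SD units for quantitative traits,
  log-odds for binary traits.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RECORD_COLUMNS",
    "DEFAULT_COLUMN_MAP",
    "GeneLocus",
    "LDMatrix",
    "SummaryStats",
    "HarmonisedSet",
    "HarmoniseReport",
    "read_sumstats",
    "write_sumstats",
    "read_ld_matrix",
    "write_ld_matrix",
    "read_gene_loci_bed",
    "harmonise",
    "align_to_reference",
]

#: canonical internal record columns, in storage order
RECORD_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "p", "n",
]

#: default external file header -> internal field mapping
DEFAULT_COLUMN_MAP = {
    "variant_id": "SNP", "chrom": "CHR", "pos": "POS",
    "effect_allele": "EA", "other_allele": "OA",
    "eaf": "EAF", "beta": "BETA", "se": "SE", "p": "P", "n": "N",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _complement(allele: str) -> str:
    return allele.translate(_COMPLEMENT)


def _is_palindromic(ea: str, oa: str) -> bool:
    return len(ea) == 1 and len(oa) == 1 and _complement(ea) == oa


@dataclass(frozen=True)
class GeneLocus:
    """Gene body coordinates, 1-based inclusive."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"GeneLocus {self.gene}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValueError(f"GeneLocus {self.gene}: start must be >= 1")

    def window(self, flank: int) -> tuple[int, int]:
        """Extended cis window [start - flank, end + flank], inclusive."""
        return max(1, self.start - flank), self.end + flank


@dataclass
class LDMatrix:
    """Square pairwise-correlation (r) matrix over an ordered variant list.

    ``r`` holds signed correlations; r² is ``r**2`` elementwise.
    """

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.variant_ids)
        if self.r.shape != (k, k):
            raise ValueError(f"LD matrix shape {self.r.shape} != ({k}, {k})")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-6):
            raise ValueError("LD matrix diagonal is not 1")
        if np.any(np.abs(self.r) > 1 + 1e-8):
            raise ValueError("LD entries must lie in [-1, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}
        if len(self._index) != k:
            raise ValueError("duplicate variant ids in LD matrix")

    def index(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} missing from LD matrix") from None

    def r2(self, a: str, b: str) -> float:
        """Squared correlation between two variants."""
        return float(self.r[self.index(a), self.index(b)] ** 2)

    @classmethod
    def from_dosages(cls, dosages: np.ndarray, variant_ids: list[str]) -> "LDMatrix":
        """Empirical LD from a (variants x individuals) dosage matrix.

        Monomorphic variants get r = 0 off-diagonal (they carry no LD
        information and must never block clumping).
        """
        d = np.asarray(dosages, dtype=float)
        sd = d.std(axis=1)
        ok = sd > 0
        r = np.eye(d.shape[0])
        if ok.sum() >= 2:
            sub = np.corrcoef(d[ok])
            r[np.ix_(ok, ok)] = sub
        np.fill_diagonal(r, 1.0)
        r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(r, 1.0)
        return cls(list(variant_ids), r)


def _validate_records(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records missing required columns: {missing}")
    return df.loc[:, RECORD_COLUMNS].reset_index(drop=True)


@dataclass
class SummaryStats:
    """One trait's GWAS summary statistics.

    ``records`` is a DataFrame with columns :data:`RECORD_COLUMNS`; one row
    per variant, variant ids unique.
    """

    trait_id: str
    trait_type: str = "quantitative"  # cytokine | quantitative | binary | expression
    tissue: str | None = None
    records: pd.DataFrame = field(default_factory=pd.DataFrame)
    read_report: dict = field(default_factory=dict, repr=False, compare=False)

    _TRAIT_TYPES = ("cytokine", "quantitative", "binary", "expression")

    def __post_init__(self) -> None:
        if self.trait_type not in self._TRAIT_TYPES:
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "expression" and not self.tissue:
            raise ValueError("expression traits require a tissue label")
        if len(self.records):
            self.records = _validate_records(self.records)
            dup = self.records["variant_id"].duplicated()
            if dup.any():
                raise ValueError(
                    f"duplicate variant ids in {self.trait_id}: "
                    f"{self.records.loc[dup, 'variant_id'].tolist()[:5]}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def z(self) -> np.ndarray:
        """Per-variant z score beta/se."""
        return (self.records["beta"] / self.records["se"]).to_numpy()

    def subset_window(self, chrom: str, start: int, end: int) -> "SummaryStats":
        """Records on ``chrom`` with start <= pos <= end (inclusive)."""
        m = (
            (self.records["chrom"].astype(str) == str(chrom))
            & (self.records["pos"] >= start)
            & (self.records["pos"] <= end)
        )
        return dataclasses.replace(self, records=self.records.loc[m], read_report={})


def read_sumstats(
    path,
    column_map: dict | None = None,
    trait_id: str | None = None,
    trait_type: str = "quantitative",
    tissue: str | None = None,
    sep: str = "\t",
) -> SummaryStats:
    """Read a delimited summary-statistics table (gzip-transparent).

    Rows with missing or invalid required fields (se <= 0, p outside (0, 1],
    eaf outside (0, 1), n < 1, effect allele == other allele) are dropped and
    counted in the returned object's ``read_report``.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=sep, dtype={cmap["chrom"]: str})
    for internal, external in cmap.items():
        if external not in raw.columns:
            raise ValueError(
                f"required column {external!r} (field {internal!r}) "
                f"missing from {path}"
            )
    df = raw.rename(columns={v: k for k, v in cmap.items()})
    df = df.loc[:, RECORD_COLUMNS].copy()
    n_in = len(df)

    for col in ("pos", "eaf", "beta", "se", "p", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    df["chrom"] = df["chrom"].astype(str)

    valid = (
        df[RECORD_COLUMNS].notna().all(axis=1)
        & (df["se"] > 0)
        & np.isfinite(df["se"])
        & (df["p"] > 0)
        & (df["p"] <= 1)
        & (df["eaf"] > 0)
        & (df["eaf"] < 1)
        & (df["n"] >= 1)
        & (df["pos"] >= 1)
        & (df["effect_allele"] != df["other_allele"])
    )
    df = df.loc[valid].copy()
    if df.empty:
        raise ValueError(f"no valid rows in {path}")
    df["pos"] = df["pos"].astype(int)
    df["n"] = df["n"].astype(int)

    ss = SummaryStats(
        trait_id=trait_id or str(path),
        trait_type=trait_type,
        tissue=tissue,
        records=df,
    )
    ss.read_report = {"n_read": n_in, "n_valid": len(df), "n_dropped": n_in - len(df)}
    return ss


def write_sumstats(ss: SummaryStats, path, column_map: dict | None = None,
                   sep: str = "\t") -> None:
    """Write a summary-statistics table with the default external header."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    out = ss.records.rename(columns=cmap)
    out.to_csv(path, sep=sep, index=False)


def read_ld_matrix(matrix_path, variants_path) -> LDMatrix:
    """Plain-text square r matrix plus one-variant-per-line sidecar."""
    with open(variants_path) as fh:
        variants = [line.strip() for line in fh if line.strip()]
    r = np.loadtxt(matrix_path)
    if r.ndim == 0:
        r = r.reshape(1, 1)
    return LDMatrix(variants, r)


def write_ld_matrix(ld: LDMatrix, matrix_path, variants_path) -> None:
    np.savetxt(matrix_path, ld.r, fmt="%.10g")
    with open(variants_path, "w") as fh:
        fh.write("\n".join(ld.variant_ids) + "\n")


def read_gene_loci_bed(path) -> list[GeneLocus]:
    """Read gene loci from BED (0-based half-open -> 1-based inclusive)."""
    loci = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            gene = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            loci.append(GeneLocus(gene=gene, chrom=chrom, start=start + 1, end=end))
    return loci


# ---------------------------------------------------------------------------
# harmonisation
# ---------------------------------------------------------------------------

#: HarmonisedSet table columns
HARMONISED_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta_exp", "se_exp", "p_exp", "eaf_exp",
    "beta_out", "se_out", "p_out", "eaf_out",
]


@dataclass
class HarmoniseReport:
    """Per-reason drop counts from one harmonisation pass."""

    n_exposure: int = 0
    n_outcome: int = 0
    n_intersect: int = 0
    n_kept: int = 0
    dropped: dict = field(default_factory=dict)

    def add(self, reason: str, count: int = 1) -> None:
        if count:
            self.dropped[reason] = self.dropped.get(reason, 0) + count


@dataclass
class HarmonisedSet:
    """Exposure/outcome effects aligned to a common effect allele per variant."""

    exposure_id: str
    outcome_id: str
    table: pd.DataFrame
    report: HarmoniseReport = field(default_factory=HarmoniseReport,
                                    repr=False, compare=False)

    def __post_init__(self) -> None:
        missing = [c for c in HARMONISED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"harmonised table missing columns: {missing}")
        if len(self.table):
            if (self.table["se_exp"] <= 0).any() or (self.table["se_out"] <= 0).any():
                raise ValueError("harmonised set contains non-positive se")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_snp(self) -> int:
        return len(self.table)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exp, se_exp, beta_out, se_out) as float arrays."""
        t = self.table
        return (
            t["beta_exp"].to_numpy(float), t["se_exp"].to_numpy(float),
            t["beta_out"].to_numpy(float), t["se_out"].to_numpy(float),
        )

    def subset(self, mask) -> "HarmonisedSet":
        return HarmonisedSet(self.exposure_id, self.outcome_id,
                             self.table.loc[mask].copy())

    def to_sumstats_pair(self, n_exp: int = 0, n_out: int = 0
                         ) -> tuple[SummaryStats, SummaryStats]:
        """Re-materialise the aligned sides as SummaryStats (for re-harmonising)."""
        def side(suffix, trait):
            df = self.table[
                ["variant_id", "chrom", "pos", "effect_allele", "other_allele"]
            ].copy()
            df["eaf"] = self.table[f"eaf_{suffix}"]
            df["beta"] = self.table[f"beta_{suffix}"]
            df["se"] = self.table[f"se_{suffix}"]
            df["p"] = self.table[f"p_{suffix}"]
            df["n"] = n_exp if suffix == "exp" else n_out
            df["n"] = df["n"].clip(lower=1)
            return SummaryStats(trait_id=trait, records=df)
        return side("exp", self.exposure_id), side("out", self.outcome_id)


def _drop_indels_multiallelic(records: pd.DataFrame, report: HarmoniseReport,
                              label: str) -> pd.DataFrame:
    snp = (records["effect_allele"].str.len() == 1) & \
          (records["other_allele"].str.len() == 1)
    report.add(f"indel_{label}", int((~snp).sum()))
    records = records.loc[snp]
    dup = records.duplicated(subset=["chrom", "pos"], keep=False)
    report.add(f"multiallelic_{label}", int(dup.sum()))
    return records.loc[~dup]


def harmonise(
    exposure: SummaryStats,
    outcome: SummaryStats,
    palindrome_eaf_limit: float = 0.42,
) -> HarmonisedSet:
    """Align outcome effects to the exposure's effect alleles.

    Variants are intersected on (chrom, pos). Outcome alleles that are the
    exposure's swapped (or strand-complement / complement-swapped) pair have
    beta_out sign-flipped and eaf_out replaced by 1 - eaf as needed.
    Palindromic variants (A/T, C/G) are kept only when both traits' EAF lie
    strictly on the same side of 0.5 and each minor-allele frequency is below
    ``palindrome_eaf_limit``; irreconcilable alleles, indels and multi-allelic
    positions are dropped. Drop reasons are tallied in ``.report``.
    """
    if not 0 < palindrome_eaf_limit <= 0.5:
        raise ValueError("palindrome_eaf_limit must be in (0, 0.5]")
    rep = HarmoniseReport(n_exposure=len(exposure), n_outcome=len(outcome))

    exp = _drop_indels_multiallelic(exposure.records, rep, "exposure")
    out = _drop_indels_multiallelic(outcome.records, rep, "outcome")
    m = exp.merge(out, on=["chrom", "pos"], suffixes=("_exp", "_out"))
    rep.n_intersect = len(m)
    if m.empty:
        raise ValueError(
            f"no shared (chrom, pos) variants between {exposure.trait_id} "
            f"and {outcome.trait_id}"
        )

    ea_e = m["effect_allele_exp"]
    oa_e = m["other_allele_exp"]
    ea_o = m["effect_allele_out"]
    oa_o = m["other_allele_out"]
    ea_e_c = ea_e.map(_complement)
    oa_e_c = oa_e.map(_complement)

    same = (ea_o == ea_e) & (oa_o == oa_e)
    swap = (ea_o == oa_e) & (oa_o == ea_e)
    comp = (ea_o == ea_e_c) & (oa_o == oa_e_c)
    comp_swap = (ea_o == oa_e_c) & (oa_o == ea_e_c)
    palin = np.array([_is_palindromic(a, b) for a, b in zip(ea_e, oa_e)])

    reconcilable = same | swap | comp | comp_swap
    rep.add("irreconcilable_alleles", int((~reconcilable).sum()))

    # palindromic: strand is unknowable from alleles; infer from EAF.
    # keep only same-side-of-0.5 + informative frequency, aligned as-is.
    eaf_e = m["eaf_exp"]
    eaf_o = m["eaf_out"]
    pal_ok = (
        ((eaf_e - 0.5) * (eaf_o - 0.5) > 0)
        & (np.minimum(eaf_e, 1 - eaf_e) < palindrome_eaf_limit)
        & (np.minimum(eaf_o, 1 - eaf_o) < palindrome_eaf_limit)
    )
    rep.add("palindromic_ambiguous", int((palin & reconcilable & ~pal_ok).sum()))

    keep = reconcilable & (~palin | pal_ok)
    flip = (swap | comp_swap) & ~palin  # palindromic kept rows are eaf-aligned
    m = m.loc[keep].copy()
    flip = flip[keep]

    m.loc[flip, "beta_out"] = -m.loc[flip, "beta_out"]
    m.loc[flip, "eaf_out"] = 1 - m.loc[flip, "eaf_out"]

    table = pd.DataFrame({
        "variant_id": m["variant_id_exp"],
        "chrom": m["chrom"],
        "pos": m["pos"],
        "effect_allele": m["effect_allele_exp"],
        "other_allele": m["other_allele_exp"],
        "beta_exp": m["beta_exp"], "se_exp": m["se_exp"],
        "p_exp": m["p_exp"], "eaf_exp": m["eaf_exp"],
        "beta_out": m["beta_out"], "se_out": m["se_out"],
        "p_out": m["p_out"], "eaf_out": m["eaf_out"],
    })
    rep.n_kept = len(table)
    if table.empty:
        raise ValueError(
            f"harmonisation of {exposure.trait_id} vs {outcome.trait_id} "
            f"left no variants (drops: {rep.dropped})"
        )
    return HarmonisedSet(exposure.trait_id, outcome.trait_id, table, rep)


def align_to_reference(records: pd.DataFrame, reference: pd.DataFrame
                       ) -> tuple[pd.DataFrame, int]:
    """Orient ``records`` to the allele labels of ``reference`` rows.

    Used by the fixed-effects meta-analysis, where all studies share a strand;
    only same/swapped allele pairs are reconciled. Returns the aligned frame
    (reference orientation) and the count of irreconcilable rows dropped.
    Variants absent from the reference pass through unchanged.
    """
    ref = reference[["chrom", "pos", "effect_allele", "other_allele"]].rename(
        columns={"effect_allele": "_ref_ea", "other_allele": "_ref_oa"}
    )
    m = records.merge(ref, on=["chrom", "pos"], how="left")
    has_ref = m["_ref_ea"].notna()
    same = (m["effect_allele"] == m["_ref_ea"]) & (m["other_allele"] == m["_ref_oa"])
    swap = (m["effect_allele"] == m["_ref_oa"]) & (m["other_allele"] == m["_ref_ea"])
    bad = has_ref & ~(same | swap)
    m.loc[swap, "beta"] = -m.loc[swap, "beta"]
    m.loc[swap, "eaf"] = 1 - m.loc[swap, "eaf"]
    m.loc[swap, ["effect_allele", "other_allele"]] = (
        m.loc[swap, ["_ref_ea", "_ref_oa"]].to_numpy()
    )
    aligned = m.loc[~bad, RECORD_COLUMNS].reset_index(drop=True)
    return aligned, int(bad.sum())
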