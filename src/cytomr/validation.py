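"""Monte-Carlo validation studies for the estimator suite and pipeline.

Each study simulates data with known ground truth — either full synthetic
cohorts (via :mod:`cytomr.simulate`) or summary-level instrument tables —
runs the package's own estimators on it, and reports a calibration or
recovery rate. They are the package's statistical self-checks: coverage of
the IVW confidence interval, null calibration of the PRESSO global test and
the pipeline's Bonferroni families, robustness of the weighted median under
directional pleiotropy, discrimination of the colocalisation posteriors, and
end-to-end recovery of a simulated cytokine cascade.

Every study takes a ``seed`` and derives independent per-replicate streams
from it, so results are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .coloc import ColocConfig, colocalise
from .mr import MRConfig, Z95, ivw, presso, weighted_median
from .pipeline import PipelineConfig, run_direction_1, run_direction_2
from .simulate import SimConfig, TraitSpec, run_gwas, simulate_cohort, theoretical_ld
from .sumstats import GeneLocus, HarmonisedSet, harmonise

__all__ = [
    "harmonised_from_arrays",
    "simulate_two_sample",
    "ivw_coverage",
    "presso_null_calibration",
    "presso_outlier_detection",
    "weighted_median_robustness",
    "coloc_discrimination",
    "cascade_recovery",
    "direction1_null_fpr",
]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Independent 31-bit child seeds from one master seed."""
    return np.random.default_rng(seed).integers(0, 2 ** 31 - 1, size=n)


def harmonised_from_arrays(bx, sx, by, sy, p_exp=None, p_out=None
                           ) -> HarmonisedSet:
    """Build a HarmonisedSet directly from effect arrays (summary-level
    simulation helper)."""
    bx = np.asarray(bx, float)
    n = len(bx)
    sx = np.asarray(sx, float)
    by = np.asarray(by, float)
    sy = np.asarray(sy, float)
    z_exp = np.where(sx > 0, bx / sx, 0.0)
    z_out = np.where(sy > 0, by / sy, 0.0)
    table = pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(n)],
        "chrom": "1",
        "pos": np.arange(1, n + 1) * 1000,
        "effect_allele": "A",
        "other_allele": "G",
        "beta_exp": bx, "se_exp": sx,
        "p_exp": p_exp if p_exp is not None
        else np.clip(2 * stats.norm.sf(np.abs(z_exp)), 1e-300, 1.0),
        "eaf_exp": 0.3,
        "beta_out": by, "se_out": sy,
        "p_out": p_out if p_out is not None
        else np.clip(2 * stats.norm.sf(np.abs(z_out)), 1e-300, 1.0),
        "eaf_out": 0.3,
    })
    return HarmonisedSet("exposure", "outcome", table)


def simulate_two_sample(
    seed: int,
    n_instruments: int = 10,
    true_beta: float = 0.2,
    n_gwas: int = 10_000,
    exposure_effects: tuple[float, float] = (0.1, 0.2),
) -> HarmonisedSet:
    """Two independent cohorts; exposure X with ``n_instruments`` causal
    variants, outcome Y = true_beta * X + noise; GWAS in each cohort; the
    known causal variants are the instruments (no selection step, so no
    winner's-curse bias enters the coverage check)."""
    rng = np.random.default_rng(seed)
    effects = rng.uniform(*exposure_effects, size=n_instruments)
    signs = rng.choice([-1.0, 1.0], size=n_instruments)
    causal = [(i, float(b * s)) for i, (b, s) in enumerate(zip(effects, signs))]
    base = dict(
        n_individuals=n_gwas,
        n_variants=n_instruments,
        ld_block_size=1,  # independent instruments
        ld_rho=0.0,
        traits={"X": TraitSpec("quantitative", noise_sd=1.0),
                "Y": TraitSpec("quantitative", noise_sd=1.0)},
        causal_map={"X": causal},
        trait_dag=[("X", "Y", true_beta)],
    )
    cohort_exp = simulate_cohort(SimConfig(**base, seed=int(rng.integers(2 ** 31))))
    cohort_out = simulate_cohort(SimConfig(**base, seed=int(rng.integers(2 ** 31))))
    gx = run_gwas(cohort_exp, "X")
    gy = run_gwas(cohort_out, "Y")
    return harmonise(gx, gy)


def ivw_coverage(
    n_reps: int = 500,
    n_instruments: int = 10,
    true_beta: float = 0.2,
    n_gwas: int = 10_000,
    seed: int = 1,
) -> dict:
    """Fraction of replicates whose IVW 95% CI covers the true effect."""
    seeds = _child_seeds(seed, n_reps)
    covered = 0
    for s in seeds:
        h = simulate_two_sample(int(s), n_instruments, true_beta, n_gwas)
        res = ivw(h)
        covered += res.ci_low <= true_beta <= res.ci_high
    return {"coverage": covered / n_reps, "n": n_reps}


def presso_null_calibration(
    n_reps: int = 500,
    n_instruments: int = 10,
    true_beta: float = 0.2,
    n_sim: int = 1000,
    alpha: float = 0.05,
    seed: int = 1,
) -> dict:
    """Rejection rate of the PRESSO global test under no pleiotropy.

    Summary-level simulation: true exposure effects U(0.1, 0.3); observed
    betas add N(0, se) noise with GWAS-scale standard errors; outcome betas
    follow the causal model exactly."""
    seeds = _child_seeds(seed, n_reps)
    rejected = 0
    for s in seeds:
        rng = np.random.default_rng(int(s))
        bx_true = rng.uniform(0.1, 0.3, size=n_instruments)
        sx = np.full(n_instruments, 0.015)
        sy = np.full(n_instruments, 0.015)
        bx = rng.normal(bx_true, sx)
        by = rng.normal(true_beta * bx_true, sy)
        h = harmonised_from_arrays(bx, sx, by, sy)
        res = presso(h, MRConfig(n_sim=n_sim, seed=int(s)))
        rejected += res.extras["presso_global_p"] < alpha
    return {"rejection_rate": rejected / n_reps, "n": n_reps}


def presso_outlier_detection(
    n_reps: int = 200,
    n_instruments: int = 10,
    true_beta: float = 0.2,
    outlier_z: float = 10.0,
    n_sim: int = 1000,
    seed: int = 1,
) -> dict:
    """Fraction of replicates in which a single injected outlier (outcome
    effect shifted by ``outlier_z`` outcome standard errors) is flagged."""
    seeds = _child_seeds(seed, n_reps)
    flagged = 0
    for s in seeds:
        rng = np.random.default_rng(int(s))
        bx_true = rng.uniform(0.1, 0.3, size=n_instruments)
        sx = np.full(n_instruments, 0.015)
        sy = np.full(n_instruments, 0.015)
        bx = rng.normal(bx_true, sx)
        by = rng.normal(true_beta * bx_true, sy)
        j = int(rng.integers(n_instruments))
        by[j] += outlier_z * sy[j]
        h = harmonised_from_arrays(bx, sx, by, sy)
        res = presso(h, MRConfig(n_sim=n_sim, seed=int(s)))
        flagged += f"v{j}" in res.extras["presso_outliers"]
    return {"detection_rate": flagged / n_reps, "n": n_reps}


def weighted_median_robustness(
    n_reps: int = 200,
    n_instruments: int = 10,
    true_beta: float = 0.2,
    pleiotropy_fraction: float = 0.4,
    pleiotropy_effect: float = 0.15,
    n_boot: int = 200,
    seed: int = 1,
) -> dict:
    """Directional-pleiotropy contrast: fraction of replicates where the
    weighted median's absolute bias is below the IVW's.

    A fixed fraction of instruments receive a constant direct outcome effect
    (directional pleiotropy); instruments carrying under half the weight are
    invalid, so the weighted median stays consistent while IVW is biased."""
    seeds = _child_seeds(seed, n_reps)
    n_bad = int(round(pleiotropy_fraction * n_instruments))
    wins = 0
    for s in seeds:
        rng = np.random.default_rng(int(s))
        bx_true = rng.uniform(0.1, 0.3, size=n_instruments)
        sx = np.full(n_instruments, 0.015)
        sy = np.full(n_instruments, 0.015)
        alpha_j = np.zeros(n_instruments)
        bad = rng.choice(n_instruments, size=n_bad, replace=False)
        alpha_j[bad] = pleiotropy_effect
        bx = rng.normal(bx_true, sx)
        by = rng.normal(true_beta * bx_true + alpha_j, sy)
        h = harmonised_from_arrays(bx, sx, by, sy)
        cfg = MRConfig(n_boot=n_boot, seed=int(s))
        bias_ivw = abs(ivw(h, cfg).beta - true_beta)
        bias_wm = abs(weighted_median(h, cfg).beta - true_beta)
        wins += bias_wm < bias_ivw
    return {"wm_win_rate": wins / n_reps, "n": n_reps}


def _locus_cohort(seed: int, shared: bool, n_individuals: int,
                  n_variants: int, ld_rho: float, effect: float) -> tuple:
    """One cohort with two traits at a locus sharing (or not) a causal
    variant; returns the two trait GWAS restricted to the locus."""
    rng = np.random.default_rng(seed)
    block = 10
    if shared:
        v1 = v2 = int(rng.integers(n_variants))
    else:
        # distinct causal variants in linkage equilibrium: different blocks
        b1, b2 = rng.choice(n_variants // block, size=2, replace=False)
        v1 = int(b1) * block + int(rng.integers(block))
        v2 = int(b2) * block + int(rng.integers(block))
    cfg = SimConfig(
        n_individuals=n_individuals,
        n_variants=n_variants,
        ld_block_size=block,
        ld_rho=ld_rho,
        traits={"T1": TraitSpec(), "T2": TraitSpec()},
        causal_map={"T1": [(v1, effect)], "T2": [(v2, effect)]},
        seed=int(rng.integers(2 ** 31)),
    )
    cohort = simulate_cohort(cfg)
    return run_gwas(cohort, "T1"), run_gwas(cohort, "T2")


def coloc_discrimination(
    n_reps: int = 200,
    n_individuals: int = 10_000,
    n_variants: int = 40,
    ld_rho: float = 0.5,
    effect: float = 0.5,
    seed: int = 1,
) -> dict:
    """Shared- vs distinct-causal-variant discrimination rates.

    Shared loci should pass both posterior decision rules; distinct loci
    should give pp_distinct > pp_shared."""
    seeds = _child_seeds(seed, 2 * n_reps)
    cfg = ColocConfig()
    shared_pass = 0
    for s in seeds[:n_reps]:
        t1, t2 = _locus_cohort(int(s), True, n_individuals, n_variants,
                               ld_rho, effect)
        res = colocalise(t1, t2, cfg)
        shared_pass += res.passes_support and res.passes_ratio
    distinct_correct = 0
    for s in seeds[n_reps:]:
        t1, t2 = _locus_cohort(int(s), False, n_individuals, n_variants,
                               ld_rho, effect)
        res = colocalise(t1, t2, cfg)
        distinct_correct += res.pp_distinct > res.pp_shared
    return {
        "shared_pass_rate": shared_pass / n_reps,
        "distinct_correct_rate": distinct_correct / n_reps,
        "n": n_reps,
    }


def cascade_recovery(
    n_reps: int = 100,
    n_individuals: int = 10_000,
    effect_cis: float = 0.3,
    effect_cascade: float = 0.5,
    seed: int = 1,
) -> dict:
    """End-to-end recovery of a simulated cytokine cascade A -> B.

    Cytokine A has a cis causal variant at its gene locus; B is causally
    downstream of A (shared causal variant by mediation). The full
    direction-2 pipeline — cis-pQTL selection, MR, coloc at A's locus,
    graph construction — should recover a significant, coloc-supported
    directed edge A -> B."""
    seeds = _child_seeds(seed, n_reps)
    n_variants = 60
    block = 10
    spacing = 1000
    recovered = 0
    for s in seeds:
        rng = np.random.default_rng(int(s))
        v_a = int(rng.integers(0, 20))  # cis variant inside A's locus region
        cfg = SimConfig(
            n_individuals=n_individuals,
            n_variants=n_variants,
            ld_block_size=block,
            ld_rho=0.5,
            pos_spacing=spacing,
            traits={"cytA": TraitSpec("cytokine"),
                    "cytB": TraitSpec("cytokine")},
            causal_map={"cytA": [(v_a, effect_cis)]},
            trait_dag=[("cytA", "cytB", effect_cascade)],
            seed=int(rng.integers(2 ** 31)),
        )
        cohort = simulate_cohort(cfg)
        ga = run_gwas(cohort, "cytA")
        gb = run_gwas(cohort, "cytB")
        pos = cfg.positions
        locus_a = GeneLocus("GENE_A", cfg.chrom,
                            int(pos[0]), int(pos[19]))
        ld = theoretical_ld(cfg)
        rows, graph = run_direction_2(
            [ga, gb], ld, {"cytA": locus_a},
            PipelineConfig(mr=MRConfig(seed=int(s))),
        )
        edges = graph.edge_table()
        hit = edges[(edges["source"] == "cytA") & (edges["target"] == "cytB")
                    & edges["coloc_supported"]]
        recovered += len(hit) > 0
    return {"recovery_rate": recovered / n_reps, "n": n_reps}


def direction1_null_fpr(
    n_reps: int = 200,
    n_risk_traits: int = 3,
    n_cytokines: int = 10,
    n_individuals: int = 2_000,
    seed: int = 1,
) -> dict:
    """False-positive rate of direction-1 significance flags under a global
    null: risk traits have genetic effects (so instruments exist) but no
    effect on any cytokine. The family threshold is alpha/n_cytokines, so
    the expected fraction of significant main rows is its Bonferroni bound."""
    seeds = _child_seeds(seed, n_reps)
    n_variants = 45
    per_trait = 3
    n_main = 0
    n_sig = 0
    for s in seeds:
        rng = np.random.default_rng(int(s))
        traits = {}
        causal = {}
        for i in range(n_risk_traits):
            tid = f"risk{i}"
            traits[tid] = TraitSpec("quantitative")
            vstart = i * per_trait * 5
            causal[tid] = [(vstart + 5 * j, 0.35) for j in range(per_trait)]
        for j in range(n_cytokines):
            traits[f"cyt{j}"] = TraitSpec("cytokine")
        cfg = SimConfig(
            n_individuals=n_individuals,
            n_variants=n_variants,
            ld_block_size=5,
            ld_rho=0.3,
            traits=traits,
            causal_map=causal,
            seed=int(rng.integers(2 ** 31)),
        )
        cohort = simulate_cohort(cfg)
        risk = [run_gwas(cohort, f"risk{i}") for i in range(n_risk_traits)]
        cyts = [run_gwas(cohort, f"cyt{j}") for j in range(n_cytokines)]
        ld = theoretical_ld(cfg)
        rows = run_direction_1(risk, cyts, ld, PipelineConfig())
        main = rows[rows["role"] == "main"]
        n_main += len(main)
        n_sig += int(main["significant"].sum())
    bound = 0.05 / n_cytokines
    return {
        "fpr": n_sig / n_main if n_main else 0.0,
        "bonferroni_bound": bound,
        "n_tests": n_main,
        "n": n_reps,
    }
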