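"""Synthetic cohort generator: LD structure, causal structure, transform,
and GWAS correctness against closed-form and statsmodels oracles."""

import numpy as np
import pytest
from scipy import stats

from cytomr.simulate import (SimConfig, TraitSpec, inverse_normal_transform,
                             run_gwas, simulate_cohort, theoretical_ld)

from conftest import make_records  # noqa: F401  (fixture import side effects)


def _basic_config(**kwargs):
    base = dict(
        n_individuals=2000,
        n_variants=20,
        ld_block_size=5,
        ld_rho=0.0,
        traits={"T": TraitSpec()},
        seed=7,
    )
    base.update(kwargs)
    return SimConfig(**base)


# ---------------------------------------------------------------------------
# genotypes and LD
# ---------------------------------------------------------------------------

def test_dosages_are_valid_and_respect_maf_range():
    cfg = _basic_config(n_individuals=5000, maf_range=(0.1, 0.4))
    cohort = simulate_cohort(cfg)
    assert set(np.unique(cohort.dosages)) <= {0, 1, 2}
    emp_maf = cohort.dosages.mean(axis=1) / 2
    assert np.all(emp_maf > 0.05) and np.all(emp_maf < 0.45)
    assert np.all((cohort.mafs >= 0.1) & (cohort.mafs <= 0.4))


def test_zero_rho_gives_independent_variants():
    cfg = _basic_config(n_individuals=4000, n_variants=30, ld_rho=0.0)
    cohort = simulate_cohort(cfg)
    r = np.corrcoef(cohort.dosages.astype(float))
    off = np.abs(r[np.triu_indices_from(r, k=1)])
    assert off.mean() <= 2 / np.sqrt(cfg.n_individuals)


def test_block_ld_decays_as_rho_power_distance():
    cfg = _basic_config(n_individuals=8000, n_variants=10, ld_block_size=10,
                        ld_rho=0.6, maf_range=(0.2, 0.5))
    cohort = simulate_cohort(cfg)
    r = np.corrcoef(cohort.dosages.astype(float))
    for d in (1, 2, 3):
        emp = np.mean([r[i, i + d] for i in range(10 - d)])
        assert emp == pytest.approx(0.6 ** d, abs=0.05)


def test_cross_block_ld_is_null():
    cfg = _basic_config(n_individuals=8000, n_variants=10, ld_block_size=5,
                        ld_rho=0.8)
    cohort = simulate_cohort(cfg)
    r = np.corrcoef(cohort.dosages.astype(float))
    cross = r[:5, 5:]
    assert np.abs(cross).max() < 0.06


def test_theoretical_ld_matches_model():
    cfg = _basic_config(n_variants=6, ld_block_size=3, ld_rho=0.5)
    ld = theoretical_ld(cfg)
    assert ld.r[0, 1] == pytest.approx(0.5)
    assert ld.r[0, 2] == pytest.approx(0.25)
    assert ld.r[2, 3] == 0.0  # block boundary
    assert ld.r2("v0", "v1") == pytest.approx(0.25)


def test_fixed_seed_reproduces_everything():
    cfg = _basic_config()
    a, b = simulate_cohort(cfg), simulate_cohort(cfg)
    np.testing.assert_array_equal(a.dosages, b.dosages)
    np.testing.assert_array_equal(a.phenotypes["T"], b.phenotypes["T"])
    ga, gb = run_gwas(a, "T"), run_gwas(b, "T")
    np.testing.assert_array_equal(ga.records["beta"], gb.records["beta"])


# ---------------------------------------------------------------------------
# phenotype model
# ---------------------------------------------------------------------------

def test_pure_noise_trait_has_unit_variance():
    cfg = _basic_config(n_individuals=5000,
                        traits={"T": TraitSpec(noise_sd=1.0)})
    cohort = simulate_cohort(cfg)
    assert cohort.phenotypes["T"].var() == pytest.approx(1.0, rel=0.1)


def test_trait_dag_effect_recovered_by_ols():
    cfg = _basic_config(
        n_individuals=5000,
        traits={"A": TraitSpec(), "B": TraitSpec()},
        causal_map={"A": [(0, 0.3)]},
        trait_dag=[("A", "B", 0.5)],
    )
    cohort = simulate_cohort(cfg)
    a, b = cohort.phenotypes["A"], cohort.phenotypes["B"]
    slope, _, _, _, stderr = stats.linregress(a, b)
    assert abs(slope - 0.5) < 3 * stderr


def test_cyclic_trait_dag_rejected():
    with pytest.raises(ValueError, match="cycle"):
        _basic_config(traits={"A": TraitSpec(), "B": TraitSpec()},
                      trait_dag=[("A", "B", 0.5), ("B", "A", 0.5)])


def test_causal_index_out_of_range_rejected():
    with pytest.raises(ValueError, match="out of range"):
        _basic_config(causal_map={"T": [(99, 0.3)]})


def test_binary_trait_matches_prevalence():
    cfg = _basic_config(
        n_individuals=5000,
        traits={"D": TraitSpec("binary", prevalence=0.2)},
        causal_map={"D": [(0, 0.3)]},
    )
    cohort = simulate_cohort(cfg)
    y = cohort.phenotypes["D"]
    assert set(np.unique(y)) == {0.0, 1.0}
    assert y.mean() == pytest.approx(0.2, abs=0.01)


def test_expression_driven_by_cis_variants():
    cfg = _basic_config(
        n_individuals=4000,
        expression_map={"GENE1": [(0, 0.5)]},
        n_tissues=3,
        tissue_effect_sd=0.05,
    )
    cohort = simulate_cohort(cfg)
    assert ("GENE1", "whole_blood") in cohort.tissue_expression
    g = cohort.dosages[0].astype(float)
    for tissue in cfg.tissue_names:
        expr = cohort.tissue_expression[("GENE1", tissue)]
        slope = np.cov(g, expr)[0, 1] / g.var()
        assert slope == pytest.approx(0.5, abs=0.12)


# ---------------------------------------------------------------------------
# inverse normal transform
# ---------------------------------------------------------------------------

def test_int_three_values_symmetric_about_zero():
    out = inverse_normal_transform(np.array([1.0, 2.0, 3.0]))
    expected = stats.norm.ppf((1 - 0.375) / 3.25)
    assert out[0] == pytest.approx(expected)
    assert out[1] == pytest.approx(0.0, abs=1e-12)
    assert out[2] == pytest.approx(-out[0])


def test_int_preserves_ranks(rng):
    v = rng.normal(size=200)
    out = inverse_normal_transform(v)
    np.testing.assert_array_equal(np.argsort(v), np.argsort(out))
    assert out.mean() == pytest.approx(0.0, abs=1e-8)


def test_int_highly_correlated_with_normal_input(rng):
    v = rng.standard_normal(10_000)
    out = inverse_normal_transform(v)
    assert np.corrcoef(v, out)[0, 1] > 0.99


def test_int_ties_share_average_rank():
    out = inverse_normal_transform(np.array([1.0, 1.0, 2.0]))
    assert out[0] == out[1]


def test_int_constant_input_rejected():
    with pytest.raises(ValueError, match="constant"):
        inverse_normal_transform(np.ones(10))


# ---------------------------------------------------------------------------
# GWAS
# ---------------------------------------------------------------------------

def test_gwas_beta_matches_closed_form_ols():
    cfg = _basic_config(n_individuals=500, n_variants=5,
                        causal_map={"T": [(0, 0.4)]})
    cohort = simulate_cohort(cfg)
    ss = run_gwas(cohort, "T")
    y = cohort.phenotypes["T"]
    for i in range(5):
        g = cohort.dosages[i].astype(float)
        slope = np.cov(g, y, ddof=1)[0, 1] / np.var(g, ddof=1)
        assert ss.records.loc[i, "beta"] == pytest.approx(slope, abs=1e-10)


def test_gwas_matches_statsmodels_with_covariates(rng):
    import statsmodels.api as sm
    cfg = _basic_config(n_individuals=400, n_variants=3,
                        causal_map={"T": [(0, 0.4)]})
    cohort = simulate_cohort(cfg)
    cov = rng.normal(size=(400, 2))
    ss = run_gwas(cohort, "T", covariates=cov)
    y = cohort.phenotypes["T"]
    for i in range(3):
        x = sm.add_constant(np.column_stack(
            [cov, cohort.dosages[i].astype(float)]))
        fit = sm.OLS(y, x).fit()
        assert ss.records.loc[i, "beta"] == pytest.approx(fit.params[-1],
                                                          abs=1e-8)
        assert ss.records.loc[i, "se"] == pytest.approx(fit.bse[-1], rel=1e-6)


def test_gwas_type_one_error_calibrated():
    # phenotype independent of every variant: p < 0.05 in roughly 5% of tests
    cfg = _basic_config(n_individuals=1000, n_variants=1000,
                        ld_block_size=1, traits={"T": TraitSpec()}, seed=11)
    cohort = simulate_cohort(cfg)
    ss = run_gwas(cohort, "T")
    frac = (ss.records["p"] < 0.05).mean()
    assert 0.03 <= frac <= 0.07


def test_gwas_logistic_recovers_log_odds():
    cfg = _basic_config(
        n_individuals=6000,
        n_variants=3,
        traits={"D": TraitSpec("binary", prevalence=0.3, noise_sd=1.0)},
        causal_map={"D": [(0, 0.4)]},
        seed=3,
    )
    cohort = simulate_cohort(cfg)
    ss = run_gwas(cohort, "D")
    # liability effect 0.4 with sd-1 noise maps to a positive log-odds
    z0 = ss.records.loc[0, "beta"] / ss.records.loc[0, "se"]
    assert ss.records.loc[0, "beta"] > 0 and z0 > 5
    null_z = np.abs(ss.z[1:])
    assert np.all(null_z < 4)


def test_gwas_monomorphic_variant_flagged():
    cfg = _basic_config(n_individuals=200)
    cohort = simulate_cohort(cfg)
    cohort.dosages[0] = 0  # force monomorphic
    ss = run_gwas(cohort, "T")
    assert ss.records.loc[0, "beta"] == 0.0
    assert np.isinf(ss.records.loc[0, "se"])
    assert ss.records.loc[0, "p"] == 1.0


def test_gwas_eaf_is_mean_dosage_over_two():
    cfg = _basic_config(n_individuals=300)
    cohort = simulate_cohort(cfg)
    ss = run_gwas(cohort, "T")
    np.testing.assert_allclose(ss.records["eaf"],
                               cohort.dosages.mean(axis=1) / 2)


def test_gwas_effect_within_four_se_of_truth():
    hits = 0
    for seed in range(20):
        cfg = _basic_config(n_individuals=3000, n_variants=5,
                            ld_block_size=1,
                            causal_map={"T": [(2, 0.25)]}, seed=seed)
        cohort = simulate_cohort(cfg)
        ss = run_gwas(cohort, "T")
        b, se = ss.records.loc[2, "beta"], ss.records.loc[2, "se"]
        hits += abs(b - 0.25) < 4 * se
    assert hits >= 19
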