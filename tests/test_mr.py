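"""MR estimator suite: closed-form examples, independent oracles,
and the estimators' symmetry properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cytomr.mr import (MRConfig, egger, ivw, or_from_beta, presso, run_mr,
                       wald_ratio, weighted_median)
from cytomr.validation import harmonised_from_arrays


def _h(bx, by, sy, sx=None):
    bx = np.asarray(bx, float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, float)
    return harmonised_from_arrays(bx, sx, by, sy)


# ---------------------------------------------------------------------------
# Wald ratio
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("bx,by,sy,expect_b,expect_se", [
    (1.0, 0.2, 0.05, 0.2, 0.05),
    (0.5, 0.25, 0.05, 0.5, 0.1),
    (-0.5, 0.25, 0.05, -0.5, 0.1),
])
def test_wald_ratio_arithmetic(bx, by, sy, expect_b, expect_se):
    res = wald_ratio(_h([bx], [by], [sy]))
    assert res.beta == pytest.approx(expect_b)
    assert res.se == pytest.approx(expect_se)
    assert res.ci_low == pytest.approx(res.beta - 1.96 * res.se)


def test_wald_ratio_zero_exposure_is_error():
    with pytest.raises(ValueError, match="beta_exp"):
        wald_ratio(_h([0.0], [0.2], [0.05]))


def test_wald_ratio_requires_single_variant():
    with pytest.raises(ValueError):
        wald_ratio(_h([0.5, 0.5], [0.1, 0.1], [0.05, 0.05]))


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------

def test_ivw_replicate_instruments():
    res = ivw(_h([1.0, 1.0], [0.2, 0.2], [0.1, 0.1]))
    assert res.beta == pytest.approx(0.2)
    assert res.se == pytest.approx(0.1 / np.sqrt(2))
    assert res.extras["Q"] == pytest.approx(0.0, abs=1e-12)


def test_ivw_on_duplicated_variant_equals_wald_ratio():
    single = _h([0.4], [0.12], [0.03])
    dup = _h([0.4, 0.4], [0.12, 0.12], [0.03, 0.03])
    assert ivw(dup).beta == pytest.approx(wald_ratio(single).beta)


def test_ivw_matches_statsmodels_wls_through_origin(rng):
    import statsmodels.api as sm
    bx = rng.normal(0.3, 0.1, 5)
    by = rng.normal(0.06, 0.05, 5)
    sy = rng.uniform(0.02, 0.08, 5)
    res = ivw(_h(bx, by, sy))
    fit = sm.WLS(by, bx, weights=1 / sy ** 2).fit()
    assert res.beta == pytest.approx(fit.params[0], abs=1e-12)
    # fixed-effects se agrees after removing statsmodels' residual scaling
    se_fe = fit.bse[0] / np.sqrt(fit.mse_resid)
    assert res.extras["se_fixed"] == pytest.approx(se_fe, abs=1e-12)


def test_ivw_random_effects_inflation_floor():
    # tiny heterogeneity: Q < df, no inflation
    res = ivw(_h([1.0, 1.0, 1.0], [0.2, 0.2, 0.2], [0.1, 0.1, 0.1]))
    assert res.se == pytest.approx(res.extras["se_fixed"])
    # large heterogeneity: se inflated by sqrt(Q / (n - 1))
    res2 = ivw(_h([1.0, 1.0], [0.5, -0.5], [0.05, 0.05]))
    assert res2.se == pytest.approx(
        res2.extras["se_fixed"] * np.sqrt(res2.extras["Q"] / 1))


def test_ivw_single_variant_directs_to_wald():
    with pytest.raises(ValueError, match="wald_ratio"):
        ivw(_h([0.5], [0.1], [0.05]))


# ---------------------------------------------------------------------------
# weighted median
# ---------------------------------------------------------------------------

def test_weighted_median_equal_weights_is_middle_ratio():
    h = _h([1.0, 1.0, 1.0], [0.1, 0.2, 0.9], [0.1, 0.1, 0.1])
    res = weighted_median(h, MRConfig(seed=1))
    assert res.beta == pytest.approx(0.2)


def test_weighted_median_degenerate_equal_ratios():
    h = _h([0.5, 1.0, 2.0], [0.15, 0.3, 0.6], [0.05, 0.1, 0.02])
    res = weighted_median(h, MRConfig(seed=1))
    assert res.beta == pytest.approx(0.3)


def test_weighted_median_matches_interpolation_oracle(rng):
    bx = rng.uniform(0.2, 0.6, 7)
    by = rng.normal(0.1, 0.1, 7)
    sy = rng.uniform(0.02, 0.1, 7)
    res = weighted_median(_h(bx, by, sy), MRConfig(seed=3))

    # independent interpolation oracle
    ratios = by / bx
    w = bx ** 2 / sy ** 2
    order = np.argsort(ratios)
    r_s, w_s = ratios[order], w[order] / w.sum()
    s = np.cumsum(w_s) - w_s / 2
    below = np.where(s < 0.5)[0][-1]
    frac = (0.5 - s[below]) / (s[below + 1] - s[below])
    expect = r_s[below] + frac * (r_s[below + 1] - r_s[below])
    assert res.beta == pytest.approx(expect, abs=1e-12)


def test_weighted_median_bootstrap_reproducible():
    h = _h([0.3, 0.4, 0.5, 0.6], [0.06, 0.1, 0.09, 0.14],
           [0.02, 0.03, 0.02, 0.04])
    a = weighted_median(h, MRConfig(seed=7))
    b = weighted_median(h, MRConfig(seed=7))
    c = weighted_median(h, MRConfig(seed=8))
    assert a.se == b.se
    assert a.se != c.se


def test_weighted_median_zero_exposure_is_error():
    with pytest.raises(ValueError):
        weighted_median(_h([0.0, 0.3, 0.4], [0.1, 0.1, 0.1],
                           [0.05, 0.05, 0.05]), MRConfig(seed=1))


# ---------------------------------------------------------------------------
# Egger
# ---------------------------------------------------------------------------

def test_egger_exact_linear_fit():
    bx = np.array([0.2, 0.4, 0.6, 0.8])
    by = 0.1 + 0.3 * bx
    res = egger(_h(bx, by, [0.05, 0.03, 0.07, 0.04]), MRConfig(seed=1))
    assert res.beta == pytest.approx(0.3, abs=1e-10)
    assert res.extras["egger_intercept"] == pytest.approx(0.1, abs=1e-10)


def test_egger_orientation_makes_exposures_positive():
    # data lies exactly on by = 0.1 + 0.3*bx after orientation to bx > 0
    bx = np.array([0.2, -0.4, 0.6])
    by_in = np.where(bx < 0, -(0.1 + 0.3 * (-bx)), 0.1 + 0.3 * bx)
    res = egger(_h(bx, by_in, [0.05, 0.05, 0.05]), MRConfig(seed=1))
    assert res.beta == pytest.approx(0.3, abs=1e-10)
    assert res.extras["egger_intercept"] == pytest.approx(0.1, abs=1e-10)


def test_egger_matches_statsmodels_wls(rng):
    import statsmodels.api as sm
    bx = rng.uniform(0.1, 0.6, 8)
    by = rng.normal(0.05 + 0.2 * bx, 0.05)
    sy = rng.uniform(0.02, 0.1, 8)
    res = egger(_h(bx, by, sy), MRConfig(seed=1))
    x = sm.add_constant(bx)
    fit = sm.WLS(by, x, weights=1 / sy ** 2).fit()
    assert res.beta == pytest.approx(fit.params[1], abs=1e-10)
    assert res.extras["egger_intercept"] == pytest.approx(fit.params[0],
                                                          abs=1e-10)


def test_egger_zero_intercept_data_matches_ivw():
    bx = np.array([0.2, 0.4, 0.6])
    by = 0.3 * bx
    sy = np.full(3, 0.05)
    e = egger(_h(bx, by, sy), MRConfig(seed=1))
    i = ivw(_h(bx, by, sy))
    assert e.beta == pytest.approx(i.beta, abs=1e-9)
    assert e.extras["egger_intercept"] == pytest.approx(0.0, abs=1e-9)


def test_egger_recovers_mean_directional_pleiotropy():
    rng = np.random.default_rng(99)
    intercepts = []
    for _ in range(500):
        n = 12
        bx = rng.uniform(0.1, 0.5, n)
        sy = np.full(n, 0.03)
        by = 0.2 * bx + 0.05 + rng.normal(0, sy)
        res = egger(_h(bx, by, sy), MRConfig(seed=1))
        intercepts.append(res.extras["egger_intercept"])
    assert np.mean(intercepts) == pytest.approx(0.05, abs=0.01)


# ---------------------------------------------------------------------------
# PRESSO
# ---------------------------------------------------------------------------

def test_presso_no_outliers_headline_equals_ivw():
    rng = np.random.default_rng(2)
    bx = rng.uniform(0.2, 0.5, 6)
    sy = np.full(6, 0.03)
    by = 0.25 * bx + rng.normal(0, sy)
    h = _h(bx, by, sy)
    p = presso(h, MRConfig(seed=5))
    i = ivw(h)
    assert p.extras["presso_outliers"] == []
    assert p.beta == i.beta and p.se == i.se and p.p == i.p


def test_presso_flags_injected_outlier_and_removes_it():
    rng = np.random.default_rng(3)
    n = 8
    bx = rng.uniform(0.2, 0.5, n)
    sy = np.full(n, 0.02)
    by = 0.25 * bx + rng.normal(0, sy)
    by[4] += 10 * sy[4]
    h = _h(bx, by, sy)
    res = presso(h, MRConfig(seed=5))
    assert "v4" in res.extras["presso_outliers"]
    assert res.n_snp < n
    assert res.extras["presso_distortion_p"] is not None
    # outlier-removed estimate is closer to truth than all-instrument IVW
    assert abs(res.beta - 0.25) < abs(res.extras["beta_all"] - 0.25)


def test_presso_reproducible_under_seed():
    rng = np.random.default_rng(4)
    bx = rng.uniform(0.2, 0.5, 5)
    sy = np.full(5, 0.03)
    by = 0.25 * bx + rng.normal(0, sy)
    h = _h(bx, by, sy)
    a = presso(h, MRConfig(seed=11))
    b = presso(h, MRConfig(seed=11))
    assert a.extras["presso_global_p"] == b.extras["presso_global_p"]


def test_presso_needs_four_variants():
    with pytest.raises(ValueError):
        presso(_h([0.3, 0.4, 0.5], [0.1, 0.1, 0.1], [0.05] * 3),
               MRConfig(seed=1))


# ---------------------------------------------------------------------------
# dispatch and odds ratios
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n_snp,methods", [
    (1, ["ratio"]),
    (2, ["ivw"]),
    (3, ["ivw", "weighted_median", "egger"]),
    (5, ["ivw", "weighted_median", "egger", "presso"]),
])
def test_run_mr_dispatch_by_instrument_count(n_snp, methods):
    rng = np.random.default_rng(n_snp)
    bx = rng.uniform(0.2, 0.5, n_snp)
    sy = np.full(n_snp, 0.03)
    by = 0.2 * bx + rng.normal(0, sy)
    results = run_mr(_h(bx, by, sy), MRConfig(seed=1))
    assert [r.method for r in results] == methods
    assert results[0].role == "main"
    assert all(r.role == "sensitivity" for r in results[1:])


@pytest.mark.parametrize("beta,se,expect", [
    (0.0, 0.1, 1.0),
    (np.log(2), 1e-9, 2.0),
])
def test_or_from_beta_closed_form(beta, se, expect):
    or_, lo, hi = or_from_beta(beta, se)
    assert or_ == pytest.approx(expect, rel=1e-6)
    assert lo <= or_ <= hi


def test_or_from_beta_matches_direct_exponentiation():
    or_, lo, hi = or_from_beta(0.1222, 0.0316)
    assert or_ == pytest.approx(1.13, abs=0.005)
    assert lo == pytest.approx(1.06, abs=0.005)
    assert hi == pytest.approx(1.20, abs=0.005)


# ---------------------------------------------------------------------------
# symmetry properties
# ---------------------------------------------------------------------------

@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_allele_flip_invariance_all_estimators(seed):
    """Jointly negating (bX, bY) for any one variant is a relabelling of the
    effect allele and must not change any estimate."""
    rng = np.random.default_rng(seed)
    n = 6
    bx = rng.uniform(0.1, 0.5, n)
    sx = rng.uniform(0.01, 0.05, n)
    by = rng.normal(0.2 * bx, 0.05)
    sy = rng.uniform(0.02, 0.08, n)
    j = int(rng.integers(n))
    bx2, by2 = bx.copy(), by.copy()
    bx2[j], by2[j] = -bx2[j], -by2[j]
    cfg = MRConfig(n_boot=100, n_sim=100, seed=17)
    for est in (ivw, weighted_median, egger):
        a = est(harmonised_from_arrays(bx, sx, by, sy), cfg)
        b = est(harmonised_from_arrays(bx2, sx, by2, sy), cfg)
        assert a.beta == pytest.approx(b.beta, rel=1e-9), est.__name__
        if est is not weighted_median:  # bootstrap draws differ after flip
            assert a.se == pytest.approx(b.se, rel=1e-9), est.__name__


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.floats(0.1, 5.0))
def test_scale_equivariance(seed, c):
    """Scaling all outcome effects by c scales every beta and se by c."""
    rng = np.random.default_rng(seed)
    n = 5
    bx = rng.uniform(0.1, 0.5, n)
    sx = rng.uniform(0.01, 0.05, n)
    by = rng.normal(0.2 * bx, 0.05)
    sy = rng.uniform(0.02, 0.08, n)
    cfg = MRConfig(n_boot=100, n_sim=100, seed=23)
    for est in (ivw, weighted_median, egger):
        a = est(harmonised_from_arrays(bx, sx, by, sy), cfg)
        b = est(harmonised_from_arrays(bx, sx, c * by, c * sy), cfg)
        assert b.beta == pytest.approx(c * a.beta, rel=1e-7), est.__name__
        assert b.se == pytest.approx(c * a.se, rel=0.05), est.__name__
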