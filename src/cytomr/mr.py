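"""Two-sample Mendelian randomisation estimators.

Implements the estimator suite applied to a :class:`~cytomr.sumstats.
HarmonisedSet` of exposure/outcome effect pairs:

* **Wald ratio** — beta_out / beta_exp for a single instrument, first-order
  delta-method standard error.
* **IVW** — weighted least squares of outcome on exposure betas through the
  origin with weights 1/se_out²; the fixed-effects standard error is
  inflated by sqrt(max(1, Q/(n-1))) (multiplicative random effects), which
  reduces to fixed effects when heterogeneity Q does not exceed its degrees
  of freedom.
* **Weighted median** — consistent when instruments carrying at least half
  the weight are valid; standard error by seeded parametric bootstrap.
* **MR-Egger** — weighted regression with a free intercept after orienting
  all exposure betas positive; the intercept estimates average directional
  pleiotropy.
* **MR-PRESSO** — simulation-based residual-sum-of-squares global test for
  horizontal pleiotropy, per-variant outlier flagging with Bonferroni
  correction, and a distortion test comparing the estimate with and without
  the flagged outliers.

`run_mr` applies the dispatch rule: the ratio method when one instrument is
available, IVW when two or more; the sensitivity suite (weighted median,
Egger, PRESSO at its own minimum) when three or more.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .sumstats import HarmonisedSet

__all__ = [
    "MRConfig",
    "MRResult",
    "wald_ratio",
    "ivw",
    "weighted_median",
    "egger",
    "presso",
    "run_mr",
    "or_from_beta",
]

#: 95% CI multiplier, as conventionally printed
Z95 = 1.96


@dataclass
class MRConfig:
    """Reproducibility knobs for the resampling-based methods."""

    n_boot: int = 1000  # weighted-median bootstrap replicates
    n_sim: int = 1000  # PRESSO simulation replicates
    seed: int = 0
    presso_outlier_alpha: float = 0.05  # Bonferroni-corrected over n_snp

    def __post_init__(self) -> None:
        if self.n_boot < 100 or self.n_sim < 100:
            raise ValueError("n_boot and n_sim must be >= 100")
        if not 0 < self.presso_outlier_alpha < 1:
            raise ValueError("presso_outlier_alpha must be in (0, 1)")


@dataclass
class MRResult:
    """One estimator's output: estimate, 95% CI, p, and method extras."""

    method: str
    beta: float
    se: float
    p: float
    n_snp: int
    role: str = "main"  # main | sensitivity
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("MRResult se must be > 0")
        self.ci_low = self.beta - Z95 * self.se
        self.ci_high = self.beta + Z95 * self.se


def _norm_p(z: float) -> float:
    return float(np.clip(2.0 * stats.norm.sf(abs(z)), np.nextafter(0, 1), 1.0))


def wald_ratio(h: HarmonisedSet) -> MRResult:
    """Single-instrument ratio estimate with first-order delta-method se."""
    if h.n_snp != 1:
        raise ValueError(f"wald_ratio needs exactly 1 variant, got {h.n_snp}")
    bx, sx, by, sy = h.arrays()
    if bx[0] == 0:
        raise ValueError("wald_ratio undefined for beta_exp = 0")
    beta = float(by[0] / bx[0])
    se = float(sy[0] / abs(bx[0]))
    return MRResult("ratio", beta, se, _norm_p(beta / se), 1)


def _ivw_fit(bx: np.ndarray, by: np.ndarray, sy: np.ndarray
             ) -> tuple[float, float, float]:
    """(beta, fixed-effects se, Q) for zero-intercept WLS, weights 1/sy²."""
    w = 1.0 / sy ** 2
    sxx = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / sxx
    se_fe = sxx ** -0.5
    q = float(np.sum(w * (by - beta * bx) ** 2))
    return beta, se_fe, q


def ivw(h: HarmonisedSet, config: MRConfig | None = None) -> MRResult:
    """Inverse-variance-weighted estimate (>= 2 instruments).

    Multiplicative random-effects inflation: the fixed-effects se is
    multiplied by sqrt(max(1, Q/(n_snp - 1))).
    """
    if h.n_snp < 2:
        raise ValueError("ivw needs >= 2 variants; use wald_ratio for one")
    bx, sx, by, sy = h.arrays()
    beta, se_fe, q = _ivw_fit(bx, by, sy)
    infl = np.sqrt(max(1.0, q / (h.n_snp - 1)))
    se = se_fe * infl
    return MRResult("ivw", beta, se, _norm_p(beta / se), h.n_snp,
                    extras={"Q": q, "se_fixed": se_fe})


def _weighted_median_estimate(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median of per-variant ratio estimates.

    With normalised weights w', the cumulative s_j = cumsum(w') - w'_j/2 is
    interpolated linearly against the sorted ratios at s = 0.5; an exact hit
    returns that ratio. A first weight already past 0.5 returns the smallest
    ratio (interpolation clamps at the ends).
    """
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - w / 2.0
    hit = np.nonzero(s == 0.5)[0]
    if hit.size:
        return float(r[hit[0]])
    return float(np.interp(0.5, s, r))


def weighted_median(h: HarmonisedSet, config: MRConfig | None = None
                    ) -> MRResult:
    """Weighted-median estimate (>= 3 instruments), bootstrap se.

    Per-variant ratio r_j = beta_out_j / beta_exp_j with weight
    beta_exp_j² / se_out_j² (the inverse variance of the ratio at first
    order). The se is the standard deviation of the estimate over ``n_boot``
    parametric bootstrap replicates drawing bX* ~ N(bX, seX) and
    bY* ~ N(bY, seY), seeded for bit reproducibility.
    """
    config = config or MRConfig()
    if h.n_snp < 3:
        raise ValueError("weighted_median needs >= 3 variants")
    bx, sx, by, sy = h.arrays()
    if np.any(bx == 0):
        raise ValueError("weighted_median undefined when any beta_exp = 0")
    ratios = by / bx
    weights = bx ** 2 / sy ** 2
    beta = _weighted_median_estimate(ratios, weights)

    rng = np.random.default_rng(config.seed)
    bx_s = rng.normal(bx, sx, size=(config.n_boot, h.n_snp))
    by_s = rng.normal(by, sy, size=(config.n_boot, h.n_snp))
    bx_s = np.where(bx_s == 0, np.finfo(float).tiny, bx_s)
    est = np.empty(config.n_boot)
    for b in range(config.n_boot):
        est[b] = _weighted_median_estimate(by_s[b] / bx_s[b],
                                           bx_s[b] ** 2 / sy ** 2)
    se = float(est.std(ddof=1))
    if se <= 0:  # degenerate (all ratios identical): fall back to IVW-scale se
        se = float((np.sum(weights)) ** -0.5)
    return MRResult("weighted_median", beta, se, _norm_p(beta / se), h.n_snp,
                    role="sensitivity", extras={"n_boot": config.n_boot})


def egger(h: HarmonisedSet, config: MRConfig | None = None) -> MRResult:
    """MR-Egger regression (>= 3 instruments).

    Each variant is oriented so beta_exp > 0 (both betas flipped together,
    which leaves the causal slope unchanged); outcome betas are regressed on
    exposure betas with a free intercept and weights 1/se_out². The slope is
    the causal estimate; the intercept (reported in ``extras``) tests average
    directional pleiotropy. Standard errors carry the multiplicative
    overdispersion factor sqrt(max(1, RSS_w/(n_snp - 2))).
    """
    if h.n_snp < 3:
        raise ValueError("egger needs >= 3 variants")
    bx, sx, by, sy = h.arrays()
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = 1.0 / sy ** 2

    # closed-form 2x2 weighted normal equations
    sw = w.sum()
    swx = float(np.sum(w * bx))
    swxx = float(np.sum(w * bx * bx))
    swy = float(np.sum(w * by))
    swxy = float(np.sum(w * bx * by))
    det = sw * swxx - swx ** 2
    if det <= 0:
        raise ValueError("degenerate exposure betas in egger regression")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    resid = by - intercept - slope * bx
    rss_w = float(np.sum(w * resid ** 2))
    infl = np.sqrt(max(1.0, rss_w / (h.n_snp - 2)))
    se_slope = np.sqrt(sw / det) * infl
    se_int = np.sqrt(swxx / det) * infl
    return MRResult(
        "egger", float(slope), float(se_slope),
        _norm_p(slope / se_slope), h.n_snp, role="sensitivity",
        extras={
            "egger_intercept": float(intercept),
            "egger_intercept_se": float(se_int),
            "egger_intercept_p": _norm_p(intercept / se_int),
            "rss_w": rss_w,
        },
    )


def _loo_ivw(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slope for each variant, vectorised."""
    w = 1.0 / sy ** 2
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx * bx)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def presso(h: HarmonisedSet, config: MRConfig | None = None) -> MRResult:
    """MR-PRESSO: pleiotropy residual sum and outlier test (>= 4 instruments).

    The observed statistic is RSS = sum_j w_j (bY_j - b_(-j) bX_j)² with
    leave-one-out IVW slopes b_(-j) and w_j = 1/seY_j². The global p compares
    it with ``n_sim`` parametric simulations under no pleiotropy
    (bX* ~ N(bX, seX), bY*_j ~ N(b_(-j) bX_j, seY_j)), with the add-one
    estimator (1 + #{RSS* >= RSS}) / (n_sim + 1). Per-variant outliers are
    flagged when the variant's observed residual term exceeds its simulated
    distribution at the Bonferroni-corrected level; if any are flagged the
    headline estimate switches to the outlier-removed IVW and a distortion p
    (random subsets of the same size removed instead) is reported.
    """
    config = config or MRConfig()
    if h.n_snp < 4:
        raise ValueError("presso needs >= 4 variants")
    n = h.n_snp
    bx, sx, by, sy = h.arrays()
    wy = 1.0 / sy ** 2

    b_loo = _loo_ivw(bx, by, sy)
    obs_terms = wy * (by - b_loo * bx) ** 2
    rss_obs = float(obs_terms.sum())

    rng = np.random.default_rng(config.seed)
    bx_s = rng.normal(bx, sx, size=(config.n_sim, n))
    by_s = rng.normal(b_loo * bx, sy, size=(config.n_sim, n))
    # vectorised leave-one-out slopes on the simulated tables
    sxy = np.sum(wy * bx_s * by_s, axis=1, keepdims=True)
    sxx = np.sum(wy * bx_s * bx_s, axis=1, keepdims=True)
    b_loo_s = (sxy - wy * bx_s * by_s) / (sxx - wy * bx_s * bx_s)
    sim_terms = wy * (by_s - b_loo_s * bx_s) ** 2
    rss_sim = sim_terms.sum(axis=1)

    global_p = (1.0 + np.sum(rss_sim >= rss_obs)) / (config.n_sim + 1.0)
    outlier_p = (1.0 + np.sum(sim_terms >= obs_terms, axis=0)) / (config.n_sim + 1.0)
    cutoff = config.presso_outlier_alpha / n
    outliers = np.nonzero(outlier_p < cutoff)[0]

    ivw_all = ivw(h, config)
    extras = {
        "presso_global_p": float(global_p),
        "presso_rss": rss_obs,
        "presso_outliers": h.table["variant_id"].iloc[outliers].tolist(),
        "presso_outlier_p": outlier_p,
        "presso_distortion_p": None,
        "beta_all": ivw_all.beta,
    }

    if outliers.size and n - outliers.size >= 2:
        keep = np.setdiff1d(np.arange(n), outliers)
        h_kept = h.subset(h.table.index.isin(keep))
        ivw_kept = ivw(h_kept, config)
        d_obs = ivw_all.beta - ivw_kept.beta
        # null distortion: remove random same-size subsets of non-outliers
        d_null = np.empty(config.n_sim)
        for s in range(config.n_sim):
            drop = rng.choice(keep, size=outliers.size, replace=False)
            mask = np.setdiff1d(np.arange(n), drop)
            b_sub, _, _ = _ivw_fit(bx[mask], by[mask], sy[mask])
            d_null[s] = ivw_all.beta - b_sub
        distortion_p = (1.0 + np.sum(np.abs(d_null) >= abs(d_obs))) / (
            config.n_sim + 1.0)
        extras["presso_distortion_p"] = float(distortion_p)
        extras["distortion"] = float(d_obs)
        return MRResult("presso", ivw_kept.beta, ivw_kept.se, ivw_kept.p,
                        int(n - outliers.size), role="sensitivity",
                        extras=extras)

    # no outliers (or too few variants left): headline equals IVW
    return MRResult("presso", ivw_all.beta, ivw_all.se, ivw_all.p, n,
                    role="sensitivity", extras=extras)


def run_mr(h: HarmonisedSet, config: MRConfig | None = None) -> list[MRResult]:
    """Dispatch the estimator suite by instrument count.

    1 instrument: ratio only (main). 2: IVW (main). >= 3: IVW (main) plus
    weighted median and Egger (sensitivity). >= 4: plus PRESSO.
    """
    config = config or MRConfig()
    if h.n_snp < 1:
        raise ValueError("run_mr needs at least one variant")
    if h.n_snp == 1:
        return [wald_ratio(h)]
    results = [ivw(h, config)]
    if h.n_snp >= 3:
        results.append(weighted_median(h, config))
        results.append(egger(h, config))
    if h.n_snp >= 4:
        results.append(presso(h, config))
    return results


def or_from_beta(beta: float, se: float) -> tuple[float, float, float]:
    """Odds ratio per 1 SD of the exposure, with 95% CI, from a log-odds beta."""
    if se <= 0:
        raise ValueError("se must be > 0")
    return (float(np.exp(beta)),
            float(np.exp(beta - Z95 * se)),
            float(np.exp(beta + Z95 * se)))
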