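# Methods

`cytomr` implements a bi-directional two-sample Mendelian randomisation (MR)
and colocalisation pipeline for circulating cytokines and cardiometabolic
traits, together with a synthetic-cohort generator that provides known causal
ground truth for every stage. This note records the statistical models, the
defaults and why they were chosen, and what the simulation-based checks do
and do not demonstrate.

## Two-sample MR model

Each genetic variant j supplies an exposure association (b<sub>Xj</sub>,
se<sub>Xj</sub>) and an outcome association (b<sub>Yj</sub>, se<sub>Yj</sub>)
aligned to a common effect allele. Under the instrumental-variable
assumptions (relevance, independence from confounders, and effect on the
outcome only through the exposure), the per-variant ratio
b<sub>Yj</sub>/b<sub>Xj</sub> estimates the causal effect β of a 1 SD
increase in the exposure (log-odds change for binary outcomes, reported as
an odds ratio per 1 SD via exp(β)).

Estimators:

* **Wald ratio** (1 instrument): β̂ = b<sub>Y</sub>/b<sub>X</sub>, first-order
  delta-method se = se<sub>Y</sub>/|b<sub>X</sub>| (no exposure-error term,
  no second-order correction — the simplest defensible default; exposure
  error of the sizes produced by the selection thresholds changes the se by
  ≪ its own Monte-Carlo error).
* **IVW** (≥2): weighted least squares of b<sub>Y</sub> on b<sub>X</sub>
  through the origin with weights 1/se<sub>Y</sub>². The fixed-effects se
  (Σw b<sub>X</sub>²)^(−1/2) is multiplied by √(max(1, Q/(n−1))) where
  Q is the weighted residual sum of squares. This multiplicative
  random-effects inflation is the dominant practice: it reduces exactly to
  fixed effects when heterogeneity does not exceed its degrees of freedom
  and never shrinks the se.
* **Weighted median** (≥3): ratios ordered ascending; with normalised
  weights w′<sub>j</sub> = (b<sub>Xj</sub>²/se<sub>Yj</sub>²)/Σ·, the
  cumulative midpoints s<sub>j</sub> = Σ<sub>k≤j</sub>w′<sub>k</sub> −
  w′<sub>j</sub>/2 are interpolated at s = 0.5. Consistent when instruments
  carrying ≥50% of the weight are valid. The se is the standard deviation of
  the estimate over a seeded parametric bootstrap (default 1000 replicates)
  drawing b<sub>X</sub>* ~ N(b<sub>X</sub>, se<sub>X</sub>),
  b<sub>Y</sub>* ~ N(b<sub>Y</sub>, se<sub>Y</sub>).
* **MR-Egger** (≥3): variants oriented so b<sub>X</sub> > 0, then weighted
  regression of b<sub>Y</sub> on b<sub>X</sub> **with** a free intercept;
  the intercept estimates average directional pleiotropy, the slope is the
  causal estimate. Standard errors carry √(max(1, RSS<sub>w</sub>/(n−2))).
* **MR-PRESSO** (≥4): observed statistic RSS = Σ w<sub>Yj</sub>(b<sub>Yj</sub>
  − β̂<sub>(−j)</sub> b<sub>Xj</sub>)² with leave-one-out IVW slopes.
  The global p compares RSS with its distribution over seeded no-pleiotropy
  simulations (default 1000), using the add-one estimator
  (1 + #{RSS* ≥ RSS})/(n<sub>sim</sub> + 1) so p is never 0. Per-variant
  outliers are flagged when the observed residual term exceeds its simulated
  distribution at α/n (Bonferroni, α = 0.05). When outliers are flagged the
  headline estimate switches to the outlier-removed IVW and a distortion p
  is computed by removing random same-size subsets of the remaining
  variants and comparing the induced shift with the observed one.

Dispatch: 1 instrument → ratio; ≥2 → IVW as the main analysis; ≥3 adds the
weighted median and Egger as sensitivity analyses; ≥4 adds PRESSO. P-values
are two-sided normal throughout (a t reference for Egger with few
instruments would be slightly more conservative; with the normal reference
all five methods are on the same footing, and the null-calibration study
confirms family-wise error control downstream). Confidence intervals use
the conventional printed multiplier 1.96.

## Harmonisation

Exposure and outcome records are joined on (chromosome, position) — variant
id dialects differ across sources — and outcome alleles are reconciled to
the exposure's effect allele, handling swapped, strand-complement and
complement-swapped labellings by flipping the outcome beta and EAF.
Palindromic variants (A/T, C/G) carry no strand information in their
alleles; they are kept only when both traits' EAFs fall strictly on the same
side of 0.5 and each minor-allele frequency is below 0.42 (a common cutoff
for frequency-based strand inference; configurable). Indels and
multi-allelic positions are dropped. Harmonisation is idempotent, and
jointly negating both betas of a variant (an allele relabelling) leaves
every estimator unchanged — both are property-tested.

## Meta-analysis and cross-tissue aggregation

Per-cohort cytokine GWAS are pooled by fixed-effects inverse-variance
weighting: β = Σwβ<sub>i</sub>/Σw, se = (Σw)^(−1/2), w = 1/se². Variants
present in any cohort are emitted with the count of contributing studies.
Cross-tissue eQTL aggregation reuses the same machinery by default (the
simplest choice consistent with "aggregated across tissues"); a
sample-size-weighted Stouffer z alternative is provided as a config switch.
No heterogeneity filtering is applied at the meta stage.

## Instrument selection

Three criteria, all clumped greedily to pairwise r² < 0.001 against an LD
reference (best p first; ties broken by position then allele strings for
determinism):

* trait GWAS instruments at P < 5×10⁻⁸ (per-trait overrides supported,
  e.g. 1×10⁻⁶ for fasting insulin);
* cis-pQTL: variants within ±500 kb of the cytokine's gene body (bounds
  inclusive, anchored to gene start/end rather than the TSS) associated
  with the circulating cytokine at P < 1×10⁻⁴;
* cis-eQTL: the same window, requiring cross-tissue expression P < 1×10⁻⁴
  **and** cytokine P < 0.05, with exposure betas taken from the
  cytokine GWAS;
* plus a secondary genome-wide criterion (P < 5×10⁻⁸ anywhere).

All p-threshold comparisons are strict (<). Cis instruments are clumped at
the same r² < 0.001 as trait instruments because the ratio/IVW estimators
assume uncorrelated variants; this is configurable. The F-statistic is not
used as a filter (diagnostic only), and no Steiger filtering is applied.

## Colocalisation

Per variant and trait, the approximate Bayes factor against the null uses
z = β/se and shrinkage r = w/(w + se²): log ABF = ½(log(1−r) + r z²), with
prior effect variance w = 0.2² for quantitative-scale traits and 0.15² on
the log-odds scale for binary traits. Hypotheses H0 (no association), H1/H2
(one trait only), H3 (distinct causal variants), H4 (shared causal variant)
are enumerated in log space with per-variant priors p1 = p2 = 10⁻⁴ and
p12 = 10⁻⁵ — the method's canonical defaults, since no priors are printed
to copy — and posteriors obtained by softmax. The Σ<sub>i≠j</sub> term of
H3 is the guarded difference exp(S1+S2) − exp(S12), returned as −∞ when it
underflows; a single-variant locus therefore has PP(H3) = 0 identically.
Decision rules: *support* PP₄+PP₃ > 0.5 and *ratio* PP₄/(PP₄+PP₃) > 0.5;
both passing is evidence for colocalising signals, a dominant PP₃ suggests
genetic confounding. For cytokine-cytokine pairs the locus is the exposure
cytokine's gene window (±500 kb).

## Pipeline and multiple testing

Direction 1 (risk factors → cytokines) uses trait-GWAS instruments and a
Bonferroni family over the cytokine outcomes (0.05/47 = 0.0011 at the study
scale). Direction 2 (cytokine → cytokine) runs cis-pQTL and cis-eQTL
criteria, colocalises each significant pair at the exposure locus, and
assembles a directed graph whose edges exist only at family significance;
communities come from greedy modularity maximisation on the undirected
|β|-weighted projection with deterministic tie-breaking (the algorithm
behind the published network figure is unnamed, so the choice is
config-exposed). Direction 3 (cytokines → outcomes) adds the genome-wide
criterion, a family of 0.05/n_outcomes (0.05/15 = 0.0033 at the study
scale), colocalisation for pairs with nominal evidence (main p < 0.05), and
odds ratios per 1 SD for binary outcomes. Significance is flagged
per-criterion on the main estimate only (ratio or IVW); sensitivity
estimates are reported but never drive the flag. Agreement between the
cis-pQTL and cis-eQTL estimates for shared pairs is summarised by a Pearson
correlation.

## Synthetic cohorts

The generator emulates the study's ingredients — per-cohort cytokine GWAS
on inverse-normal-transformed phenotypes, quantitative and binary
cardiometabolic traits, per-tissue expression — with configurable truth.

* **Haplotypes.** Within an LD block, alleles form a first-order binary
  Markov chain with adjacent correlation ρ and a block-constant allele
  frequency drawn from `maf_range`; correlations along a two-state Markov
  chain multiply, so the haplotype (and dosage) correlation at distance d
  is exactly ρ^d inside a block and 0 across blocks. The block-constant
  frequency is what keeps every transition probability valid: binary
  variables with very different frequencies cannot be strongly correlated
  (Fréchet bound), which is also why variants in tight LD in real data have
  similar frequencies. A latent-Gaussian threshold construction was
  rejected because thresholding attenuates the dosage-scale correlation by
  roughly 40%, breaking the ρ^d contract the clumping and proxy logic rely
  on. `theoretical_ld` exposes this model LD as the deterministic
  reference-panel stand-in for clumping; an empirical matrix from the
  cohort's own dosages is also available, but at an r² ceiling of 0.001 its
  O(1/n) sampling noise dominates the threshold.
* **Phenotypes.** Quantitative traits are Σ(causal dosage × effect) +
  Σ(upstream trait × DAG effect) + N(0, noise_sd), with effects in SD units
  of the liability; binary traits threshold that liability at its empirical
  (1 − prevalence) quantile. Direct variant→outcome effects
  (`pleiotropy_map`) inject instrument-invalidating horizontal pleiotropy.
  Expression per (gene, tissue) is driven by configured cis variants with a
  tissue-shared effect plus N(0, `tissue_effect_sd`) perturbations.
* **GWAS.** Quantitative traits: per-variant closed-form OLS (vectorised;
  Frisch–Waugh residualisation when covariates are supplied), p from the
  normal Wald statistic. Cytokines are rank-inverse-normal transformed
  first (Blom offset (r − 0.375)/(m + 0.25)) by default. Binary traits:
  per-variant logistic regression (statsmodels), with non-converged or
  separated fits and monomorphic variants emitted as beta 0 / se ∞ so that
  downstream selection drops them; no Firth correction at desk scale.

What the generator does **not** emulate: realistic demography and
relatedness, imputation uncertainty, sample overlap between exposure and
outcome GWAS (several checks deliberately use one cohort for both traits of
a coloc pair, where it is harmless), covariate structures, winner's curse
from instrument discovery in the same data used for estimation (the
coverage study uses the known causal set precisely to isolate estimator
calibration from selection effects), and trans-regulatory architecture.
Passing checks therefore demonstrate the correctness and calibration of the
estimators and plumbing under the stated models, not robustness to every
failure mode of real consortium data.

## Validation studies and problem sizes

The Monte-Carlo studies in `cytomr.validation` (also run by
`scripts/acceptance.py`) use these conditions, chosen to mirror the
simulation settings stated for each check:

| study | conditions |
| --- | --- |
| IVW coverage | 500 replicates, 10 valid instruments, true β = 0.2, two independent cohorts of n = 10,000 |
| family-null calibration | 200 pipeline replicates, 3 instrumented risk traits × 10 null cytokines, n = 2,000 |
| PRESSO null | 500 summary-level replicates, 10 instruments, 1000 simulations each |
| robustness contrast | 200 replicates, 40% of 10 instruments with constant directional pleiotropy (+0.15 outcome-scale) |
| outlier detection | 200 replicates, one instrument shifted by 10 outcome se |
| coloc discrimination | 200 + 200 replicates, 40-variant loci, ρ = 0.5 blocks, effect 0.5 SD, n = 10,000 |
| cascade recovery | 100 full direction-2 replicates, cis effect 0.3 SD, cascade effect 0.5 SD, n = 10,000 |

## Numerical choices and degenerate inputs

All colocalisation accumulation is in log space; softmax normalisation
guards the posterior sum. Clumping is deterministic under input
permutation. The weighted-median bootstrap and all PRESSO simulations are
seeded; a fixed seed reproduces every output bit. A degenerate bootstrap
(all ratios identical) falls back to the IVW-scale se rather than zero.
Egger raises on collinear oriented exposure betas (determinant ≤ 0).
Harmonisation, selection and MR raise informative errors on empty
intersections, missing LD entries and undersized instrument sets, and the
pipeline logs-and-skips rather than aborting a whole run.

## Known limitations

Correlated-instrument (generalised) IVW is not implemented — instruments
are pre-clumped to near-independence, and the r² < 0.001 ceiling makes the
residual correlation negligible. Multivariable MR, Steiger directionality,
mode-based estimators and SuSiE-style multi-causal colocalisation are out
of scope. The Egger intercept test has low power with few instruments, as
expected. Reproducing the published real-data effect estimates requires the
external consortium summary statistics and is not attempted here.
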