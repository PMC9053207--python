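# Methods

## Statistical model

TMB scores within a cancer type are treated as log-normal; the response
analyzed is `log(TMB + 1)` (the +1 keeps zero-mutation specimens in the
model). For each cancer type independently, ordinary least squares
regresses this response on biopsy-site indicators plus three
specimen-quality covariates: median sequencing coverage, pathologist-
estimated tumor purity, and computationally estimated tumor purity.
Covariates are entered as provided (no log or standardization at fit
time); since estimated marginal means difference them out, only their
within-stratum association with TMB matters.

Estimated marginal means are computed on an unweighted reference grid —
one row per site level, each covariate fixed at its arithmetic mean over
the stratum's analyzed specimens. Back-transformation to mut/Mb uses
re-gridding: the grid's mean vector is mapped through
`g(η) = exp(η) − 1` and its covariance through the first-order delta
method, `V = D Σ_η Dᵀ` with `D = diag(exp(η))`. Contrasts (site minus
reference) therefore estimate differences of `exp(E[log(TMB+1)]) − 1`
— a geometric-mean-style location difference, *not* a difference of
arithmetic-mean TMB. Inference uses the t distribution with the OLS
residual degrees of freedom, the conventional default for linear-model
EMMs; no multiplicity correction is applied by default
(Benjamini–Hochberg is available via `adjust="bh"`).

Numerical choices: the design is built explicitly (intercept,
treatment-coded site dummies against the alphabetically first level,
covariate columns); the coding cancels in EMM contrasts. Rank is checked
before fitting and a rank-deficient design raises an error naming the
aliased columns (found by pivoted QR). A zero residual variance
(deterministic responses) collapses the CI to a point, with p = 0 for a
nonzero estimate. The reference-vs-itself contrast row is reported with
estimate 0 and p = 1.

The pooled metastatic-vs-primary comparison replaces the site factor
with a two-level primary/metastatic factor and reuses the same chain.
Pooling heterogeneous metastatic sites can mask opposite-signed site
effects — the package's simulations demonstrate this cancellation — so
the pooled row should be read alongside the per-site contrasts.

## Cohort selection

Filter order is frozen and tested: (1) most recently collected specimen
per patient, date ties broken by the lexicographically smallest specimen
id; (2) pathologist purity ≥ 0.30, boundary inclusive (the pathologist
estimate is used because specimen adequacy is a pathologist review; the
column is configurable); (3) within each cancer type independently, drop
biopsy-site strata with fewer than 50 specimens, counted after the
preceding filters. All filters are idempotent and return row subsets;
removal counts are logged and surfaced in the pipeline manifest.

## TMB scoring

Score = (count of somatic, nonsynonymous calls with allele frequency
≥ the 5% threshold) / effective panel megabases. The AF boundary is
inclusive, as is the 10 mut/Mb TMB-high cutoff; both are configurable.
The AF rule *retains* calls at or above threshold and discards those
below — low-AF calls are treated as sequencing noise; discarding
high-AF calls would remove exactly the clonal somatic mutations the
score is meant to count. Panel size is a required input because the
effective denominator is assay-specific.

## Stratified analyses

Metastasis-history control: for a target metastatic site, the stratum
keeps all specimens biopsied at that site plus primary-site specimens of
patients with a metastasis record at that site dated strictly before
specimen collection. The EMM chain then runs on the two-site stratum.

Paired biopsies: patients with specimens from two different sites within
a 90-day window (boundary inclusive) contribute one pair per site
combination — the minimal-gap qualifying pair, ties broken by earlier
collection dates. The paired test is an exact two-sided Wilcoxon
signed-rank: zero differences dropped, tied absolute differences
mid-ranked, and the null distribution of the positive-rank sum
enumerated exactly over all 2ⁿ sign assignments (a convolution over
doubled ranks keeps the support integral) for n ≤ 25, with a
tie-corrected normal approximation beyond. An exact test is required
because realistic pair counts are tiny (single digits); a paired t on
log(TMB+1) is available behind `method="t-log"`.

## Synthetic cohort generator

The generator emulates a de-identified clinico-genomic cohort:

- `log(TMB+1) = mu_log + delta_log(site) + β·covariates + ε`,
  `ε ~ N(0, sigma_log)`, TMB floored at 0 (the floor can bind only when
  the log-normal draw is below 1 and is negligible at the default
  `mu_log = 2`).
- Coverage ~ Normal(500, 100) reads, matching a high-quality targeted
  panel, standardized to z-scores inside the linear predictor.
  Pathologist purity ~ Uniform(0.20, 1.0) — deliberately extending below
  the 0.30 filter so the filter is exercised — and computational purity
  is the pathologist value plus Normal(0, 0.08) jitter clipped to [0,1];
  both enter standardized by the uniform's population mean and SD. These
  covariate distributions are conventions: nothing in a real cohort pins
  them down, and they exist to give the adjustment real work.
- Default covariate coefficients (0.05 per coverage SD, 0.10 / 0.05 per
  purity SD) induce the mild quality–TMB correlation the model adjusts
  for; recovery and type-I simulations set them to 0 so the estimand is
  unambiguous (see below).
- Each specimen at a non-primary site gets a metastasis record at that
  site dated 30–1000 days before collection; primary-site patients carry
  a prior record at a random metastatic site with probability
  `met_prob = 0.30`; noise records dated after collection appear with
  probability 0.05. `met_tmb_boost_log` shifts the TMB of met-bearing
  primary patients — the knob used to construct confounding scenarios
  that the met-history control must remove.
- With probability `multi_specimen_prob = 0.15` a patient contributes an
  extra, earlier specimen (10–400 days before, site re-drawn within the
  cancer), feeding the latest-specimen filter and the pair search.
- Variant lists are synthesized backwards from the TMB: exactly
  `round(TMB × panel_mb)` somatic nonsynonymous calls with AF in
  [0.05, 0.60], plus Poisson noise calls below the AF threshold,
  synonymous calls, and germline calls. Re-scoring the variants
  reproduces the stored TMB to within the 0.5/panel_mb rounding.
- All draws come from one seeded NumPy generator; equal configs give
  byte-identical tables.

### Ground truth

`true_effect_table` reports, per non-primary site, the population value
of the re-gridded EMM contrast implied by the config: the difference of
`exp(E[log(TMB+1)]) − 1` between site and primary, with
`E[log(TMB+1)]` computed by Monte Carlo over the covariate and noise
distributions (absorbing the TMB ≥ 0 floor; 200k draws by default).
Without the floor this is exactly `exp(mu+δ+β·c̄) − exp(mu+β·c̄)`. Note
the estimand is the back-transformed *mean of logs*, not `E[TMB]`; a
Monte-Carlo of `E[exp(X) − 1]` would converge to the larger
`exp(mu+σ²/2) − 1`-style quantity, which is not what the EMM chain
estimates. The table is defined on the generator's population (before
selection filters); recovery simulations therefore use null covariate
coefficients, under which the purity filter leaves the estimand
unchanged.

## What the simulations do and do not show

Parameter-recovery and type-I simulations use two-site cohorts of 500
specimens per site and 500 replicates — large enough that the coverage
standard error is about 1% while the full suite stays fast. They show
that the chain's estimates, CIs and p-values behave as advertised *under
the generator's assumptions*: log-normal TMB, linear covariate effects,
independent specimens. Real cohorts violate these in ways the synthetic
data does not emulate — panel version heterogeneity, site-dependent
purity distributions, within-patient correlation, informative biopsy-site
choice — so passing tests certify the statistical machinery, not the
published effect sizes, which came from a proprietary cohort of ~138k
specimens and are not reproducible at this scale. The delta-method t
inference on the response scale is first-order; its type-I error runs
slightly above nominal (typically 5–7% in the package's own
simulations), which is inherent to back-transformed Wald-type intervals.

## Known limitations

- No mixed/hierarchical models or robust (sandwich) variances; one
  specimen per patient is assumed after selection.
- First-order delta method only; no bias-corrected back-transformation.
- The odds-ratio estimator is the unconditional cross-product with a
  Woolf CI; small-sample exact (Fisher) inference is out of scope, and
  published odds ratios computed with other estimators may differ in the
  second decimal.
- The dichotomous analysis is unadjusted for covariates by design; only
  the continuous analysis adjusts.
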