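# tmbsite

Biopsy-site effects on tumor mutational burden (TMB), as a tested,
reusable analysis pipeline.

## The problem

TMB — the number of somatic nonsynonymous mutations per megabase of
sequenced coding territory (mut/Mb) — is used clinically to select
patients for immunotherapy, with a pan-tumor TMB-high threshold of
10 mut/Mb. In real-world genomic testing the specimen may come from any
lesion: the primary tumor, a lymph node, a liver or brain metastasis.
If the biopsied site itself shifts the observed TMB, the same patient can
fall on different sides of the clinical cutoff depending on which lesion
was sampled. This package quantifies that site effect, per cancer type,
while adjusting for specimen-quality confounders.

## The model

For each cancer type independently, with TMB approximately log-normal,

```
log(TMB_i + 1) = β₀ + Σ_s β_s · 1[site_i = s] + γ₁·coverage_i + γ₂·purity_path,i + γ₃·purity_comp,i + ε_i
```

is fit by OLS. Estimated marginal means (EMMs) are formed on a reference
grid — one row per biopsy site, covariates held at their stratum means —
and *re-gridded* to the response scale: means and covariance are pushed
through `g(η) = exp(η) − 1` by the first-order delta method. Site-vs-
reference contrasts are then reported in mut/Mb with t-based 95% CIs and
p-values (df = OLS residual df). In the balanced no-covariate limit the
back-transformed EMM of a site is `exp(mean log(TMB+1)) − 1`, a
geometric-mean-style statistic.

Around the model sit the rest of the pipeline stages:

- **Cohort selection** — most recent specimen per patient, pathologist
  purity ≥ 30%, and (per cancer type) removal of biopsy-site strata with
  fewer than 50 specimens.
- **TMB scoring** — somatic nonsynonymous calls with allele frequency
  ≥ 5%, divided by the panel's effective megabases.
- **Dichotomous analysis** — TMB-high (≥ 10 mut/Mb) percentages per
  site, percentage-point differences, cross-product odds ratios with
  Woolf CIs, Pearson chi-square tests, and a skip rule for pairs with
  < 10 TMB-high or TMB-low specimens.
- **Stratified analyses** — metastasis-history-controlled contrasts
  (primary-site patients kept only with a documented metastasis at the
  compared site before collection) and a paired-biopsy analysis (two
  sites within 90 days, exact Wilcoxon signed-rank).
- **Synthetic cohorts** — a generator emulating a clinico-genomic
  database, with known ground-truth site effects for recovery tests.

Filters are scikit-learn transformers and the site model is a
scikit-learn estimator (`SiteEffectModel`), so stages compose with
`sklearn.pipeline.Pipeline`.

## Worked example

```python
from tmbsite import (CohortConfig, SiteEffectSpec, generate_cohort,
                     selection_pipeline, true_effect_table)
from tmbsite.emm import run_all

cfg = CohortConfig(
    site_effects=[
        SiteEffectSpec(cancer_type="NSCLC", site="lung", is_primary=True, n_specimens=2000),
        SiteEffectSpec(cancer_type="NSCLC", site="brain", delta_log=0.35, n_specimens=800),
        SiteEffectSpec(cancer_type="NSCLC", site="bone", delta_log=0.0, n_specimens=400),
    ],
    seed=42,
)
specimens, variants, met_records = generate_cohort(cfg)
cohort = selection_pipeline(site_map={"NSCLC": "lung"}).transform(specimens)
table = run_all(cohort, {"NSCLC": "lung"})
print(table.round(3).to_string(index=False))
```

prints

```
cancer_type                site reference_site  estimate  ci_low  ci_high  p_value  n_site  n_reference
      NSCLC metastatic (pooled)        primary     1.950   1.539    2.361    0.000    1032         1760
      NSCLC                bone           lung     0.490  -0.066    1.047    0.084     339         1760
      NSCLC               brain           lung     2.761   2.252    3.269    0.000     693         1760
      NSCLC                lung           lung     0.000   0.000    0.000    1.000    1760         1760
```

Brain specimens carry an estimated +2.76 mut/Mb (95% CI 2.25–3.27)
relative to lung after covariate adjustment — the generator's true brain
effect here is +3.08 mut/Mb (`true_effect_table(cfg)`), inside the CI —
while bone shows no significant difference (its true effect is 0). The
pooled metastatic row averages the two and understates the brain-specific
shift, which is exactly why the per-site view matters.

A command-line interface wraps the same stages
(`tmbsite simulate | score | filter | model | dichotomous | met-controlled | paired | run`);
`tmbsite run --config cfg.yaml` executes the whole pipeline and writes
result tables plus an audit manifest of thresholds and filter counts.

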