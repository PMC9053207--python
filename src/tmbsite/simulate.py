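"""Synthetic clinico-genomic cohort generator.

Emulates the structure of a real-world tumor-profiling cohort linked to
clinical records: per-cancer, per-biopsy-site log-normal TMB with
site-specific location shifts on the ``log(TMB+1)`` scale, purity and
coverage covariates correlated with TMB, multiple dated specimens per
patient, and dated metastasis-history records. The generator carries its
own ground truth (:func:`true_effect_table`), which parameter-recovery
tests compare against the model chain's estimates.

Model
-----
For a specimen at site *s* of cancer *c*::

    log(TMB + 1) = mu_log[c] + delta_log[s] + beta_cov * z_cov
                   + beta_pp * z_pp + beta_pc * z_pc + eps,
    eps ~ Normal(0, sigma_log),  TMB floored at 0.

Coverage is Normal(coverage_mean, coverage_sd) and enters standardized to
z-scores; pathologist purity is Uniform on ``purity_range`` and enters
standardized by its population mean and SD; computational purity is the
pathologist value plus Normal(0, 0.08) jitter, clipped to [0, 1], on the
same standardized scale. The primary site of each cancer type has
``delta_log = 0`` by convention.
"""

from __future__ import annotations

from typing import Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, NonNegativeInt, field_validator, model_validator

from tmbsite._validation import MET_RECORD_COLUMNS, SPECIMEN_COLUMNS, VARIANT_COLUMNS

__all__ = ["SiteEffectSpec", "CohortConfig", "generate_cohort", "true_effect_table"]

_BASES = np.array(list("ACGT"))
_EPOCH = np.datetime64("2015-01-01")
_WINDOW_DAYS = 5 * 365  # collection dates span a 5-year window


class SiteEffectSpec(BaseModel):
    """One (cancer type, biopsy site) stratum and its true effect.

    ``delta_log`` is the additive shift on the ``log(TMB+1)`` scale relative
    to the cancer's primary site (whose shift is 0 by convention).
    """

    cancer_type: str
    site: str
    is_primary: bool = False
    delta_log: float = 0.0
    n_specimens: NonNegativeInt = 0

    @model_validator(mode="after")
    def _primary_delta_zero(self) -> "SiteEffectSpec":
        if self.is_primary and self.delta_log != 0.0:
            raise ValueError("delta_log: primary site must have delta_log = 0")
        return self


class CohortConfig(BaseModel):
    """Full parameterisation of a synthetic cohort.

    Defaults describe a high-quality targeted-sequencing cohort: median
    coverage around 500x, pathologist purity spread across [0.20, 1.0] so
    that the >=30% purity filter removes a realistic fraction, and a
    log-normal TMB with ``mu_log = 2`` (median about 6.4 mut/Mb).
    """

    site_effects: list[SiteEffectSpec]
    mu_log: Union[float, dict[str, float]] = 2.0
    sigma_log: float = Field(0.6, gt=0)
    beta_coverage: float = 0.05
    beta_purity_path: float = 0.10
    beta_purity_comp: float = 0.05
    coverage_mean: float = Field(500.0, gt=0)
    coverage_sd: float = Field(100.0, gt=0)
    purity_range: tuple[float, float] = (0.20, 1.0)
    met_prob: float = Field(0.30, ge=0, le=1)
    multi_specimen_prob: float = Field(0.15, ge=0, le=1)
    met_noise_prob: float = Field(0.05, ge=0, le=1)
    met_tmb_boost_log: float = 0.0
    panel_mb: float = Field(1.1, gt=0)
    seed: int = 0

    @field_validator("purity_range")
    @classmethod
    def _purity_in_unit_interval(cls, v: tuple[float, float]) -> tuple[float, float]:
        lo, hi = v
        if not (0 <= lo < hi <= 1):
            raise ValueError("purity_range: must satisfy 0 <= low < high <= 1")
        return v

    @model_validator(mode="after")
    def _one_primary_per_cancer(self) -> "CohortConfig":
        cancers = {e.cancer_type for e in self.site_effects}
        for c in cancers:
            n_primary = sum(e.is_primary for e in self.site_effects if e.cancer_type == c)
            if n_primary != 1:
                raise ValueError(
                    f"site_effects: cancer type {c!r} must have exactly one primary "
                    f"site (found {n_primary})"
                )
        return self

    def mu_for(self, cancer_type: str) -> float:
        if isinstance(self.mu_log, dict):
            try:
                return self.mu_log[cancer_type]
            except KeyError:
                raise ValueError(f"mu_log: no baseline for cancer type {cancer_type!r}")
        return self.mu_log

    def primary_site_map(self) -> dict[str, str]:
        return {e.cancer_type: e.site for e in self.site_effects if e.is_primary}


def _purity_z(p: np.ndarray, purity_range: tuple[float, float]) -> np.ndarray:
    lo, hi = purity_range
    mean = (lo + hi) / 2.0
    sd = (hi - lo) / np.sqrt(12.0)
    return (p - mean) / sd


def _draw_specimen_block(
    rng: np.random.Generator,
    config: CohortConfig,
    n: int,
    mu: float,
    delta: float,
    boost: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    coverage = rng.normal(config.coverage_mean, config.coverage_sd, n)
    coverage = np.maximum(coverage, 1.0)
    purity_path = rng.uniform(*config.purity_range, n)
    purity_comp = np.clip(purity_path + rng.normal(0.0, 0.08, n), 0.0, 1.0)
    z_cov = (coverage - config.coverage_mean) / config.coverage_sd
    lp = (
        mu
        + delta
        + config.beta_coverage * z_cov
        + config.beta_purity_path * _purity_z(purity_path, config.purity_range)
        + config.beta_purity_comp * _purity_z(purity_comp, config.purity_range)
    )
    if boost is not None:
        lp = lp + boost
    tmb = np.maximum(np.exp(lp + config.sigma_log * rng.standard_normal(n)) - 1.0, 0.0)
    return {
        "tmb": tmb,
        "purity_pathologist": purity_path,
        "purity_computational": purity_comp,
        "median_coverage": coverage,
    }


def _synthesize_variants(
    rng: np.random.Generator, specimen_ids: np.ndarray, tmb: np.ndarray, panel_mb: float
) -> pd.DataFrame:
    """Variant lists consistent with each specimen's TMB under the scoring rule.

    Qualifying calls (somatic, nonsynonymous, AF >= 0.05) number
    ``round(tmb * panel_mb)``; sub-threshold, synonymous, and germline noise
    calls are added so the AF/class/status filters all do real work.
    """
    rows_sid, rows_af, rows_fc, rows_ss = [], [], [], []
    n_qual = np.rint(tmb * panel_mb).astype(int)
    n_low = rng.poisson(2.0, len(tmb))
    n_syn = rng.poisson(2.0, len(tmb))
    n_germ = rng.poisson(1.0, len(tmb))
    for sid, nq, nl, ns, ng in zip(specimen_ids, n_qual, n_low, n_syn, n_germ):
        total = nq + nl + ns + ng
        if total == 0:
            continue
        af = np.concatenate(
            [
                rng.uniform(0.05, 0.60, nq),
                rng.uniform(0.01, 0.0499, nl),
                rng.uniform(0.01, 0.60, ns + ng),
            ]
        )
        fc = np.array(["nonsynonymous"] * (nq + nl) + ["synonymous"] * ns + ["other"] * ng)
        ss = np.array(["somatic"] * (nq + nl + ns) + ["germline"] * ng)
        rows_sid.append(np.repeat(sid, total))
        rows_af.append(af)
        rows_fc.append(fc)
        rows_ss.append(ss)
    if not rows_sid:
        return pd.DataFrame(columns=VARIANT_COLUMNS)
    n_total = sum(len(a) for a in rows_af)
    ref = rng.integers(0, 4, n_total)
    alt = (ref + rng.integers(1, 4, n_total)) % 4
    out = pd.DataFrame(
        {
            "specimen_id": np.concatenate(rows_sid),
            "chrom": np.char.add("chr", rng.integers(1, 23, n_total).astype(str)),
            "pos": rng.integers(1, 248_000_000, n_total),
            "ref": _BASES[ref],
            "alt": _BASES[alt],
            "allele_frequency": np.round(np.concatenate(rows_af), 4),
            "functional_class": np.concatenate(rows_fc),
            "somatic_status": np.concatenate(rows_ss),
        }
    )
    return out[VARIANT_COLUMNS]


def generate_cohort(
    config: CohortConfig, include_variants: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (specimens, variants, metastasis records) for ``config``.

    Identical configs (including ``seed``) yield identical tables. Every
    specimen biopsied at a non-primary ("metastatic") site gets a metastasis
    record at that site dated before collection; patients biopsied at the
    primary site carry a prior metastasis record at a random metastatic site
    with probability ``met_prob`` (those specimens get the
    ``met_tmb_boost_log`` shift, the knob for confounding scenarios), and
    noise records dated *after* collection appear with ``met_noise_prob``.

    With probability ``multi_specimen_prob`` a patient contributes one extra,
    earlier specimen, so the latest-specimen filter and the paired-biopsy
    search both have work to do.

    Parameters
    ----------
    config : CohortConfig
    include_variants : bool
        Skip variant synthesis (large) when only specimen-level analyses
        are needed, e.g. in simulation loops.
    """
    rng = np.random.default_rng(config.seed)
    primary_map = config.primary_site_map()
    sites_by_cancer: dict[str, list[str]] = {}
    for e in config.site_effects:
        sites_by_cancer.setdefault(e.cancer_type, []).append(e.site)
    delta_by = {(e.cancer_type, e.site): e.delta_log for e in config.site_effects}

    spec_frames: list[pd.DataFrame] = []
    met_rows: list[pd.DataFrame] = []
    pid_counter = 0
    sid_counter = 0

    for eff in config.site_effects:
        n = eff.n_specimens
        if n == 0:
            continue
        mu = config.mu_for(eff.cancer_type)
        dates = _EPOCH + rng.integers(0, _WINDOW_DAYS, n).astype("timedelta64[D]")

        # metastasis history of primary-site patients, decided before the TMB
        # draw so the boost can act on it
        met_sites = [s for s in sites_by_cancer[eff.cancer_type] if s != primary_map[eff.cancer_type]]
        if eff.is_primary and met_sites:
            has_met = rng.random(n) < config.met_prob
            met_site_idx = rng.integers(0, len(met_sites), n)
        else:
            has_met = np.zeros(n, dtype=bool)
            met_site_idx = np.zeros(n, dtype=int)
        boost = np.where(has_met, config.met_tmb_boost_log, 0.0)

        block = _draw_specimen_block(rng, config, n, mu, eff.delta_log, boost)
        pids = np.array([f"P{pid_counter + i:07d}" for i in range(n)])
        sids = np.array([f"S{sid_counter + i:07d}" for i in range(n)])
        pid_counter += n
        sid_counter += n
        df = pd.DataFrame(
            {
                "specimen_id": sids,
                "patient_id": pids,
                "cancer_type": eff.cancer_type,
                "biopsy_site": eff.site,
                "collection_date": dates,
                **block,
            }
        )
        df["is_primary_site"] = eff.is_primary
        spec_frames.append(df)

        # guaranteed prior-metastasis record for metastatic specimens
        if not eff.is_primary:
            lag = rng.integers(30, 1000, n).astype("timedelta64[D]")
            met_rows.append(
                pd.DataFrame({"patient_id": pids, "site": eff.site, "record_date": dates - lag})
            )
        elif met_sites:
            sel = np.flatnonzero(has_met)
            if sel.size:
                lag = rng.integers(30, 1000, sel.size).astype("timedelta64[D]")
                met_rows.append(
                    pd.DataFrame(
                        {
                            "patient_id": pids[sel],
                            "site": np.array(met_sites)[met_site_idx[sel]],
                            "record_date": dates[sel] - lag,
                        }
                    )
                )
        # noise records dated after collection (must be ignored downstream)
        noisy = np.flatnonzero(rng.random(n) < config.met_noise_prob)
        if noisy.size and met_sites:
            lead = rng.integers(1, 400, noisy.size).astype("timedelta64[D]")
            met_rows.append(
                pd.DataFrame(
                    {
                        "patient_id": pids[noisy],
                        "site": rng.choice(met_sites, noisy.size),
                        "record_date": dates[noisy] + lead,
                    }
                )
            )

        # extra, earlier specimens for a subset of patients
        extra = np.flatnonzero(rng.random(n) < config.multi_specimen_prob)
        if extra.size:
            m = extra.size
            extra_sites = rng.choice(sites_by_cancer[eff.cancer_type], m)
            extra_delta = np.array(
                [delta_by[(eff.cancer_type, s)] for s in extra_sites]
            )
            eblock = _draw_specimen_block(rng, config, m, mu, 0.0)
            eblock["tmb"] = np.maximum(
                np.exp(
                    np.log(eblock["tmb"] + 1.0) + extra_delta
                )
                - 1.0,
                0.0,
            )
            esids = np.array([f"S{sid_counter + i:07d}" for i in range(m)])
            sid_counter += m
            gap = rng.integers(10, 400, m).astype("timedelta64[D]")
            edf = pd.DataFrame(
                {
                    "specimen_id": esids,
                    "patient_id": pids[extra],
                    "cancer_type": eff.cancer_type,
                    "biopsy_site": extra_sites,
                    "collection_date": dates[extra] - gap,
                    **eblock,
                }
            )
            edf["is_primary_site"] = edf["biopsy_site"] == primary_map[eff.cancer_type]
            spec_frames.append(edf)
            is_met_extra = ~edf["is_primary_site"].to_numpy()
            if is_met_extra.any():
                lag = rng.integers(30, 1000, int(is_met_extra.sum())).astype("timedelta64[D]")
                met_rows.append(
                    pd.DataFrame(
                        {
                            "patient_id": edf.loc[is_met_extra, "patient_id"].to_numpy(),
                            "site": edf.loc[is_met_extra, "biopsy_site"].to_numpy(),
                            "record_date": edf.loc[is_met_extra, "collection_date"].to_numpy() - lag,
                        }
                    )
                )

    if spec_frames:
        specimens = pd.concat(spec_frames, ignore_index=True)[SPECIMEN_COLUMNS]
    else:
        specimens = pd.DataFrame(columns=SPECIMEN_COLUMNS)
    if met_rows:
        met_records = pd.concat(met_rows, ignore_index=True)[MET_RECORD_COLUMNS]
    else:
        met_records = pd.DataFrame(columns=MET_RECORD_COLUMNS)

    if include_variants and len(specimens):
        variants = _synthesize_variants(
            rng,
            specimens["specimen_id"].to_numpy(),
            specimens["tmb"].to_numpy(),
            config.panel_mb,
        )
    else:
        variants = pd.DataFrame(columns=VARIANT_COLUMNS)
    return specimens, variants, met_records


def true_effect_table(config: CohortConfig, n_mc: int = 200_000) -> pd.DataFrame:
    """Population value of the re-gridded EMM contrast for each non-primary site.

    The back-transformed estimated marginal mean of a site converges to
    ``exp(E[log(TMB+1)]) - 1`` with covariates held at their population
    means; the true contrast is the difference of that quantity between the
    site and the cancer's primary site. ``E[log(TMB+1)]`` is computed by
    Monte Carlo over the noise and covariate distributions (``n_mc`` draws),
    which also absorbs the TMB >= 0 floor; with the floor inactive this
    reduces to ``exp(mu + delta) - exp(mu)``.

    Boost shifts from confounding scenarios (``met_tmb_boost_log``) are not
    site effects and are excluded.
    """
    rng = np.random.default_rng(config.seed + 10_007)
    primary_map = config.primary_site_map()

    def mean_log_tmb1(mu: float, delta: float) -> float:
        block = _draw_specimen_block(rng, config, n_mc, mu, delta)
        return float(np.log(block["tmb"] + 1.0).mean())

    baselines = {
        c: mean_log_tmb1(config.mu_for(c), 0.0) for c in primary_map
    }
    rows = []
    for e in config.site_effects:
        if e.is_primary:
            continue
        m_site = mean_log_tmb1(config.mu_for(e.cancer_type), e.delta_log)
        m_ref = baselines[e.cancer_type]
        rows.append(
            {
                "cancer_type": e.cancer_type,
                "site": e.site,
                "reference_site": primary_map[e.cancer_type],
                "true_difference": (np.exp(m_site) - 1.0) - (np.exp(m_ref) - 1.0),
            }
        )
    return pd.DataFrame(rows, columns=["cancer_type", "site", "reference_site", "true_difference"])
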