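"""Metastasis-history-controlled and paired-biopsy analyses.

Comparing, say, brain-biopsied to lung-biopsied NSCLC patients is
confounded: everyone biopsied in the brain has a brain metastasis, while
only some lung-biopsied patients do. The met-controlled analysis removes
this imbalance by keeping primary-site specimens only for patients with a
metastasis documented at the target site *before* specimen collection,
then re-running the EMM model chain.

The paired analysis goes further: patients biopsied at two different sites
within a 90-day window (inclusive) contribute a within-patient TMB pair,
tested with an exact two-sided Wilcoxon signed-rank test (full
distribution enumerated for n <= 25; zero differences dropped, ties
mid-ranked; normal approximation with tie correction beyond that).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from tmbsite._validation import as_datetime, require_columns
from tmbsite.emm import CONTRAST_COLUMNS, DEFAULT_COVARIATES, emm_contrasts, fit_site_model, reference_grid, regrid_response

logger = logging.getLogger(__name__)

__all__ = [
    "filter_by_met_history",
    "run_met_controlled",
    "find_biopsy_pairs",
    "paired_site_test",
    "PairedTestResult",
    "exact_signed_rank",
]

DEFAULT_WINDOW_DAYS = 90
EXACT_ENUMERATION_MAX_N = 25

PAIR_COLUMNS = ["patient_id", "site_a", "site_b", "tmb_a", "tmb_b", "gap_days"]


def filter_by_met_history(
    specimens: pd.DataFrame, met_records: pd.DataFrame, target_site: str
) -> pd.DataFrame:
    """Restrict a one-cancer stratum to the met-history-controlled set.

    Returns all specimens biopsied at ``target_site`` plus primary-site
    specimens of patients with a metastasis record at ``target_site`` dated
    strictly before the specimen's collection date. Other specimens (and
    primary specimens whose only record at the site postdates collection)
    are excluded.
    """
    require_columns(
        specimens, ["patient_id", "biopsy_site", "collection_date", "is_primary_site"], "specimens"
    )
    require_columns(met_records, ["patient_id", "site", "record_date"], "met_records")
    at_target = specimens["biopsy_site"] == target_site
    primaries = specimens[specimens["is_primary_site"].astype(bool) & ~at_target].copy()
    if len(primaries) and len(met_records):
        recs = met_records[met_records["site"] == target_site][["patient_id", "record_date"]].copy()
        recs["record_date"] = as_datetime(recs["record_date"])
        key = "specimen_id" if "specimen_id" in primaries.columns else "patient_id"
        merged = primaries.assign(_cd=as_datetime(primaries["collection_date"])).merge(
            recs, on="patient_id", how="left"  # fans out on multiple records
        )
        eligible = set(merged.loc[merged["record_date"] < merged["_cd"], key])
        primaries = primaries[primaries[key].isin(eligible)]
    else:
        primaries = primaries.iloc[0:0]
    return pd.concat([specimens[at_target], primaries]).sort_index()


def run_met_controlled(
    cohort: pd.DataFrame,
    met_records: pd.DataFrame,
    site_map: dict[str, str],
    target_sites: dict[str, list[str]],
    alpha: float = 0.05,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Met-history-controlled site contrasts, one per (cancer, target site).

    For each cancer type and each of its target metastatic sites, the
    cohort is restricted by :func:`filter_by_met_history` and the EMM chain
    is fit on the two-site stratum with the mapped primary site as
    reference. Strata failing model preconditions are skipped with a
    logged reason.
    """
    frames = []
    for cancer, sites in target_sites.items():
        sub = cohort[cohort["cancer_type"] == cancer]
        if cancer not in site_map:
            logger.warning("skipping %s: no primary site mapped", cancer)
            continue
        ref = site_map[cancer]
        for target in sites:
            stratum = filter_by_met_history(sub, met_records, target)
            stratum = stratum[stratum["biopsy_site"].isin([target, ref])]
            try:
                fit = fit_site_model(stratum, covariates)
                rgrid = regrid_response(reference_grid(fit, stratum))
                con = emm_contrasts(rgrid, ref, alpha, cancer_type=cancer)
                frames.append(con[con["site"] == target])
            except ValueError as e:
                logger.warning("skipping %s / %s: %s", cancer, target, e)
    if not frames:
        return pd.DataFrame(columns=CONTRAST_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def find_biopsy_pairs(
    specimens: pd.DataFrame,
    window_days: int = DEFAULT_WINDOW_DAYS,
    site_pair: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Within-patient biopsy pairs from different sites within the window.

    Uses pre-deduplication specimens (multiple per patient). For each
    patient and site pair, the qualifying combination with the smallest
    date gap is emitted (ties broken by earlier collection dates); the gap
    boundary is inclusive (90 days in, 91 out) and same-site pairs are
    excluded. Output is independent of input row order.

    Parameters
    ----------
    site_pair : (site_a, site_b), optional
        Restrict to and orient one specific pair of sites; otherwise all
        site pairs are emitted with ``site_a < site_b`` alphabetically.
    """
    require_columns(
        specimens, ["patient_id", "biopsy_site", "collection_date", "tmb"], "find_biopsy_pairs"
    )
    work = specimens.assign(_cd=as_datetime(specimens["collection_date"])).sort_values(
        ["patient_id", "_cd", "biopsy_site"], kind="mergesort"
    )
    rows = []
    for pid, sub in work.groupby("patient_id", sort=True):
        if sub["biopsy_site"].nunique() < 2:
            continue
        best: dict[tuple[str, str], tuple] = {}
        recs = list(
            sub[["biopsy_site", "_cd", "tmb"]]
            .rename(columns={"_cd": "cdate"})
            .itertuples(index=False)
        )
        for r1, r2 in combinations(recs, 2):
            if r1.biopsy_site == r2.biopsy_site:
                continue
            gap = abs((r2.cdate - r1.cdate).days)
            if gap > window_days:
                continue
            a, b = r1, r2
            if site_pair is not None:
                if {a.biopsy_site, b.biopsy_site} != set(site_pair):
                    continue
                if a.biopsy_site != site_pair[0]:
                    a, b = b, a
            elif a.biopsy_site > b.biopsy_site:
                a, b = b, a
            key = (a.biopsy_site, b.biopsy_site)
            cand = (gap, min(a.cdate, b.cdate), max(a.cdate, b.cdate), a, b)
            if key not in best or cand[:3] < best[key][:3]:
                best[key] = cand
        for (sa, sb), (gap, _, _, a, b) in sorted(best.items()):
            rows.append(
                {
                    "patient_id": pid,
                    "site_a": sa,
                    "site_b": sb,
                    "tmb_a": a.tmb,
                    "tmb_b": b.tmb,
                    "gap_days": gap,
                }
            )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def _signed_rank_distribution(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of each achievable doubled rank-sum over all 2^n sign patterns."""
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=np.int64)
    counts[0] = 1
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def exact_signed_rank(diffs: np.ndarray) -> tuple[float, float, int]:
    """Exact two-sided Wilcoxon signed-rank test by full enumeration.

    Zero differences are dropped; tied absolute differences get mid-ranks.
    The null distribution of W+ (sum of positive ranks) is enumerated over
    all 2^n sign assignments via a convolution over doubled (hence integer)
    ranks, and the two-sided p is ``min(1, 2 * min(P(W <= w), P(W >= w)))``.

    Returns (W+, p, n_nonzero).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return np.nan, np.nan, 0
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    doubled = np.rint(2 * ranks).astype(np.int64)
    counts = _signed_rank_distribution(doubled)
    total = float(2**n)
    w2 = int(round(2 * w))
    p_le = counts[: w2 + 1].sum() / total
    p_ge = counts[w2:].sum() / total
    return w, min(1.0, 2.0 * min(p_le, p_ge)), n


@dataclass
class PairedTestResult:
    statistic: float
    p_value: float
    n: int
    method: str
    tested: bool
    reason: str = ""


def paired_site_test(pairs: pd.DataFrame, method: str = "wilcoxon-exact") -> PairedTestResult:
    """Paired test of TMB differences ``tmb_a - tmb_b`` across patients.

    ``"wilcoxon-exact"`` (default): exact signed-rank for n <= 25 nonzero
    differences, normal approximation with tie correction above that.
    ``"t-log"``: paired t-test on ``log(TMB+1)`` differences.

    Fewer than 2 pairs, or all-zero differences, yield an untested result
    with the reason recorded.
    """
    require_columns(pairs, ["tmb_a", "tmb_b"], "paired_site_test")
    d = pairs["tmb_a"].to_numpy(float) - pairs["tmb_b"].to_numpy(float)
    if len(d) < 2:
        return PairedTestResult(np.nan, np.nan, len(d), method, False, "fewer than 2 pairs")
    if np.all(d == 0):
        return PairedTestResult(np.nan, np.nan, len(d), method, False, "all differences zero")
    if method == "t-log":
        dl = np.log(pairs["tmb_a"].to_numpy(float) + 1) - np.log(pairs["tmb_b"].to_numpy(float) + 1)
        t, p = stats.ttest_1samp(dl, 0.0)
        return PairedTestResult(float(t), float(p), len(d), method, True)
    if method != "wilcoxon-exact":
        raise ValueError(f"unknown method {method!r}")
    nz = d[d != 0]
    if len(nz) <= EXACT_ENUMERATION_MAX_N:
        w, p, n = exact_signed_rank(d)
        return PairedTestResult(w, p, n, "wilcoxon-exact", True)
    res = stats.wilcoxon(nz, alternative="two-sided", correction=False, mode="approx")
    return PairedTestResult(float(res.statistic), float(res.pvalue), len(nz), "wilcoxon-approx", True)
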