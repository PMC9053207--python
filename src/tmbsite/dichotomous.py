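"""Dichotomous TMB-high analysis.

Specimens are grouped into TMB-high (score >= 10 mut/Mb, inclusive) and
TMB-low, then each biopsy site is compared to the cancer's reference site:
difference in percentage points, cross-product odds ratio with a Woolf
log-scale confidence interval, and a Pearson chi-square test on the 2x2
table (no continuity correction by default; Yates available behind a
flag). Pairs where either site has fewer than ``min_cell`` TMB-high or
TMB-low specimens are reported as skipped, not tested.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from tmbsite._validation import require_columns
from tmbsite.scoring import TMB_HIGH_CUTOFF

__all__ = ["tabulate_high", "compare_sites", "site_distribution"]

DEFAULT_MIN_CELL = 10

RESULT_COLUMNS = [
    "cancer_type",
    "site",
    "reference_site",
    "pct_site",
    "pct_reference",
    "pct_difference",
    "odds_ratio",
    "or_ci_low",
    "or_ci_high",
    "p_value",
    "skipped",
    "skip_reason",
]


def tabulate_high(specimens: pd.DataFrame, cutoff: float = TMB_HIGH_CUTOFF) -> pd.DataFrame:
    """Per (cancer type, site): TMB-high and total specimen counts."""
    require_columns(specimens, ["cancer_type", "biopsy_site", "tmb"], "tabulate_high")
    if len(specimens) == 0:
        return pd.DataFrame(columns=["cancer_type", "site", "n_high", "n_total"])
    g = specimens.assign(_high=specimens["tmb"] >= cutoff).groupby(
        ["cancer_type", "biopsy_site"], sort=True
    )["_high"]
    out = g.agg(n_high="sum", n_total="size").reset_index()
    out = out.rename(columns={"biopsy_site": "site"})
    out["n_high"] = out["n_high"].astype(int)
    return out


def _resolve_reference(reference_site: str | Mapping[str, str], cancer: str) -> str:
    if isinstance(reference_site, Mapping):
        if cancer not in reference_site:
            raise ValueError(f"no reference site mapped for cancer type {cancer!r}")
        return reference_site[cancer]
    return reference_site


def compare_sites(
    counts: pd.DataFrame,
    reference_site: str | Mapping[str, str],
    min_cell: int = DEFAULT_MIN_CELL,
    alpha: float = 0.05,
    yates: bool = False,
) -> pd.DataFrame:
    """Site-vs-reference TMB-high comparisons from a count table.

    For each cancer type and non-reference site: the percentage-point
    difference, the 2x2 cross-product odds ratio ``(a d) / (b c)`` with
    Woolf CI on the log scale, and the Pearson chi-square p-value. The
    comparison is skipped (``skipped=True``) when either site of the pair
    has fewer than ``min_cell`` TMB-high or fewer than ``min_cell``
    TMB-low specimens; a zero cell leaves the odds ratio undefined (NaN)
    with the reason flagged — no continuity fudge is applied silently.

    Parameters
    ----------
    counts : DataFrame
        Output of :func:`tabulate_high` (cancer_type, site, n_high, n_total).
    reference_site : str or mapping cancer_type -> site
    """
    require_columns(counts, ["cancer_type", "site", "n_high", "n_total"], "compare_sites")
    z = stats.norm.ppf(1 - alpha / 2)
    rows = []
    for cancer, sub in counts.groupby("cancer_type", sort=True):
        ref = _resolve_reference(reference_site, str(cancer))
        ref_rows = sub[sub["site"] == ref]
        if len(ref_rows) != 1:
            raise ValueError(
                f"reference site {ref!r} not present exactly once for {cancer!r}"
            )
        m_high = int(ref_rows["n_high"].iloc[0])
        m_total = int(ref_rows["n_total"].iloc[0])
        m_low = m_total - m_high
        for _, r in sub[sub["site"] != ref].iterrows():
            a, n_tot = int(r["n_high"]), int(r["n_total"])
            b = n_tot - a
            row = {
                "cancer_type": cancer,
                "site": r["site"],
                "reference_site": ref,
                "pct_site": 100.0 * a / n_tot if n_tot else np.nan,
                "pct_reference": 100.0 * m_high / m_total if m_total else np.nan,
                "odds_ratio": np.nan,
                "or_ci_low": np.nan,
                "or_ci_high": np.nan,
                "p_value": np.nan,
                "skipped": False,
                "skip_reason": "",
            }
            row["pct_difference"] = row["pct_site"] - row["pct_reference"]
            if min(a, b, m_high, m_low) < min_cell:
                row["skipped"] = True
                row["skip_reason"] = f"min_cell: a pair group has <{min_cell} TMB-high or TMB-low specimens"
                rows.append(row)
                continue
            if min(a, b, m_high, m_low) == 0:
                # OR undefined on a zero cell; no silent continuity fudge
                row["skip_reason"] = "zero_cell: odds ratio undefined"
            else:
                # cross-product OR with Woolf log-scale CI
                orr = (a * m_low) / (b * m_high)
                se_log = np.sqrt(1 / a + 1 / b + 1 / m_high + 1 / m_low)
                row["odds_ratio"] = orr
                row["or_ci_low"] = np.exp(np.log(orr) - z * se_log)
                row["or_ci_high"] = np.exp(np.log(orr) + z * se_log)
            table = np.array([[a, b], [m_high, m_low]])
            if table.sum(axis=0).min() > 0 and table.sum(axis=1).min() > 0:
                row["p_value"] = float(
                    stats.chi2_contingency(table, correction=yates)[1]
                )
            rows.append(row)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def site_distribution(specimens: pd.DataFrame) -> pd.DataFrame:
    """Per cancer type: specimen count and percentage by biopsy site.

    Percentages are out of the cancer type's total and sum to 100 within
    rounding.
    """
    require_columns(specimens, ["cancer_type", "biopsy_site"], "site_distribution")
    if len(specimens) == 0:
        return pd.DataFrame(columns=["cancer_type", "site", "n", "pct"])
    out = (
        specimens.groupby(["cancer_type", "biopsy_site"], sort=True)
        .size()
        .rename("n")
        .reset_index()
        .rename(columns={"biopsy_site": "site"})
    )
    totals = out.groupby("cancer_type")["n"].transform("sum")
    out["pct"] = 100.0 * out["n"] / totals
    return out
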