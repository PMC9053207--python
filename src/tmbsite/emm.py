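"""Covariate-adjusted site models on log(TMB+1) with back-transformed
estimated-marginal-mean contrasts.

For each cancer type independently, ordinary least squares regresses
``log(TMB + 1)`` on biopsy-site indicators plus quality covariates (median
sequencing coverage and two tumor-purity estimates by default). Estimated
marginal means (EMMs) are computed on a reference grid with one row per
site level and every covariate fixed at its stratum mean; the grid is then
*re-gridded* to the response scale — means and covariance are pushed
through ``g(eta) = exp(eta) - 1`` by the first-order delta method — so
site-vs-reference contrasts come out in mut/Mb with t-based confidence
intervals and p-values (degrees of freedom = OLS residual df).

In the balanced no-covariate limit the back-transformed EMM of a site is
``exp(mean of log(TMB+1)) - 1``, a geometric-mean-style statistic, and the
contrast is the difference of those.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from tmbsite._validation import require_columns

logger = logging.getLogger(__name__)

__all__ = [
    "ModelFit",
    "ReferenceGrid",
    "ResponseGrid",
    "SiteEffectModel",
    "fit_site_model",
    "reference_grid",
    "regrid_response",
    "emm_contrasts",
    "metastatic_vs_primary",
    "run_all",
]

DEFAULT_COVARIATES = ("median_coverage", "purity_pathologist", "purity_computational")
POOLED_LABEL = "metastatic (pooled)"

CONTRAST_COLUMNS = [
    "cancer_type",
    "site",
    "reference_site",
    "estimate",
    "ci_low",
    "ci_high",
    "p_value",
    "n_site",
    "n_reference",
]


@dataclass
class ModelFit:
    """OLS fit of log(TMB+1) on factor indicators plus covariates.

    ``params``/``cov`` live on the log(TMB+1) scale; the response transform
    is fixed as g(eta) = exp(eta) - 1.
    """

    params: np.ndarray
    cov: np.ndarray
    columns: list[str]
    df_resid: int
    sigma2: float
    factor: str
    levels: list[str]
    covariates: list[str]
    level_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class ReferenceGrid:
    """One row per factor level, covariates at their stratum means."""

    levels: list[str]
    linear_rows: np.ndarray  # L: (n_levels, n_params)
    eta: np.ndarray  # L beta
    eta_cov: np.ndarray  # L Sigma L'
    covariate_means: dict[str, float]
    df_resid: int
    level_counts: dict[str, int]


@dataclass
class ResponseGrid:
    """Reference grid re-gridded to the response scale (mut/Mb)."""

    levels: list[str]
    mean: np.ndarray  # exp(eta) - 1
    cov: np.ndarray  # delta-method covariance
    df_resid: int
    level_counts: dict[str, int]


def _build_design(
    X: pd.DataFrame, factor: str, covariates: list[str]
) -> tuple[np.ndarray, list[str], list[str]]:
    levels = sorted(X[factor].astype(str).unique())
    cols = [np.ones(len(X))]
    names = ["Intercept"]
    for lv in levels[1:]:
        cols.append((X[factor].astype(str) == lv).to_numpy(float))
        names.append(f"{factor}[{lv}]")
    for c in covariates:
        cols.append(X[c].to_numpy(float))
        names.append(c)
    return np.column_stack(cols), names, levels


def _aliased_columns(design: np.ndarray, names: list[str], rank: int) -> list[str]:
    # pivoted QR: columns pivoted past the numerical rank are linearly
    # dependent on the ones before them
    _, _, piv = scipy.linalg.qr(design, mode="economic", pivoting=True)
    return [names[j] for j in sorted(piv[rank:])]


def _fit(X: pd.DataFrame, factor: str, covariates: list[str]) -> ModelFit:
    require_columns(X, [factor, "tmb", *covariates], "model input")
    design, names, levels = _build_design(X, factor, covariates)
    if len(levels) < 2:
        raise ValueError(
            f"model requires at least 2 levels of {factor!r}; got {levels}"
        )
    n, p = design.shape
    if n <= p:
        raise ValueError(f"model needs n > {p} design columns; got n = {n}")
    rank = np.linalg.matrix_rank(design)
    if rank < p:
        aliased = _aliased_columns(design, names, rank)
        raise ValueError(
            "rank-deficient design; aliased column(s): " + ", ".join(aliased)
        )
    y = np.log(X["tmb"].to_numpy(float) + 1.0)
    res = sm.OLS(y, design).fit()
    counts = X[factor].astype(str).value_counts().to_dict()
    return ModelFit(
        params=np.asarray(res.params),
        cov=np.asarray(res.cov_params()),
        columns=names,
        df_resid=int(res.df_resid),
        sigma2=float(res.ssr / res.df_resid),
        factor=factor,
        levels=levels,
        covariates=list(covariates),
        level_counts={str(k): int(v) for k, v in counts.items()},
    )


def fit_site_model(
    specimens: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    factor: str = "biopsy_site",
) -> ModelFit:
    """OLS of log(TMB+1) on biopsy-site indicators plus covariates.

    One cancer type at a time; site levels are treatment-coded against the
    alphabetically first level (the coding does not affect EMM contrasts).

    Raises
    ------
    ValueError
        On a single site level, n <= number of design columns, or a
        rank-deficient design (the aliased columns are named).
    """
    return _fit(specimens, factor, list(covariates))


def reference_grid(fit: ModelFit, specimens: pd.DataFrame) -> ReferenceGrid:
    """EMM reference grid: one row per factor level, covariates at stratum means."""
    require_columns(specimens, [fit.factor, *fit.covariates], "reference_grid input")
    means = {c: float(specimens[c].mean()) for c in fit.covariates}
    L = np.zeros((len(fit.levels), len(fit.columns)))
    for i, lv in enumerate(fit.levels):
        L[i, 0] = 1.0
        for j, name in enumerate(fit.columns):
            if name == f"{fit.factor}[{lv}]":
                L[i, j] = 1.0
            elif name in means:
                L[i, j] = means[name]
    eta = L @ fit.params
    return ReferenceGrid(
        levels=list(fit.levels),
        linear_rows=L,
        eta=eta,
        eta_cov=L @ fit.cov @ L.T,
        covariate_means=means,
        df_resid=fit.df_resid,
        level_counts=dict(fit.level_counts),
    )


def regrid_response(grid: ReferenceGrid) -> ResponseGrid:
    """Push the grid through g(eta) = exp(eta) - 1 by the delta method.

    Means become ``exp(eta) - 1``; the covariance becomes
    ``D eta_cov D'`` with ``D = diag(exp(eta))`` (first-order delta
    method — the standard re-gridding construction).
    """
    d = np.exp(grid.eta)
    return ResponseGrid(
        levels=list(grid.levels),
        mean=d - 1.0,
        cov=(grid.eta_cov * d[:, None]) * d[None, :],
        df_resid=grid.df_resid,
        level_counts=dict(grid.level_counts),
    )


def emm_contrasts(
    rgrid: ResponseGrid,
    reference_site: str,
    alpha: float = 0.05,
    cancer_type: str | None = None,
) -> pd.DataFrame:
    """Site-vs-reference differences in mut/Mb with t CIs and p-values.

    The reference-vs-itself row is included with estimate 0 and p = 1.
    A zero standard error (deterministic responses) collapses the CI to a
    point; the p-value is then 0 for a nonzero estimate and 1 otherwise.
    """
    if reference_site not in rgrid.levels:
        raise ValueError(
            f"reference site {reference_site!r} not among grid levels {rgrid.levels}"
        )
    r = rgrid.levels.index(reference_site)
    tdist = stats.t(rgrid.df_resid)
    tcrit = tdist.ppf(1 - alpha / 2)
    rows = []
    for i, lv in enumerate(rgrid.levels):
        est = float(rgrid.mean[i] - rgrid.mean[r])
        var = float(rgrid.cov[i, i] + rgrid.cov[r, r] - 2 * rgrid.cov[i, r])
        se = np.sqrt(max(var, 0.0))
        if i == r:
            est, se, p, lo, hi = 0.0, 0.0, 1.0, 0.0, 0.0
        elif se == 0.0:
            p = 1.0 if est == 0.0 else 0.0
            lo = hi = est
        else:
            p = float(2 * tdist.sf(abs(est) / se))
            lo, hi = est - tcrit * se, est + tcrit * se
        rows.append(
            {
                "cancer_type": cancer_type,
                "site": lv,
                "reference_site": reference_site,
                "estimate": est,
                "ci_low": lo,
                "ci_high": hi,
                "p_value": p,
                "n_site": rgrid.level_counts.get(lv, 0),
                "n_reference": rgrid.level_counts.get(reference_site, 0),
            }
        )
    return pd.DataFrame(rows, columns=CONTRAST_COLUMNS)


def metastatic_vs_primary(
    specimens: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    alpha: float = 0.05,
    cancer_type: str | None = None,
) -> pd.DataFrame:
    """Pooled metastatic-vs-primary contrast (mut/Mb) for one cancer type.

    All non-primary sites are pooled into a single "metastatic" level; the
    model and covariates are otherwise identical to the per-site chain.
    Pooling heterogeneous sites can *mask* opposite-signed site effects —
    the per-site contrasts are the finer-grained picture.
    """
    require_columns(specimens, ["is_primary_site"], "metastatic_vs_primary input")
    grp = np.where(specimens["is_primary_site"].astype(bool), "primary", "metastatic")
    work = specimens.assign(_group=grp)
    if len(set(grp)) < 2:
        raise ValueError("both primary and metastatic specimens are required")
    fit = _fit(work, "_group", list(covariates))
    rgrid = regrid_response(reference_grid(fit, work))
    out = emm_contrasts(rgrid, "primary", alpha, cancer_type=cancer_type)
    out = out[out["site"] == "metastatic"].copy()
    out["site"] = POOLED_LABEL
    return out.reset_index(drop=True)


class SiteEffectModel(BaseEstimator):
    """Per-stratum biopsy-site TMB model (scikit-learn estimator).

    Fits OLS on log(TMB+1) with site indicators plus covariates, builds the
    EMM reference grid, re-grids to mut/Mb, and stores site-vs-reference
    contrasts.

    Parameters
    ----------
    reference_site : str or None
        Baseline site for contrasts. If None, taken from the (unique) site
        flagged ``is_primary_site`` in the data.
    covariates : tuple of str
        Quality covariates entered linearly.
    alpha : float
        Two-sided level for confidence intervals.
    pool_metastatic : bool
        Replace the site factor by a two-level primary/metastatic factor
        and report the single pooled contrast.

    Attributes
    ----------
    model_fit_ : ModelFit
    grid_ : ReferenceGrid
    response_grid_ : ResponseGrid
    contrasts_ : DataFrame of site-vs-reference differences in mut/Mb
    reference_site_ : str
    """

    def __init__(
        self,
        reference_site: str | None = None,
        covariates: tuple[str, ...] = DEFAULT_COVARIATES,
        alpha: float = 0.05,
        pool_metastatic: bool = False,
    ):
        self.reference_site = reference_site
        self.covariates = covariates
        self.alpha = alpha
        self.pool_metastatic = pool_metastatic

    def _resolve_reference(self, X: pd.DataFrame) -> str:
        if self.reference_site is not None:
            return self.reference_site
        require_columns(X, ["is_primary_site"], "SiteEffectModel")
        refs = X.loc[X["is_primary_site"].astype(bool), "biopsy_site"].unique()
        if len(refs) != 1:
            raise ValueError(
                "reference_site not given and the data do not flag exactly one "
                f"primary site (found {sorted(refs)})"
            )
        return str(refs[0])

    def fit(self, X: pd.DataFrame, y=None) -> "SiteEffectModel":
        cancer = None
        if "cancer_type" in X.columns:
            uniq = X["cancer_type"].unique()
            cancer = str(uniq[0]) if len(uniq) == 1 else None
        if self.pool_metastatic:
            self.contrasts_ = metastatic_vs_primary(
                X, tuple(self.covariates), self.alpha, cancer_type=cancer
            )
            self.reference_site_ = "primary"
        else:
            ref = self._resolve_reference(X)
            self.model_fit_ = _fit(X, "biopsy_site", list(self.covariates))
            self.grid_ = reference_grid(self.model_fit_, X)
            self.response_grid_ = regrid_response(self.grid_)
            self.contrasts_ = emm_contrasts(
                self.response_grid_, ref, self.alpha, cancer_type=cancer
            )
            self.reference_site_ = ref
        self.n_obs_ = len(X)
        return self


def run_all(
    cohort: pd.DataFrame,
    site_map: dict[str, str],
    alpha: float = 0.05,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Full contrast table across cancer types.

    Per cancer type: one pooled metastatic-vs-primary row plus one row per
    site level (including the reference-vs-itself row) against the mapped
    primary site. Strata violating model preconditions are skipped with a
    logged reason. Raw p-values are reported; ``adjust="bh"`` adds a
    Benjamini-Hochberg ``p_adjusted`` column.
    """
    require_columns(cohort, ["cancer_type", "biopsy_site", "tmb"], "run_all cohort")
    frames: list[pd.DataFrame] = []
    for cancer, sub in cohort.groupby("cancer_type", sort=True):
        if cancer not in site_map:
            logger.warning("skipping %s: no primary site mapped", cancer)
            continue
        ref = site_map[cancer]
        flagged = sub.assign(is_primary_site=sub["biopsy_site"] == ref)
        try:
            frames.append(
                metastatic_vs_primary(flagged, covariates, alpha, cancer_type=str(cancer))
            )
        except ValueError as e:
            logger.warning("skipping pooled contrast for %s: %s", cancer, e)
        try:
            fit = _fit(sub, "biopsy_site", list(covariates))
            rgrid = regrid_response(reference_grid(fit, sub))
            frames.append(emm_contrasts(rgrid, ref, alpha, cancer_type=str(cancer)))
        except ValueError as e:
            logger.warning("skipping site contrasts for %s: %s", cancer, e)
    if not frames:
        return pd.DataFrame(columns=CONTRAST_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        mask = out["site"] != out["reference_site"]
        adj = np.full(len(out), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = multipletests(
                out.loc[mask, "p_value"].to_numpy(), method="fdr_bh"
            )[1]
        out["p_adjusted"] = adj
    return out
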