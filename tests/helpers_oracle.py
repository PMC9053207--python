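"""Independent brute-force oracle for the EMM chain.

Deliberately written without reusing any code from the package: OLS by
explicit normal equations via pseudoinverse, reference grid assembled by
hand, the response-scale covariance from a numerical finite-difference
Jacobian, and t-based inference composed step by step. Used to verify the
production chain to tight tolerances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def oracle_design(df: pd.DataFrame, factor: str, covariates: list[str]):
    levels = sorted(df[factor].astype(str).unique())
    X = [np.ones(len(df))]
    names = ["Intercept"]
    for lv in levels[1:]:
        X.append((df[factor].astype(str) == lv).to_numpy(float))
        names.append(f"{factor}[{lv}]")
    for c in covariates:
        X.append(df[c].to_numpy(float))
        names.append(c)
    return np.column_stack(X), names, levels


def oracle_ols(df: pd.DataFrame, factor: str, covariates: list[str]):
    """Normal-equations OLS of log(tmb+1): beta, covariance, df, sigma2."""
    X, names, levels = oracle_design(df, factor, covariates)
    y = np.log(df["tmb"].to_numpy(float) + 1.0)
    xtx_inv = np.linalg.pinv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    return beta, sigma2 * xtx_inv, dof, sigma2, names, levels


def oracle_grid(df, factor, covariates, beta, cov, names, levels):
    """Linear rows at covariate means, one per level; eta and its covariance."""
    means = {c: df[c].mean() for c in covariates}
    L = []
    for lv in levels:
        row = []
        for name in names:
            if name == "Intercept":
                row.append(1.0)
            elif name == f"{factor}[{lv}]":
                row.append(1.0)
            elif name in means:
                row.append(means[name])
            else:
                row.append(0.0)
        L.append(row)
    L = np.array(L)
    return L @ beta, L @ cov @ L.T


def oracle_regrid_fd(eta, eta_cov, h=1e-6):
    """Response-scale mean/cov with a finite-difference Jacobian of exp(x)-1."""
    g = lambda x: np.exp(x) - 1.0
    k = len(eta)
    J = np.zeros((k, k))
    for j in range(k):
        e = np.zeros(k)
        e[j] = h
        J[:, j] = (g(eta + e) - g(eta - e)) / (2 * h)
    return g(eta), J @ eta_cov @ J.T


def oracle_contrast(mean, cov, dof, i, r, alpha=0.05):
    est = mean[i] - mean[r]
    se = np.sqrt(cov[i, i] + cov[r, r] - 2 * cov[i, r])
    tdist = stats.t(dof)
    p = 2 * tdist.sf(abs(est) / se)
    tc = tdist.ppf(1 - alpha / 2)
    return est, est - tc * se, est + tc * se, p


def oracle_chain(df: pd.DataFrame, reference: str, covariates: list[str], alpha=0.05):
    """Full independent chain: OLS -> grid -> delta regrid -> t contrasts."""
    beta, cov, dof, sigma2, names, levels = oracle_ols(df, "biopsy_site", covariates)
    eta, eta_cov = oracle_grid(df, "biopsy_site", covariates, beta, cov, names, levels)
    m, V = oracle_regrid_fd(eta, eta_cov)
    r = levels.index(reference)
    rows = {}
    for i, lv in enumerate(levels):
        if lv == reference:
            continue
        rows[lv] = oracle_contrast(m, V, dof, i, r, alpha)
    return rows


def brute_force_signed_rank_p(diffs: np.ndarray) -> float:
    """Exact two-sided signed-rank p by explicit 2^n enumeration."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for mask in range(2**n):
        signs = np.array([(mask >> i) & 1 for i in range(n)], bool)
        ws.append(ranks[signs].sum())
    ws = np.array(ws)
    total = len(ws)
    p_le = np.sum(ws <= w_obs + 1e-12) / total
    p_ge = np.sum(ws >= w_obs - 1e-12) / total
    return min(1.0, 2 * min(p_le, p_ge))
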