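"""Differential expression against a continuous obesity index.

Per gene j and sample i the model is

    y_ij = b0_j + beta_OI,j * OI_i + beta_sex,j * sex_i + e_ij

fitted by (weighted) least squares, followed by empirical-Bayes moderation
of the residual variances toward a shared prior (d0, s0^2) estimated by
moment matching on the log sample variances, moderated t-statistics with
d0 + d_g degrees of freedom, Benjamini-Hochberg adjustment, and calling of
genes at FDR < 0.05.  An intercept is always included (the slope on a
non-centered response is meaningless without one); sex is coded 0/1 with
female = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .datatypes import ProcessedExpression, SampleTable

__all__ = [
    "GeneFit",
    "ModeratedResult",
    "fit_gene_models",
    "moderate_statistics",
    "benjamini_hochberg",
    "call_de_genes",
    "run_de",
]

log = logging.getLogger(__name__)


@dataclass
class GeneFit:
    gene_id: str
    beta_oi: float
    beta_sex: float
    se_beta_oi: float
    sigma2: float  # residual variance s_g^2
    df_residual: float  # d_g
    stdized_unscaled: float  # v_g, unscaled variance of beta_oi


@dataclass
class ModeratedResult:
    gene_id: str
    beta_oi: float
    t_moderated: float
    p_value: float
    p_adjusted: float
    log_odds: float
    direction: str  # up_in_obese / down_in_obese
    d0: float
    s0_sq: float


def fit_gene_models(
    expr: ProcessedExpression, samples: SampleTable
) -> list[GeneFit]:
    """Exact per-gene OLS/WLS on the design [intercept, OI, sex]."""
    sample_ids = expr.sample_ids
    tab = samples.table.loc[sample_ids]
    n = len(sample_ids)
    if n <= 3:
        raise ValueError("need more than 3 samples to fit intercept + OI + sex")
    oi = tab["oi"].to_numpy(dtype=float)
    sex = (tab["sex"] == "male").astype(float).to_numpy()
    if np.ptp(oi) == 0:
        raise ValueError("OI constant across samples: slope not estimable")
    cols = [np.ones(n), oi]
    names = ["intercept", "oi"]
    if np.ptp(sex) > 0:
        cols.append(sex)
        names.append("sex")
    else:
        log.warning("single-sex design: dropping the sex term")
    X = np.column_stack(cols)
    p = X.shape[1]
    oi_idx = names.index("oi")
    sex_idx = names.index("sex") if "sex" in names else None

    Y = expr.values.to_numpy(dtype=float)
    if expr.weights is not None:
        W = expr.weights.to_numpy(dtype=float)
        # batched weighted normal equations, one 3x3 solve per gene
        XtWX = np.einsum("gn,nk,nl->gkl", W, X, X)
        XtWy = np.einsum("gn,nk->gk", W * Y, X)
        beta = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]
        resid = Y - beta @ X.T
        rss = np.einsum("gn,gn->g", W * resid, resid)
        covu = np.linalg.inv(XtWX)  # unscaled (sigma^2-free) covariance
        v_oi = covu[:, oi_idx, oi_idx]
    else:
        XtX = X.T @ X
        beta = np.linalg.solve(XtX, X.T @ Y.T).T
        resid = Y - beta @ X.T
        rss = np.einsum("gn,gn->g", resid, resid)
        v_oi = np.full(Y.shape[0], np.linalg.inv(XtX)[oi_idx, oi_idx])

    df = n - p
    sigma2 = rss / df
    se = np.sqrt(np.maximum(sigma2, 0.0) * v_oi)
    fits = []
    for g, gid in enumerate(expr.gene_ids):
        fits.append(
            GeneFit(
                gene_id=gid,
                beta_oi=float(beta[g, oi_idx]),
                beta_sex=float(beta[g, sex_idx]) if sex_idx is not None else 0.0,
                se_beta_oi=float(se[g]),
                sigma2=float(sigma2[g]),
                df_residual=float(df),
                stdized_unscaled=float(v_oi[g]),
            )
        )
    return fits


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(
    sigma2: np.ndarray, df: np.ndarray
) -> tuple[float, float]:
    """Estimate the shared prior (d0, s0^2) for the residual variances.

    Matches the first two moments of log(s_g^2): with s_g^2 ~ s0^2 *
    (chi2_d0/d0)^-1 * chi2_dg/dg, e_g = log s_g^2 - digamma(dg/2) +
    log(dg/2) has mean log s0^2 + digamma(d0/2) - log(d0/2) and variance
    trigamma(d0/2) + trigamma(dg/2); d0 comes from a trigamma inversion.
    """
    s2 = np.maximum(np.asarray(sigma2, dtype=float), 1e-12)
    df = np.asarray(df, dtype=float)
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1)
    excess = evar - special.polygamma(1, df / 2.0).mean()
    if excess <= 0:
        return np.inf, float(np.exp(emean))
    half_d0 = _trigamma_inverse(float(excess))
    d0 = 2.0 * half_d0
    # E[e] = log s0^2 - digamma(d0/2) + log(d0/2) under the inverse-chi2 prior
    s0_sq = float(np.exp(emean + special.digamma(half_d0) - np.log(half_d0)))
    return float(d0), s0_sq


def _log_odds(
    t: np.ndarray, df_total: np.ndarray, v: np.ndarray, proportion: float
) -> np.ndarray:
    """B-statistic (log posterior odds of differential expression).

    Uses the standard moderated-t mixture: a fraction ``proportion`` of
    genes has slope variance inflated by v0, estimated from the most
    extreme t-statistics by quantile matching.
    """
    G = len(t)
    ntarget = max(int(np.ceil(proportion / 2.0 * G)), 1)
    order = np.argsort(-np.abs(t))
    top = order[:ntarget]
    # expected tail quantiles of the top |t| under a uniform p-value rank
    ptarget = (np.arange(ntarget) + 0.5) / G / 2.0
    ttarget = stats.t.isf(ptarget, df_total[top])
    v0_top = v[top] * np.maximum((np.abs(t[top]) / ttarget) ** 2 - 1.0, 0.0)
    v0 = float(np.mean(v0_top)) if ntarget else 0.0
    k = v / (v + v0) if v0 > 0 else np.ones_like(v)
    odds_prior = np.log(proportion / (1.0 - proportion))
    with np.errstate(divide="ignore", invalid="ignore"):
        b = (
            odds_prior
            + 0.5 * np.log(k)
            + (df_total + 1.0) / 2.0
            * np.log((t ** 2 + df_total) / (k * t ** 2 + df_total))
        )
    return b


def moderate_statistics(
    fits: list[GeneFit],
    prior_proportion: float = 0.01,
    d0_override: float | None = None,
) -> list[ModeratedResult]:
    """Empirical-Bayes moderated t-statistics, p-values and B-statistics.

    The posterior residual variance is s~_g^2 = (d0 s0^2 + d_g s_g^2) /
    (d0 + d_g); t_mod = beta / (s~_g sqrt(v_g)) on d0 + d_g df.
    ``d0_override`` forces the prior df (0 recovers ordinary t; inf gives
    complete shrinkage to s0^2).
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 genes to moderate variances")
    sigma2 = np.array([f.sigma2 for f in fits])
    df = np.array([f.df_residual for f in fits])
    beta = np.array([f.beta_oi for f in fits])
    v = np.array([f.stdized_unscaled for f in fits])

    if d0_override is not None:
        d0 = float(d0_override)
        _, s0_sq = estimate_prior(sigma2, df)
        if not np.isfinite(d0):
            post_s2 = np.full_like(sigma2, s0_sq)
        elif d0 == 0:
            post_s2 = sigma2.copy()
        else:
            post_s2 = (d0 * s0_sq + df * sigma2) / (d0 + df)
    else:
        d0, s0_sq = estimate_prior(sigma2, df)
        if np.isfinite(d0):
            post_s2 = (d0 * s0_sq + df * sigma2) / (d0 + df)
        else:
            log.warning("no excess variance dispersion: complete shrinkage")
            post_s2 = np.full_like(sigma2, s0_sq)

    df_total = df + (d0 if np.isfinite(d0) else np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / np.sqrt(np.maximum(post_s2, 1e-300) * v)
    if np.isfinite(d0):
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
        b = _log_odds(t, df_total, v, prior_proportion)
    else:
        p = 2.0 * stats.norm.sf(np.abs(t))
        b = _log_odds(t, np.full_like(t, 1e6), v, prior_proportion)
    p_adj = benjamini_hochberg(p)

    results = []
    for g, f in enumerate(fits):
        results.append(
            ModeratedResult(
                gene_id=f.gene_id,
                beta_oi=f.beta_oi,
                t_moderated=float(t[g]),
                p_value=float(p[g]),
                p_adjusted=float(p_adj[g]),
                log_odds=float(b[g]),
                direction="up_in_obese" if f.beta_oi > 0 else "down_in_obese",
                d0=float(d0),
                s0_sq=float(s0_sq),
            )
        )
    return results


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    adj_(i) = min_{j >= i} (p_(j) * m / j), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def call_de_genes(
    results: list[ModeratedResult], fdr: float = 0.05
) -> tuple[list[ModeratedResult], dict[str, int]]:
    """Call DE genes at adjusted p strictly below ``fdr``; positive OI
    slope means up-regulated in obese animals."""
    if not results:
        raise ValueError("no results to call")
    de = [r for r in results if r.p_adjusted < fdr]
    counts = {
        "up_in_obese": sum(r.direction == "up_in_obese" for r in de),
        "down_in_obese": sum(r.direction == "down_in_obese" for r in de),
    }
    return de, counts


def run_de(
    expr: ProcessedExpression,
    samples: SampleTable,
    fdr: float = 0.05,
    prior_proportion: float = 0.01,
) -> pd.DataFrame:
    """Full DE stage; returns a per-gene table sorted by p then gene id."""
    fits = fit_gene_models(expr, samples)
    results = moderate_statistics(fits, prior_proportion=prior_proportion)
    rows = [
        {
            "gene_id": r.gene_id,
            "beta_oi": r.beta_oi,
            "t_mod": r.t_moderated,
            "p": r.p_value,
            "p_adj": r.p_adjusted,
            "log_odds": r.log_odds,
            "direction": r.direction,
            "is_de": r.p_adjusted < fdr,
        }
        for r in results
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["p", "gene_id"], kind="mergesort")
        .reset_index(drop=True)
    )
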