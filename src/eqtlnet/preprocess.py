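"""Count preprocessing: the two normalization stacks of the pipeline.

The differential-expression stack is low-count filter (total mode) ->
median-of-ratios size factors -> voom-style log2-CPM with optional
precision weights (-> optional sex correction).  The eQTL stack is
low-count filter (any-sample mode) -> quantile normalization -> log2 ->
per-gene centering -> per-sample z-transform -> removal of the leading
expression principal components.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata
import statsmodels.api as sm

from .datatypes import ExpressionCounts, ProcessedExpression

__all__ = [
    "filter_low_expression",
    "median_of_ratios_size_factors",
    "voom_transform",
    "regress_out_covariate",
    "eqtl_normalize",
    "remove_principal_components",
    "remove_nongenetic_pcs",
]

log = logging.getLogger(__name__)


def filter_low_expression(
    counts: ExpressionCounts, threshold: int = 5, mode: str = "any_sample"
) -> ExpressionCounts:
    """Remove lowly expressed genes.

    ``any_sample`` (eQTL stack): drop a gene if its count falls below
    ``threshold`` in any sample (min < threshold).  ``total`` (DE stack):
    drop a gene whose counts are at or below ``threshold`` in every sample
    (max <= threshold).  Surviving gene order is preserved.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    mat = counts.counts.to_numpy()
    if mode == "any_sample":
        keep = mat.min(axis=1) >= threshold
    elif mode == "total":
        keep = mat.max(axis=1) > threshold
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    if not keep.any():
        raise ValueError(
            "low-expression filter removed every gene; lower the threshold"
        )
    kept = [g for g, k in zip(counts.gene_ids, keep) if k]
    log.info("low-expression filter (%s, >=%d): kept %d/%d genes",
             mode, threshold, len(kept), len(keep))
    return counts.subset_genes(kept)


def median_of_ratios_size_factors(counts: ExpressionCounts) -> pd.Series:
    """DESeq-style median-of-ratios library size factors.

    factor_j = median over reference genes of count_gj / geometric mean of
    gene g across samples; genes with a zero count in any sample are
    excluded from the reference set.
    """
    mat = counts.counts.to_numpy(dtype=float)
    usable = (mat > 0).all(axis=1)
    if not usable.any():
        raise ValueError("no gene has nonzero counts in every sample")
    ref = mat[usable]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def _lowess_trend(x: np.ndarray, y: np.ndarray, frac: float = 0.5):
    """Fitted lowess trend returned as an interpolator over x."""
    fit = sm.nonparametric.lowess(y, x, frac=frac, return_sorted=True)
    xs, ys = fit[:, 0], fit[:, 1]

    def predict(q: np.ndarray) -> np.ndarray:
        return np.interp(q, xs, ys)

    return predict


def voom_transform(
    counts: ExpressionCounts,
    size_factors: pd.Series,
    use_weights: bool = True,
) -> ProcessedExpression:
    """Variance-stabilizing log2-CPM with optional precision weights.

    values = log2((count + 0.5) / (effective library size + 1) * 1e6)
    with effective library size = size factor x mean column sum.  Scaling
    by the composition-robust size factor (rather than each sample's own
    column sum) keeps strongly regulated high-abundance genes from biasing
    every other gene's log-CPM.  Weights come from a lowess trend of
    sqrt(per-gene residual SD) against mean log2-count, evaluated at each
    observation's fitted log2 count and raised to the power -4.
    """
    sf = size_factors.loc[counts.sample_ids].to_numpy(dtype=float)
    if (sf <= 0).any():
        raise ValueError("size factors must be positive")
    mat = counts.counts.to_numpy(dtype=float)
    lib_eff = sf * mat.sum(axis=0).mean()
    values = np.log2((mat + 0.5) / (lib_eff + 1.0)[None, :] * 1e6)
    vdf = pd.DataFrame(values, index=counts.gene_ids, columns=counts.sample_ids)

    weights = None
    if use_weights:
        if mat.shape[0] < 10:
            log.warning("fewer than 10 genes; falling back to unweighted voom")
        else:
            # mean-variance trend: sqrt(per-gene SD) against mean log2 count
            log_lib = np.log2(lib_eff + 1.0)
            mean_log_count = values.mean(axis=1) + log_lib.mean() - np.log2(1e6)
            sqrt_sd = np.sqrt(values.std(axis=1, ddof=1))
            trend = _lowess_trend(mean_log_count, sqrt_sd)
            # evaluate at the gene's mean log2-CPM shifted by each sample's
            # library offset: signal-independent, so weights do not feed
            # back into the residuals
            fitted_log_count = (
                values.mean(axis=1)[:, None] + log_lib[None, :] - np.log2(1e6)
            )
            pred = np.clip(trend(fitted_log_count), 1e-3, None)
            w = pred ** -4.0
            weights = pd.DataFrame(
                w, index=counts.gene_ids, columns=counts.sample_ids
            )
    return ProcessedExpression(
        values=vdf,
        weights=weights,
        provenance=["voom_log2cpm" + ("+weights" if weights is not None else "")],
        gene_meta=counts.gene_meta,
    )


def regress_out_covariate(
    expr: ProcessedExpression, covariate: pd.Series | np.ndarray
) -> ProcessedExpression:
    """Replace each gene by residuals of OLS on intercept + covariate.

    A factor covariate (e.g. sex) should be passed numerically coded.
    Residuals are exactly orthogonal to the covariate.
    """
    cov = np.asarray(
        covariate.loc[expr.sample_ids] if isinstance(covariate, pd.Series) else covariate,
        dtype=float,
    )
    if len(cov) != len(expr.sample_ids):
        raise ValueError("covariate length must equal sample count")
    if np.ptp(cov) == 0:
        log.warning("constant covariate: regress_out_covariate is a no-op")
        return expr.evolve(expr.values.copy(), "regress_covariate(identity)")
    X = np.column_stack([np.ones_like(cov), cov])
    Y = expr.values.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y - (X @ beta).T
    out = pd.DataFrame(resid, index=expr.gene_ids, columns=expr.sample_ids)
    return expr.evolve(out, "regress_covariate")


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Cross-sample quantile normalization.

    Each sample's sorted values are replaced by the cross-sample mean of
    order statistics; tied values receive the mean of the reference values
    at their tied ranks, so every column ends with the same multiset of
    values (up to tie handling).
    """
    mat = values.to_numpy(dtype=float)
    order_means = np.sort(mat, axis=0).mean(axis=1)
    out = np.empty_like(mat)
    n = mat.shape[0]
    for j in range(mat.shape[1]):
        ranks = rankdata(mat[:, j], method="average")  # 1..n, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), order_means)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def eqtl_normalize(counts: ExpressionCounts) -> ProcessedExpression:
    """The eQTL-stack normalization, applied in order: quantile
    normalization across samples, log2, per-gene mean-centering, and a
    per-sample z-transform (each sample column to mean 0, SD 1).

    Expects counts already filtered in ``any_sample`` mode so every value
    is positive before the log.
    """
    qn = quantile_normalize(counts.counts.astype(float))
    if (qn.to_numpy() <= 0).any():
        raise ValueError(
            "nonpositive values after quantile normalization; apply the "
            "any_sample low-count filter first"
        )
    vals = np.log2(qn.to_numpy())
    vals = vals - vals.mean(axis=1, keepdims=True)  # gene-level centering
    sd = vals.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise ValueError("sample with zero variance after centering")
    vals = (vals - vals.mean(axis=0, keepdims=True)) / sd
    out = pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids)
    return ProcessedExpression(
        values=out,
        provenance=["quantile_normalize", "log2", "gene_center", "sample_ztransform"],
        gene_meta=counts.gene_meta,
    )


def remove_nongenetic_pcs(
    expr: ProcessedExpression,
    genotypes,
    n_pcs: int,
    alpha: float = 0.05,
    max_scan: int | None = None,
) -> ProcessedExpression:
    """Project out the top ``n_pcs`` sample-space components that are NOT
    under genetic control.

    Leading expression components are scanned in order of variance; a
    component whose sample loadings associate with any SNP dosage at a
    Bonferroni-corrected Spearman p below ``alpha`` is considered
    genetically driven (it carries eQTL signal, e.g. from linked cis
    effects or family structure) and is kept; the first ``n_pcs``
    non-genetic components are removed.  With no genetically controlled
    components this reduces to :func:`remove_principal_components`.
    """
    from scipy.stats import rankdata as _rankdata
    from scipy import stats as _stats

    n_genes, n_samples = expr.values.shape
    if not 0 <= n_pcs < min(n_genes, n_samples):
        raise ValueError(f"n_pcs must lie in [0, {min(n_genes, n_samples) - 1}]")
    if n_pcs == 0:
        return expr.evolve(expr.values.copy(), "remove_pcs(0)", removed_pcs=0)
    X = expr.values.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)

    dos = genotypes.dosage.loc[expr.sample_ids].to_numpy(dtype=float)
    dos = np.where(np.isnan(dos), np.nanmean(dos, axis=0, keepdims=True), dos)
    keep_cols = np.ptp(dos, axis=0) > 0
    dos = dos[:, keep_cols]
    rd = _rankdata(dos, axis=0)
    rd = (rd - rd.mean(axis=0)) / np.where(rd.std(axis=0) == 0, 1, rd.std(axis=0))
    n_snps = rd.shape[1]
    thresh = alpha / max(n_snps, 1)

    if max_scan is None:
        max_scan = min(n_pcs + 10, vt.shape[0])
    removed: list[int] = []
    protected: list[int] = []
    for k in range(max_scan):
        if len(removed) == n_pcs:
            break
        v = vt[k]
        rv = _rankdata(v)
        rv = (rv - rv.mean()) / rv.std()
        rho_max = float(np.max(np.abs(rd.T @ rv)) / n_samples)
        rho_max = min(rho_max, 1 - 1e-15)
        t = rho_max * np.sqrt((n_samples - 2) / (1 - rho_max**2))
        p = 2.0 * _stats.t.sf(t, n_samples - 2)
        if p < thresh:
            protected.append(k)
        else:
            removed.append(k)
    if protected:
        log.info("PC removal: protected genetically controlled components %s",
                 [k + 1 for k in protected])
    if not removed:
        return expr.evolve(expr.values.copy(), "remove_pcs(0;all_genetic)",
                           removed_pcs=0)
    V = vt[removed].T  # samples x removed
    resid = Xc - (Xc @ V) @ V.T
    out = pd.DataFrame(resid, index=expr.gene_ids, columns=expr.sample_ids)
    return expr.evolve(
        out, f"remove_nongenetic_pcs({len(removed)})", removed_pcs=len(removed)
    )


def remove_principal_components(
    expr: ProcessedExpression, n_pcs: int
) -> ProcessedExpression:
    """Project out the top ``n_pcs`` sample-space principal components.

    Components are computed on the gene-centered matrix; the removal is a
    projection, so applying it twice with the same ``n_pcs`` is idempotent.
    The leading expression PCs typically capture technical/batch variation,
    and removing a few increases eQTL yield.
    """
    n_genes, n_samples = expr.values.shape
    if not 0 <= n_pcs < min(n_genes, n_samples):
        raise ValueError(f"n_pcs must lie in [0, {min(n_genes, n_samples) - 1}]")
    if n_pcs == 0:
        return expr.evolve(expr.values.copy(), "remove_pcs(0)", removed_pcs=0)
    X = expr.values.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    # right singular vectors = sample-space components
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    V = vt[:n_pcs].T  # samples x n_pcs
    resid = Xc - (Xc @ V) @ V.T
    out = pd.DataFrame(resid, index=expr.gene_ids, columns=expr.sample_ids)
    return expr.evolve(out, f"remove_pcs({n_pcs})", removed_pcs=n_pcs)
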