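"""cis/trans eQTL mapping with permutation-based FDR.

SNP quality control (call rate > 0.95, MAF > 0.05, exact Hardy-Weinberg
P > 1e-4, all strict), Spearman rank association between alternate-allele
dosage and normalized expression, a 1-Mb cis window around the gene TSS,
and an empirical FDR from permutations of the expression sample labels
(ten by default) that preserve the gene-gene correlation structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .datatypes import GenotypeMatrix, ProcessedExpression

__all__ = [
    "SnpQcReport",
    "hwe_exact_test",
    "snp_qc",
    "classify_pair",
    "rank_association",
    "map_eqtls",
    "permutation_fdr",
    "top_eqtl_per_gene",
    "summarize_eqtls",
    "scan_pc_removal",
]

log = logging.getLogger(__name__)

CIS_WINDOW_BP = 1_000_000

RECORD_COLUMNS = [
    "snp_id",
    "gene_id",
    "kind",
    "distance_bp",
    "rho",
    "p_value",
    "n_used",
]


@dataclass
class SnpQcReport:
    snp_id: str
    call_rate: float
    maf: float
    hwe_p: float
    passed: bool
    reasons: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test conditional on the allele counts.

    P = sum of probabilities of all heterozygote counts (same parity as
    the minor-allele count) whose conditional probability does not exceed
    the observed one.  Monomorphic markers return 1 by convention.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0

    # probabilities over het counts via the standard recurrence,
    # normalized at the end
    mid = n_rare * (2 * n - n_rare) // (2 * n)
    if (mid % 2) != (n_rare % 2):
        mid += 1
    probs = {mid: 1.0}
    het = mid
    while het >= 2:
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        nxt = probs[het] * het * (het - 1.0) / (4.0 * (hom_r + 1.0) * (hom_c + 1.0))
        probs[het - 2] = nxt
        het -= 2
    het = mid
    while het + 2 <= min(n_rare, 2 * n - n_rare):
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        nxt = probs[het] * 4.0 * hom_r * hom_c / ((het + 2.0) * (het + 1.0))
        probs[het + 2] = nxt
        het += 2
    total = sum(probs.values())
    obs = probs[n_het] / total
    p = sum(v for v in probs.values() if v / total <= obs * (1 + 1e-12)) / total
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# SNP QC


def snp_qc(
    genotypes: GenotypeMatrix,
    call_rate_min: float = 0.95,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-4,
) -> tuple[GenotypeMatrix, list[SnpQcReport]]:
    """Filter SNPs on call rate, MAF and Hardy-Weinberg equilibrium.

    All thresholds are strict (a SNP exactly at a boundary is removed),
    matching 'above 0.95', 'above 0.05' and 'P > 1e-4'.
    """
    dos = genotypes.dosage.to_numpy(dtype=float)
    n = dos.shape[0]
    reports: list[SnpQcReport] = []
    keep: list[str] = []
    for j, snp in enumerate(genotypes.snp_ids):
        col = dos[:, j]
        obs = col[~np.isnan(col)]
        call_rate = len(obs) / n
        if len(obs) == 0:
            maf, hwe_p = 0.0, 1.0
        else:
            p_alt = obs.mean() / 2.0
            maf = min(p_alt, 1.0 - p_alt)
            n_hom_ref = int((obs == 0).sum())
            n_het = int((obs == 1).sum())
            n_hom_alt = int((obs == 2).sum())
            hwe_p = hwe_exact_test(n_hom_ref, n_het, n_hom_alt)
        reasons = []
        if not call_rate > call_rate_min:
            reasons.append("call_rate")
        if not maf > maf_min:
            reasons.append("maf")
        if not hwe_p > hwe_p_min:
            reasons.append("hwe")
        passed = not reasons
        reports.append(
            SnpQcReport(snp, call_rate, float(maf), float(hwe_p), passed, tuple(reasons))
        )
        if passed:
            keep.append(snp)
    if not keep:
        raise ValueError("no SNP passed quality control")
    log.info("SNP QC: kept %d/%d SNPs", len(keep), genotypes.n_snps)
    return genotypes.subset_snps(keep), reports


# ---------------------------------------------------------------------------
# association


def classify_pair(
    snp_chrom: str,
    snp_pos: int,
    gene_chrom: str,
    gene_tss: int,
    window_bp: int = CIS_WINDOW_BP,
) -> tuple[str, float]:
    """cis iff same chromosome and |SNP - TSS| strictly below the window;
    signed distance (SNP - TSS) is reported for same-chromosome pairs and
    NaN across chromosomes."""
    if snp_pos <= 0 or gene_tss <= 0:
        raise ValueError("positions must be positive")
    if snp_chrom != gene_chrom:
        return "trans", float("nan")
    dist = float(snp_pos - gene_tss)
    kind = "cis" if abs(dist) < window_bp else "trans"
    return kind, dist


def rank_association(dosage, expr) -> tuple[float, float, int]:
    """Spearman correlation (average ranks for ties) between dosage and
    expression over pairwise-complete samples, with the t-approximation
    p-value on n-2 df.  Returns (rho, p, n_used); constant input raises.
    """
    d = np.asarray(dosage, dtype=float)
    e = np.asarray(expr, dtype=float)
    ok = ~(np.isnan(d) | np.isnan(e))
    d, e = d[ok], e[ok]
    n = len(d)
    if n < 4:
        raise ValueError("need at least 4 pairwise-complete samples")
    if np.ptp(d) == 0 or np.ptp(e) == 0:
        raise ValueError("constant dosage or expression")
    rd = rankdata(d)
    re_ = rankdata(e)
    rho = float(np.corrcoef(rd, re_)[0, 1])
    p = _p_from_rho(np.array([rho]), n)[0]
    return rho, float(p), n


def _p_from_rho(rho: np.ndarray, n: int) -> np.ndarray:
    rho_c = np.clip(rho, -1.0 + 1e-15, 1.0 - 1e-15)
    t = rho_c * np.sqrt((n - 2) / (1.0 - rho_c ** 2))
    return 2.0 * stats.t.sf(np.abs(t), n - 2)


def _rank_standardize(mat: np.ndarray) -> np.ndarray:
    """Row-wise average ranks, then z-scored rows (NaN rows not allowed)."""
    r = rankdata(mat, axis=1).astype(float)
    r -= r.mean(axis=1, keepdims=True)
    sd = r.std(axis=1, ddof=0)
    sd[sd == 0] = np.nan
    return r / sd[:, None]


def map_eqtls(
    genotypes: GenotypeMatrix,
    expr: ProcessedExpression,
    window_bp: int = CIS_WINDOW_BP,
    gene_subset: list[str] | None = None,
    snp_subset: list[str] | None = None,
    mode: str = "both",
) -> pd.DataFrame:
    """Test SNP-gene pairs by Spearman rank correlation.

    ``mode`` selects the enumerated pairs: ``cis`` (only pairs within the
    window, indexed by position), ``trans`` (all remaining pairs) or
    ``both``.  Genes without coordinates are excluded from cis/trans
    classification and skipped with a log message.  SNPs with missing
    dosages fall back to per-pair pairwise-complete tests.
    """
    if mode not in ("cis", "trans", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    gene_meta = expr.gene_meta
    if gene_meta is None:
        raise ValueError("expression lacks gene coordinates")

    genes = list(expr.gene_ids)
    if gene_subset is not None:
        missing = set(gene_subset) - set(genes)
        if missing:
            raise ValueError(f"genes not in expression: {sorted(missing)[:5]}")
        genes = [g for g in genes if g in set(gene_subset)]
    snps = list(genotypes.snp_ids)
    if snp_subset is not None:
        missing = set(snp_subset) - set(snps)
        if missing:
            raise ValueError(f"SNPs not in genotypes: {sorted(missing)[:5]}")
        snps = [s for s in snps if s in set(snp_subset)]
    if not genes or not snps:
        raise ValueError("empty gene or SNP set after subsetting")

    annotated = gene_meta.loc[genes].dropna(subset=["chrom", "tss_bp"])
    skipped = set(genes) - set(annotated.index)
    if skipped:
        log.info("excluding %d unannotated genes from eQTL mapping", len(skipped))
    genes = [g for g in genes if g in set(annotated.index)]

    sample_ids = [s for s in expr.sample_ids if s in set(genotypes.sample_ids)]
    E = expr.values.loc[genes, sample_ids].to_numpy(dtype=float)
    D = genotypes.dosage.loc[sample_ids, snps].to_numpy(dtype=float).T  # snps x n
    n = len(sample_ids)

    gene_chrom = annotated.loc[genes, "chrom"].to_numpy()
    gene_tss = annotated.loc[genes, "tss_bp"].to_numpy(dtype=float)
    snp_chrom = genotypes.snp_meta.loc[snps, "chrom"].to_numpy()
    snp_pos = genotypes.snp_meta.loc[snps, "pos_bp"].to_numpy(dtype=float)

    same_chrom = gene_chrom[:, None] == snp_chrom[None, :]
    dist = snp_pos[None, :] - gene_tss[:, None]
    is_cis = same_chrom & (np.abs(dist) < window_bp)
    if mode == "cis":
        pair_mask = is_cis
    elif mode == "trans":
        pair_mask = ~is_cis
    else:
        pair_mask = np.ones_like(is_cis, dtype=bool)

    ZE = _rank_standardize(E)
    snp_missing = np.isnan(D).any(axis=1)
    snp_const = np.array([np.ptp(row[~np.isnan(row)]) == 0 if (~np.isnan(row)).sum() else True for row in D])
    clean = ~snp_missing & ~snp_const
    rho = np.full((len(genes), len(snps)), np.nan)
    if clean.any():
        ZD = _rank_standardize(D[clean])
        rho[:, clean] = (ZE @ ZD.T) / n

    gi, si = np.nonzero(pair_mask)
    rows = {
        "snp_id": np.array(snps, dtype=object)[si],
        "gene_id": np.array(genes, dtype=object)[gi],
        "kind": np.where(is_cis[gi, si], "cis", "trans"),
        "distance_bp": np.where(same_chrom[gi, si], dist[gi, si], np.nan),
        "rho": rho[gi, si],
        "p_value": np.nan,
        "n_used": n,
    }
    out = pd.DataFrame(rows)

    # per-pair fallback for SNPs with missing calls
    dirty = np.nonzero(snp_missing & ~snp_const)[0]
    if len(dirty):
        for j in dirty:
            d = D[j]
            ok = ~np.isnan(d)
            n_ok = int(ok.sum())
            sel = out["snp_id"] == snps[j]
            if n_ok < 4 or np.ptp(d[ok]) == 0:
                out = out[~sel]
                continue
            rd = rankdata(d[ok])
            ZE_ok = _rank_standardize(E[:, ok])
            zd = (rd - rd.mean()) / rd.std(ddof=0)
            r = (ZE_ok @ zd) / n_ok
            gidx = {g: k for k, g in enumerate(genes)}
            rsel = out.loc[sel]
            out.loc[sel, "rho"] = [r[gidx[g]] for g in rsel["gene_id"]]
            out.loc[sel, "n_used"] = n_ok
    if len(np.nonzero(snp_const)[0]):
        const_ids = {snps[j] for j in np.nonzero(snp_const)[0]}
        log.info("skipping %d constant/missing SNPs", len(const_ids))
        out = out[~out["snp_id"].isin(const_ids)]

    out = out.reset_index(drop=True)
    for n_ok, grp in out.groupby("n_used"):
        out.loc[grp.index, "p_value"] = _p_from_rho(
            grp["rho"].to_numpy(dtype=float), int(n_ok)
        )
    return out[RECORD_COLUMNS]


# ---------------------------------------------------------------------------
# permutation FDR


def _qvalues(real_p: np.ndarray, perm_p: list[np.ndarray]) -> np.ndarray:
    """Permutation q-values: FDR(t) = mean permuted count with p <= t over
    the real count with p <= t, monotonized so the estimate is
    nondecreasing in the threshold (each record takes the minimum estimate
    over thresholds at or above its own p)."""
    order = np.argsort(real_p, kind="mergesort")
    sorted_p = real_p[order]
    real_count = np.arange(1, len(sorted_p) + 1)
    perm_counts = np.zeros(len(sorted_p))
    for pp in perm_p:
        pp_sorted = np.sort(pp)
        perm_counts += np.searchsorted(pp_sorted, sorted_p, side="right")
    perm_mean = perm_counts / max(len(perm_p), 1)
    raw = perm_mean / real_count
    mono = np.minimum.accumulate(raw[::-1])[::-1]
    mono = np.minimum(mono, 1.0)
    out = np.empty(len(real_p))
    out[order] = mono
    return out


def estimate_fdr_at(
    real_p: np.ndarray, perm_p: list[np.ndarray], threshold: float
) -> float:
    """Raw permutation FDR estimate at one p-value threshold:
    (mean permuted count with p <= t) / (real count with p <= t), capped
    at 1.  No monotonization — this is the pointwise estimator whose
    calibration the permutation scheme guarantees."""
    real_count = int(np.sum(np.asarray(real_p) <= threshold))
    if real_count == 0:
        return float("nan")
    perm_mean = float(np.mean([np.sum(pp <= threshold) for pp in perm_p]))
    return min(perm_mean / real_count, 1.0)


def permutation_fdr(
    genotypes: GenotypeMatrix,
    expr: ProcessedExpression,
    real_records: pd.DataFrame,
    n_perm: int = 10,
    fdr_threshold: float = 0.05,
    scope: str = "separate",
    seed: int | np.random.Generator = 0,
    window_bp: int = CIS_WINDOW_BP,
    gene_subset: list[str] | None = None,
    snp_subset: list[str] | None = None,
    mode: str = "both",
) -> pd.DataFrame:
    """Attach permutation-based FDR estimates and return significant records.

    Each permutation shuffles the expression sample labels once globally
    (preserving gene-gene correlation), re-runs the identical mapping, and
    the empirical FDR at threshold t is the mean permuted discovery count
    over the real discovery count.  ``scope='separate'`` estimates FDR for
    cis and trans records independently; ``'joint'`` pools them.
    Significant records have FDR strictly below ``fdr_threshold``.
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    records = real_records.copy()
    if records.empty:
        records["fdr"] = []
        return records

    perm_records: list[pd.DataFrame] = []
    sample_ids = list(expr.sample_ids)
    for _ in range(n_perm):
        perm_idx = rng.permutation(len(sample_ids))
        vals = pd.DataFrame(
            expr.values.to_numpy()[:, perm_idx],
            index=expr.values.index,
            columns=sample_ids,
        )
        perm_expr = ProcessedExpression(
            values=vals,
            provenance=[*expr.provenance, "permute_samples"],
            gene_meta=expr.gene_meta,
        )
        full = map_eqtls(
            genotypes,
            perm_expr,
            window_bp=window_bp,
            gene_subset=gene_subset,
            snp_subset=snp_subset,
            mode=mode,
        )
        # only the null p-value distribution per scope is needed
        perm_records.append(full[["kind", "p_value"]])

    records["fdr"] = np.nan
    if scope == "separate":
        scopes = [("cis",), ("trans",)]
    elif scope == "joint":
        scopes = [("cis", "trans")]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    for kinds in scopes:
        mask = records["kind"].isin(kinds)
        if not mask.any():
            continue
        real_p = records.loc[mask, "p_value"].to_numpy(dtype=float)
        perm_p = [
            pr.loc[pr["kind"].isin(kinds), "p_value"].to_numpy(dtype=float)
            for pr in perm_records
        ]
        records.loc[mask, "fdr"] = _qvalues(real_p, perm_p)
    sig = records[records["fdr"] < fdr_threshold].copy()
    return sig.sort_values(["p_value", "snp_id", "gene_id"], kind="mergesort").reset_index(
        drop=True
    )


def top_eqtl_per_gene(records: pd.DataFrame) -> pd.DataFrame:
    """Strongest association per gene: minimum p, ties broken by smaller
    |distance| then lexicographic SNP id."""
    if records.empty:
        return records.copy()
    df = records.copy()
    df["_absdist"] = df["distance_bp"].abs().fillna(np.inf)
    df = df.sort_values(
        ["gene_id", "p_value", "_absdist", "snp_id"], kind="mergesort"
    )
    out = df.groupby("gene_id", sort=True).head(1).drop(columns="_absdist")
    return out.reset_index(drop=True)


def summarize_eqtls(
    records: pd.DataFrame, bin_width_bp: int = 100_000
) -> dict[str, pd.DataFrame | pd.Series]:
    """Summaries: signed cis SNP-TSS distance histogram, per-trans-SNP
    target-gene counts, and cis/trans (and cross-chromosome) totals."""
    cis = records[records["kind"] == "cis"] if len(records) else records
    trans = records[records["kind"] == "trans"] if len(records) else records
    if len(cis):
        d = cis["distance_bp"].to_numpy(dtype=float)
        lo = np.floor(d.min() / bin_width_bp) * bin_width_bp
        hi = np.ceil(d.max() / bin_width_bp) * bin_width_bp
        if hi <= lo:
            hi = lo + bin_width_bp
        bins = np.arange(lo, hi + bin_width_bp, bin_width_bp)
        hist, edges = np.histogram(d, bins=bins)
        hist_df = pd.DataFrame(
            {"bin_start": edges[:-1].astype(np.int64), "bin_end": edges[1:].astype(np.int64), "count": hist}
        )
    else:
        hist_df = pd.DataFrame(columns=["bin_start", "bin_end", "count"])
    targets = (
        trans.groupby("snp_id")["gene_id"].nunique().sort_values(ascending=False)
        if len(trans)
        else pd.Series(dtype=int)
    )
    counts = pd.Series(
        {
            "cis": int(len(cis)),
            "trans": int(len(trans)),
            "trans_cross_chrom": int(trans["distance_bp"].isna().sum()) if len(trans) else 0,
        }
    )
    return {"cis_distance_hist": hist_df, "trans_targets": targets, "counts": counts}


def scan_pc_removal(
    genotypes: GenotypeMatrix,
    expr,
    candidate_n_pcs: list[int],
    n_perm: int = 10,
    fdr_threshold: float = 0.05,
    seed: int = 0,
    window_bp: int = CIS_WINDOW_BP,
    mode: str = "cis",
) -> pd.DataFrame:
    """Map eQTLs for each candidate number of removed PCs and report the
    significant cis / total counts; the count-maximizing choice mirrors
    the 'remove the number of PCs that maximizes eQTL yield' heuristic."""
    from .preprocess import remove_principal_components

    rows = []
    for n_pcs in candidate_n_pcs:
        reduced = remove_principal_components(expr, n_pcs)
        recs = map_eqtls(genotypes, reduced, window_bp=window_bp, mode=mode)
        sig = permutation_fdr(
            genotypes,
            reduced,
            recs,
            n_perm=n_perm,
            fdr_threshold=fdr_threshold,
            seed=seed,
            window_bp=window_bp,
            mode=mode,
        )
        rows.append(
            {
                "n_pcs": n_pcs,
                "n_cis": int((sig["kind"] == "cis").sum()),
                "n_total": int(len(sig)),
            }
        )
    return pd.DataFrame(rows)
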