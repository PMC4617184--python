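"""End-to-end orchestration of the systems-genetics pipeline.

Ties the stages together on in-memory objects: preprocessing (two
normalization stacks), differential expression against the obesity
index, cis/trans eQTL mapping with permutation FDR, supervised
co-expression network analysis on the DE/eQTL gene union, and
integration with module overlap statistics and the merged PPI graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import de as de_mod
from . import eqtl as eqtl_mod
from . import integrate as integrate_mod
from . import network as net_mod
from . import preprocess as pre_mod
from .config import RunConfig
from .datatypes import ExpressionCounts, GenotypeMatrix, ProcessedExpression, SampleTable

__all__ = ["PipelineResult", "run_pipeline", "evaluate_cis_recovery", "evaluate_de_recovery"]

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    de_table: pd.DataFrame
    de_genes: list[str]
    eqtl_records: pd.DataFrame
    significant_eqtls: pd.DataFrame
    top_per_gene: pd.DataFrame
    qc_reports: list
    beta: int | None = None
    soft_threshold_table: pd.DataFrame | None = None
    module_labels: pd.Series | None = None
    eigengenes: pd.DataFrame | None = None
    mtr: pd.DataFrame | None = None
    mtr_p: pd.DataFrame | None = None
    selected_modules: list = field(default_factory=list)
    module_eqtl_table: pd.DataFrame | None = None
    merged_graph: object | None = None
    betweenness: dict | None = None
    communities: dict | None = None
    modularity: float | None = None

    @property
    def cis_count(self) -> int:
        return int((self.significant_eqtls["kind"] == "cis").sum())

    @property
    def trans_count(self) -> int:
        return int((self.significant_eqtls["kind"] == "trans").sum())


def run_pipeline(
    genotypes: GenotypeMatrix,
    counts: ExpressionCounts,
    samples: SampleTable,
    ppi_edges: pd.DataFrame | None = None,
    config: RunConfig | None = None,
    run_network: bool = True,
) -> PipelineResult:
    """Run DE + eQTL mapping (+ optional network/integration stages)."""
    cfg = config or RunConfig()
    cfg.validate()
    sample_ids = [s for s in counts.sample_ids if s in set(genotypes.sample_ids)]
    geno = genotypes.subset_samples(sample_ids)
    counts = counts.subset_samples(sample_ids)
    samples = samples.subset(sample_ids)

    # --- DE stack -----------------------------------------------------
    de_counts = pre_mod.filter_low_expression(
        counts, cfg.low_count_threshold, mode=cfg.de_filter_mode
    )
    size_factors = pre_mod.median_of_ratios_size_factors(de_counts)
    de_expr = pre_mod.voom_transform(de_counts, size_factors, use_weights=cfg.voom_weights)
    if cfg.de_sex_regression:
        de_expr = pre_mod.regress_out_covariate(de_expr, samples.sex_numeric)
    de_table = de_mod.run_de(
        de_expr, samples, fdr=cfg.de_fdr, prior_proportion=cfg.de_prior_proportion
    )
    de_genes = list(de_table.loc[de_table["is_de"], "gene_id"])

    # --- eQTL stack ---------------------------------------------------
    geno_qc, qc_reports = eqtl_mod.snp_qc(
        geno, cfg.call_rate_min, cfg.maf_min, cfg.hwe_p_min
    )
    eqtl_counts = pre_mod.filter_low_expression(
        counts, cfg.low_count_threshold, mode=cfg.eqtl_filter_mode
    )
    eqtl_expr = pre_mod.eqtl_normalize(eqtl_counts)
    if cfg.protect_genetic_pcs:
        eqtl_expr = pre_mod.remove_nongenetic_pcs(
            eqtl_expr, geno_qc, cfg.n_pcs_removed
        )
    else:
        eqtl_expr = pre_mod.remove_principal_components(eqtl_expr, cfg.n_pcs_removed)
    records = eqtl_mod.map_eqtls(
        geno_qc, eqtl_expr, window_bp=cfg.cis_window_bp, mode=cfg.eqtl_mode
    )
    sig = eqtl_mod.permutation_fdr(
        geno_qc,
        eqtl_expr,
        records,
        n_perm=cfg.n_permutations,
        fdr_threshold=cfg.eqtl_fdr,
        scope=cfg.fdr_scope,
        seed=cfg.seed,
        window_bp=cfg.cis_window_bp,
        mode=cfg.eqtl_mode,
    )
    top = eqtl_mod.top_eqtl_per_gene(sig)
    result = PipelineResult(
        de_table=de_table,
        de_genes=de_genes,
        eqtl_records=records,
        significant_eqtls=sig,
        top_per_gene=top,
        qc_reports=qc_reports,
    )
    if not run_network:
        return result

    # --- supervised network ------------------------------------------
    cis_genes = set(sig.loc[sig["kind"] == "cis", "gene_id"])
    union = set(de_genes) | cis_genes
    union &= set(eqtl_expr.gene_ids)
    if len(union) < 30:
        log.warning("DE/eQTL union too small (%d genes); skipping network stage", len(union))
        return result
    net_expr = net_mod.build_input_set(
        set(de_genes) & set(eqtl_expr.gene_ids), cis_genes, eqtl_expr
    )
    beta, scan = net_mod.soft_threshold_scan(
        net_expr,
        candidate_betas=cfg.candidate_betas,
        target_r2=cfg.target_r2,
        signed=cfg.signed_network,
    )
    adj = net_mod.adjacency_matrix(net_expr.values, beta, signed=cfg.signed_network)
    tom = net_mod.topological_overlap(adj)
    labels = net_mod.detect_modules(tom, cfg.min_module_size, cfg.cut_quantile)
    result.beta, result.soft_threshold_table = beta, scan
    result.module_labels = labels
    if not (labels != 0).any():
        log.warning("no modules detected; skipping eigengene/integration stages")
        return result
    eig, _ = net_mod.module_eigengenes(net_expr, labels)
    kme = net_mod.compute_kme(net_expr, eig)
    traits = samples.table[["oi"] + samples.phenotype_columns].astype(float)
    mtr, mtr_p, selected = net_mod.module_trait_relationships(
        eig, traits, cfg.mtr_threshold, cfg.mtr_alpha
    )
    result.eigengenes, result.mtr, result.mtr_p = eig, mtr, mtr_p
    result.selected_modules = selected
    result.module_eqtl_table = integrate_mod.count_module_eqtls(
        labels, cis_genes, universe=set(labels.index)
    )

    if ppi_edges is not None and selected:
        mod = selected[0][0]
        edges = integrate_mod.module_edge_list(
            tom, list(labels.index[labels == mod]), cfg.coexpr_edge_threshold
        )
        graph = integrate_mod.merge_coexpression_ppi(edges, ppi_edges)
        result.merged_graph = graph
        result.betweenness = integrate_mod.betweenness_centrality(graph)
        result.communities, result.modularity = integrate_mod.community_clusters(graph)
    return result


# ---------------------------------------------------------------------------
# truth-table evaluation helpers (synthetic studies)


def evaluate_cis_recovery(
    significant: pd.DataFrame, truth, kind: str = "cis"
) -> dict[str, float]:
    """Recall and empirical FDR against the planted truth.

    Recall is gene-level: a planted gene counts as recovered when it
    carries at least one significant eQTL of the given kind.  The FDR is
    record-level with gene-based truth: a significant record is a true
    positive when its target gene carries a planted effect (markers in
    linkage with the planted SNP tag the same signal, so they are not
    separate false positives), and false otherwise.
    """
    planted = {g for _, g, _ in (truth.planted_cis if kind == "cis" else truth.planted_trans)}
    if len(significant):
        recs = significant.loc[significant["kind"] == kind]
    else:
        recs = significant
    hits = set(recs["gene_id"]) if len(recs) else set()
    tp_genes = len(hits & planted)
    recall = tp_genes / len(planted) if planted else float("nan")
    n_rec = len(recs)
    n_false = int((~recs["gene_id"].isin(planted)).sum()) if n_rec else 0
    fdr = n_false / n_rec if n_rec else 0.0
    return {
        "recall": recall,
        "fdr": fdr,
        "n_detected_genes": float(len(hits)),
        "n_records": float(n_rec),
    }


def evaluate_de_recovery(de_genes: list[str], truth) -> dict[str, float]:
    """Recall and empirical FDR of DE calls against planted OI slopes.

    Genes in OI-driven modules also truly co-vary with the OI, so they are
    excluded from the false-positive count.
    """
    planted = truth.de_gene_ids
    oi_module_genes = {
        g for g, m in truth.module_labels.items() if m in truth.oi_driven_modules
    }
    hits = set(de_genes)
    tp = len(hits & planted)
    fp = len(hits - planted - oi_module_genes)
    scored = tp + fp
    recall = tp / len(planted) if planted else float("nan")
    fdr = fp / scored if scored else 0.0
    return {"recall": recall, "fdr": fdr, "n_called": float(len(hits))}
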