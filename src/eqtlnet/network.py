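"""Supervised weighted gene co-expression network analysis.

The input gene set is the union of eQTL and DE genes.  The adjacency is
|Pearson correlation|^beta (unsigned by default) with beta the smallest
power reaching a scale-free topology fit R^2 of at least 0.90; the
topological overlap measure (TOM) combines direct adjacency and shared
neighbors; modules come from average-linkage hierarchical clustering of
1 - TOM with a static height cut and a minimum module size (25 genes by
default); each module is summarized by its eigengene (first principal
component), correlated with traits (module-trait relationships, MTR) and
with member genes (kME) for membership filtering and hub-gene calling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import ProcessedExpression

__all__ = [
    "NetworkMatrices",
    "ModuleSet",
    "build_input_set",
    "adjacency_matrix",
    "scale_free_fit",
    "soft_threshold_scan",
    "topological_overlap",
    "detect_modules",
    "module_eigengenes",
    "compute_kme",
    "module_trait_relationships",
    "filter_module_membership",
    "identify_hub_gene",
]

log = logging.getLogger(__name__)


@dataclass
class NetworkMatrices:
    beta: int
    r_squared: float
    adjacency: pd.DataFrame
    tom: pd.DataFrame

    @property
    def connectivity(self) -> pd.Series:
        a = self.adjacency
        return a.sum(axis=1) - np.diag(a.to_numpy())


@dataclass
class ModuleSet:
    labels: pd.Series  # gene -> module id (0 = unassigned)
    eigengenes: pd.DataFrame | None = None  # modules x samples
    variance_explained: dict[int, float] = field(default_factory=dict)
    kme: pd.DataFrame | None = None  # genes x modules
    mtr: pd.DataFrame | None = None  # (module, trait) correlation
    mtr_p: pd.DataFrame | None = None
    hubs: dict[int, str] = field(default_factory=dict)

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.labels) - {0})

    def genes_in(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])


def build_input_set(
    de_genes, cis_eqtl_genes, expr: ProcessedExpression
) -> ProcessedExpression:
    """Union of DE and cis-eQTL genes, deduplicated, order as in ``expr``."""
    wanted = set(de_genes) | set(cis_eqtl_genes)
    missing = wanted - set(expr.gene_ids)
    if missing:
        raise ValueError(f"genes absent from expression: {sorted(missing)[:5]}")
    subset = [g for g in expr.gene_ids if g in wanted]
    if not subset:
        raise ValueError("empty DE/eQTL gene union")
    log.info("supervised network input: %d unique genes", len(subset))
    return ProcessedExpression(
        values=expr.values.loc[subset],
        weights=expr.weights.loc[subset] if expr.weights is not None else None,
        provenance=[*expr.provenance, "build_input_set"],
        removed_pcs=expr.removed_pcs,
        gene_meta=expr.gene_meta,
    )


def _drop_constant_genes(values: pd.DataFrame) -> pd.DataFrame:
    sd = values.std(axis=1, ddof=0)
    const = sd == 0
    if const.any():
        log.warning("dropping %d constant genes before correlation", int(const.sum()))
        values = values.loc[~const]
    return values


def adjacency_matrix(
    values: pd.DataFrame, beta: int, signed: bool = False
) -> pd.DataFrame:
    """Soft-threshold adjacency: |cor|^beta (unsigned, default) or
    ((1 + cor)/2)^beta (signed)."""
    cor = np.corrcoef(values.to_numpy(dtype=float))
    cor = np.clip(cor, -1.0, 1.0)
    if signed:
        adj = ((1.0 + cor) / 2.0) ** beta
    else:
        adj = np.abs(cor) ** beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=values.index, columns=values.index)


def scale_free_fit(
    connectivity: np.ndarray, n_bins: int = 10, min_occupied: int = 8
) -> float:
    """Scale-free topology index: R^2 of log10 p(k) against log10 (mean k)
    over equal-width connectivity bins (empty bins dropped), signed
    negative when the log-log slope is positive.

    Fewer than ``min_occupied`` occupied bins means the connectivity
    distribution has collapsed (e.g. an excessive soft power) and the fit
    is reported as 0 rather than a spuriously perfect line.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if len(k) < 2 or np.ptp(k) == 0:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    occupied = counts > 0
    if occupied.sum() < min_occupied:
        return 0.0
    mean_k = np.array(
        [k[idx == b].mean() if counts[b] else np.nan for b in range(n_bins)]
    )
    x = np.log10(mean_k[occupied])
    y = np.log10(counts[occupied] / counts.sum())
    slope, _, r, _, _ = stats.linregress(x, y)
    r2 = float(r ** 2)
    return -r2 if slope > 0 else r2


def soft_threshold_scan(
    expr_subset: ProcessedExpression | pd.DataFrame,
    candidate_betas=range(1, 21),
    target_r2: float = 0.90,
    signed: bool = False,
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Choose the smallest beta whose scale-free fit reaches ``target_r2``;
    if none does, return the beta with the maximum fit (with a warning)."""
    values = (
        expr_subset.values if isinstance(expr_subset, ProcessedExpression) else expr_subset
    )
    values = _drop_constant_genes(values)
    if values.shape[0] < 30:
        log.warning("soft-threshold scan on fewer than 30 genes is unstable")
    rows = []
    chosen = None
    for beta in candidate_betas:
        adj = adjacency_matrix(values, beta, signed=signed)
        k = adj.to_numpy().sum(axis=0) - 1.0
        r2 = scale_free_fit(k, n_bins=n_bins)
        rows.append({"beta": int(beta), "r_squared": r2, "mean_k": float(k.mean())})
        if chosen is None and r2 >= target_r2:
            chosen = int(beta)
    table = pd.DataFrame(rows)
    if chosen is None:
        # fall back to the best-fitting power among those that keep the
        # network non-degenerate (mean connectivity >= 1); an excessive
        # power drives all adjacencies to 0 and fakes a good fit
        viable = table[table["mean_k"] >= 1.0]
        if viable.empty:
            viable = table
        chosen = int(viable.loc[viable["r_squared"].idxmax(), "beta"])
        log.warning(
            "no beta reached R^2 >= %.2f; falling back to argmax beta=%d",
            target_r2,
            chosen,
        )
    return chosen, table


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    L_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu; diagonal 1."""
    a = adjacency.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    L = a @ a  # includes u = i or j only via zeroed diagonal, so exact
    k = a.sum(axis=1)
    kmin = np.minimum(k[:, None], k[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + a) / (kmin + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def detect_modules(
    tom: pd.DataFrame, min_size: int = 25, cut_quantile: float = 0.99
) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    The tree is cut at ``cut_quantile`` times the maximum merge height;
    clusters of at least ``min_size`` genes become modules, labelled 1, 2,
    ... by decreasing size (0 = unassigned).  This deterministic cut
    stands in for the adaptive dynamic tree cut.
    """
    genes = list(tom.index)
    if len(genes) < min_size:
        log.warning("fewer genes than min module size: all unassigned")
        return pd.Series(0, index=genes, name="module")
    dism = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dism, 0.0)
    dism = np.clip((dism + dism.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dism, checks=False), method="average")
    cut_h = cut_quantile * Z[:, 2].max()
    raw = fcluster(Z, t=cut_h, criterion="distance")
    labels = pd.Series(0, index=genes, name="module")
    sizes = pd.Series(raw).value_counts()
    big = sizes[sizes >= min_size]
    # stable ordering: decreasing size, ties by first-occurring raw label
    order = sorted(big.index, key=lambda c: (-big[c], c))
    for new_id, raw_id in enumerate(order, start=1):
        labels[np.asarray(raw) == raw_id] = new_id
    return labels


def module_eigengenes(
    expr_subset: ProcessedExpression | pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, dict[int, float]]:
    """First principal component of each module over samples.

    Genes are standardized first; the eigengene is scaled to unit variance
    and sign-oriented so that its mean correlation with module genes is
    positive.  Returns (modules x samples eigengenes, variance explained).
    """
    values = (
        expr_subset.values if isinstance(expr_subset, ProcessedExpression) else expr_subset
    )
    eigengenes = {}
    varexp = {}
    for mod in sorted(set(labels) - {0}):
        genes = list(labels.index[labels == mod])
        sub = values.loc[genes].to_numpy(dtype=float)
        sd = sub.std(axis=1, ddof=0)
        keep = sd > 0
        if not keep.all():
            log.warning("module %d: dropping %d constant genes from PCA",
                        mod, int((~keep).sum()))
        sub = sub[keep]
        if sub.shape[0] < 2:
            raise ValueError(f"module {mod} has fewer than 2 usable genes")
        z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, ddof=0, keepdims=True)
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        pc = vt[0]
        pc = (pc - pc.mean()) / pc.std(ddof=0)
        cors = np.array([np.corrcoef(row, pc)[0, 1] for row in z])
        if cors.mean() < 0:
            pc = -pc
        eigengenes[mod] = pc
        varexp[mod] = float(s[0] ** 2 / (s ** 2).sum())
    eg = pd.DataFrame(eigengenes, index=values.columns).T
    eg.index.name = "module"
    return eg, varexp


def compute_kme(
    expr_subset: ProcessedExpression | pd.DataFrame, eigengenes: pd.DataFrame
) -> pd.DataFrame:
    """kME: correlation of every gene with every module eigengene."""
    values = (
        expr_subset.values if isinstance(expr_subset, ProcessedExpression) else expr_subset
    )
    V = values.to_numpy(dtype=float)
    E = eigengenes.to_numpy(dtype=float)
    Vz = (V - V.mean(axis=1, keepdims=True))
    Vsd = Vz.std(axis=1, ddof=0)
    Vsd[Vsd == 0] = np.nan
    Vz = Vz / Vsd[:, None]
    Ez = (E - E.mean(axis=1, keepdims=True)) / E.std(axis=1, ddof=0, keepdims=True)
    n = V.shape[1]
    kme = (Vz @ Ez.T) / n
    return pd.DataFrame(kme, index=values.index, columns=eigengenes.index)


def module_trait_relationships(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    select_threshold: float = 0.5,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple[int, str]]]:
    """Pearson MTR between eigengenes and numeric traits with t-test
    p-values; (module, trait) pairs with |MTR| strictly above
    ``select_threshold`` and p below ``alpha`` are selected."""
    samples = list(eigengenes.columns)
    tr = traits.loc[samples]
    n = len(samples)
    cors = pd.DataFrame(index=eigengenes.index, columns=tr.columns, dtype=float)
    pvals = cors.copy()
    for trait in tr.columns:
        y = tr[trait].to_numpy(dtype=float)
        if np.ptp(y[~np.isnan(y)]) == 0:
            log.warning("constant trait %r: MTR undefined", trait)
            continue
        for mod in eigengenes.index:
            x = eigengenes.loc[mod].to_numpy(dtype=float)
            r, p = stats.pearsonr(x, y)
            cors.loc[mod, trait] = r
            pvals.loc[mod, trait] = p
    selected = [
        (int(mod), str(trait))
        for mod in cors.index
        for trait in cors.columns
        if pd.notna(cors.loc[mod, trait])
        and abs(cors.loc[mod, trait]) > select_threshold
        and pvals.loc[mod, trait] < alpha
    ]
    return cors, pvals, selected


def filter_module_membership(
    kme: pd.DataFrame,
    labels: pd.Series,
    own_min: float = 0.6,
    other_max: float = 0.6,
    literal_other_rule: bool = False,
) -> pd.Series:
    """Retain a gene in its module iff its own-module kME is strictly above
    ``own_min`` and its maximum |kME| with any other module is strictly
    below ``other_max``.  ``literal_other_rule=True`` instead *requires*
    cross-module kME above the threshold (the counter-intuitive reading of
    the published rule, exposed for comparison).  Dropped genes become
    unassigned (0)."""
    out = labels.copy()
    for gene in labels.index:
        mod = labels[gene]
        if mod == 0:
            continue
        own = kme.loc[gene, mod] if mod in kme.columns else np.nan
        others = [m for m in kme.columns if m != mod]
        other = kme.loc[gene, others].abs().max() if others else 0.0
        keep_own = pd.notna(own) and own > own_min
        if literal_other_rule:
            keep_other = (not others) or other > other_max
        else:
            keep_other = (not others) or other < other_max
        if not (keep_own and keep_other):
            out[gene] = 0
    return out


def identify_hub_gene(
    module_genes: list[str],
    connectivity: pd.Series,
    kme_own: pd.Series,
    trait_cor: pd.Series,
    kme_min: float = 0.8,
    trait_min: float = 0.6,
) -> tuple[str, list[str]]:
    """Hub gene of a module.

    Primary rule: the member with the highest intramodular connectivity
    (lexicographic gene-id tie-break).  Alternative rule: every member
    with kME strictly above ``kme_min`` and |gene-trait correlation|
    strictly above ``trait_min`` is hub-eligible.  Returns (hub,
    hub_eligible list).
    """
    if not module_genes:
        raise ValueError("module is empty")
    conn = connectivity.loc[module_genes]
    top = conn.max()
    hub = sorted(conn.index[conn == top])[0]
    eligible = sorted(
        g
        for g in module_genes
        if kme_own.get(g, np.nan) > kme_min
        and abs(trait_cor.get(g, np.nan)) > trait_min
    )
    return hub, eligible
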