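"""Synthetic F2-intercross study generator with known planted truth.

Emulates a divergent-breed pig intercross profiled for adipose expression:
two founder lines (by default fixed for alternate alleles, maximizing F2
segregation), an additive heritable Obesity Index (OI), selective
expression profiling of lean / intermediate / obese groups, RNA-seq-like
negative-binomial counts with planted cis-/trans-eQTLs, OI-associated
genes, sex effects and correlated gene modules (some driven by the OI),
and a protein-protein interaction edge list enriched within true modules.

Every generated quantity is recorded in a :class:`TruthRecord` so that
recovery by the analysis stages can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionCounts, GenotypeMatrix, SampleTable

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "SimulatedStudy",
    "simulate_f2_genotypes",
    "simulate_obesity_index",
    "select_profiling_groups",
    "simulate_expression",
    "simulate_ppi",
    "simulate_module_expression",
    "simulate_study",
]

CIS_WINDOW_BP = 1_000_000


@dataclass
class SimulationConfig:
    """Generator parameters.

    Defaults emulate the study design this package models: 279 F2 animals
    from an intercross of two breeds divergent for obesity, genotyped on a
    moderately dense SNP chip, with adipose expression profiled for 12
    lean / 12 intermediate / 12 obese animals selected on an additive
    Obesity Index of heritability ~0.5.  Gene and SNP counts default to a
    desk-scale study (a few thousand markers, ~1,000 genes) rather than a
    full chip/transcriptome.
    """

    n_f2: int = 279
    n_chrom: int = 5
    chrom_length_bp: int = 100_000_000
    n_snps_per_chrom: int = 400
    genetic_map_cm_per_mb: float = 1.0
    n_f1_pairs: int = 93  # ~3 full sibs per family
    founder_fixed: bool = True  # founders fixed for alternate alleles
    founder_alt_freqs: tuple[float, float] = (0.05, 0.95)  # used if not fixed
    missing_rate: float = 0.0

    n_genes: int = 1000
    n_causal_oi_snps: int = 50
    oi_heritability: float = 0.5
    n_cis_eqtl: int = 100
    n_trans_eqtl: int = 10
    cis_effect_sd: float = 0.6  # log2 units per alternate allele
    cis_effect_fixed: float | None = None  # fixed |effect|, random sign
    trans_effect_sd: float = 0.4
    trans_effect_fixed: float | None = None
    n_de_genes: int = 100
    de_effect_range: tuple[float, float] = (0.5, 1.5)  # |slope|, log2 per OI SD
    n_modules: int = 5
    module_sizes: list[int] = field(default_factory=lambda: [60, 50, 40, 30, 25])
    n_oi_driven_modules: int = 2
    module_cor: float = 0.7  # latent-factor loading on the log2 scale
    nb_dispersion: float = 0.1
    libsize_range: tuple[float, float] = (800_000.0, 1_200_000.0)
    sex_effect_sd: float = 0.2
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 2.0

    profile_group_size: int | None = 12  # None profiles every F2 animal
    seed: int = 0

    def validate(self) -> None:
        if self.n_chrom <= 0 or self.n_snps_per_chrom <= 0:
            raise ValueError("need at least one chromosome and one SNP")
        if self.n_f2 <= 0 or self.n_genes <= 0 or self.n_f1_pairs <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.oi_heritability <= 1.0:
            raise ValueError("oi_heritability must lie in [0, 1]")
        if sum(self.module_sizes[: self.n_modules]) > self.n_genes:
            raise ValueError("module sizes exceed gene count")
        if self.n_cis_eqtl > self.n_genes:
            raise ValueError("more cis effects than genes")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass
class TruthRecord:
    """Planted signals, keyed by the generated SNP/gene/module ids."""

    planted_cis: list[tuple[str, str, float]] = field(default_factory=list)
    planted_trans: list[tuple[str, str, float]] = field(default_factory=list)
    oi_causal_snps: list[tuple[str, float]] = field(default_factory=list)
    de_genes: list[tuple[str, float]] = field(default_factory=list)
    module_labels: dict[str, int] = field(default_factory=dict)
    oi_driven_modules: set[int] = field(default_factory=set)

    @property
    def cis_genes(self) -> set[str]:
        return {g for _, g, _ in self.planted_cis}

    @property
    def de_gene_ids(self) -> set[str]:
        return {g for g, _ in self.de_genes}


@dataclass
class SimulatedStudy:
    genotypes: GenotypeMatrix
    counts: ExpressionCounts
    samples: SampleTable
    ppi_edges: pd.DataFrame  # columns: gene_a, gene_b
    truth: TruthRecord
    pedigree: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# genotypes


def _meiosis(
    hap_a: np.ndarray, hap_b: np.ndarray, positions_morgan: np.ndarray, rng
) -> np.ndarray:
    """One gamete from a parent with haplotypes ``hap_a``/``hap_b``.

    Crossovers are a Poisson process along the chromosome (rate 1 per
    Morgan), which yields Haldane map distances between any marker pair.
    """
    length = positions_morgan[-1] - positions_morgan[0] if len(positions_morgan) else 0.0
    n_xo = rng.poisson(length)
    if n_xo:
        breaks = np.sort(
            rng.uniform(positions_morgan[0], positions_morgan[-1], size=n_xo)
        )
        segment = np.searchsorted(breaks, positions_morgan, side="right")
    else:
        segment = np.zeros(len(positions_morgan), dtype=int)
    phase = rng.integers(2)
    use_a = (segment + phase) % 2 == 0
    return np.where(use_a, hap_a, hap_b)


def simulate_f2_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate SNP dosages for an F2 intercross of two divergent founders.

    Founder line A carries the reference allele and line B the alternate
    allele (fixed by default; ``founder_alt_freqs`` gives a polymorphic
    mode).  F1s inherit one haplotype from each line; F2 gametes are
    formed by Poisson-process recombination so that the recombination
    fraction between markers follows the Haldane map function.  Returns
    the dosage matrix and a pedigree table (sample -> F1 mating pair).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n_chrom, m = config.n_chrom, config.n_snps_per_chrom
    morgan_per_bp = config.genetic_map_cm_per_mb / 100.0 / 1e6

    snp_ids, chroms, positions = [], [], []
    pos_morgan_per_chrom = []
    for c in range(n_chrom):
        pos = np.sort(
            rng.choice(np.arange(1, config.chrom_length_bp + 1), size=m, replace=False)
        )
        positions.append(pos)
        chroms.extend([f"chr{c + 1}"] * m)
        snp_ids.extend([f"snp_{c + 1}_{i + 1}" for i in range(m)])
        pos_morgan_per_chrom.append(pos * morgan_per_bp)
    positions = np.concatenate(positions)

    n_snps = n_chrom * m
    if config.founder_fixed:
        hap_line_a = np.zeros(n_snps, dtype=np.int8)
        hap_line_b = np.ones(n_snps, dtype=np.int8)

        def draw_founder_hap(line: str) -> np.ndarray:
            return hap_line_a.copy() if line == "A" else hap_line_b.copy()

    else:
        fa, fb = config.founder_alt_freqs

        def draw_founder_hap(line: str) -> np.ndarray:
            p = fa if line == "A" else fb
            return (rng.random(n_snps) < p).astype(np.int8)

    # F1 parents: one haplotype from each founder line
    f1_haps = []
    for _ in range(2 * config.n_f1_pairs):
        f1_haps.append((draw_founder_hap("A"), draw_founder_hap("B")))

    pair_of = rng.integers(config.n_f1_pairs, size=config.n_f2)
    dosage = np.empty((config.n_f2, n_snps), dtype=float)
    for i in range(config.n_f2):
        sire = f1_haps[2 * pair_of[i]]
        dam = f1_haps[2 * pair_of[i] + 1]
        gamete = np.zeros(n_snps, dtype=np.int8)
        for c in range(n_chrom):
            sl = slice(c * m, (c + 1) * m)
            pm = pos_morgan_per_chrom[c]
            g1 = _meiosis(sire[0][sl], sire[1][sl], pm, rng)
            g2 = _meiosis(dam[0][sl], dam[1][sl], pm, rng)
            gamete[sl] = g1 + g2
        dosage[i] = gamete

    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan

    sample_ids = [f"F2_{i + 1:04d}" for i in range(config.n_f2)]
    ref_alt = rng.choice(list("ACGT"), size=(n_snps, 2))
    same = ref_alt[:, 0] == ref_alt[:, 1]
    ref_alt[same, 1] = np.where(ref_alt[same, 0] == "A", "G", "A")
    snp_meta = pd.DataFrame(
        {
            "chrom": chroms,
            "pos_bp": positions.astype(np.int64),
            "allele_ref": ref_alt[:, 0],
            "allele_alt": ref_alt[:, 1],
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    geno = GenotypeMatrix(
        dosage=pd.DataFrame(dosage, index=sample_ids, columns=snp_ids),
        snp_meta=snp_meta,
    )
    pedigree = pd.DataFrame(
        {"f1_pair": pair_of}, index=pd.Index(sample_ids, name="sample_id")
    )
    return geno, pedigree


# ---------------------------------------------------------------------------
# obesity index and selective profiling


def simulate_obesity_index(
    genotypes: GenotypeMatrix,
    causal: list[tuple[str, float]],
    heritability: float,
    rng: np.random.Generator | None = None,
    allow_no_causal: bool = False,
) -> pd.Series:
    """Additive genetic Obesity Index: OI_i = sum(effect * dosage) + noise.

    Environmental noise variance is set so that var(g)/var(OI) equals
    ``heritability`` in expectation; the result is centered to mean 0.
    With heritability 1 the OI equals the centered genetic value exactly.
    """
    if not 0.0 <= heritability <= 1.0:
        raise ValueError("heritability must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng()
    if not causal:
        if not allow_no_causal:
            raise ValueError(
                "no causal SNPs given; pass allow_no_causal=True for a zero "
                "genetic value"
            )
        g = np.zeros(genotypes.n_samples)
    else:
        snps = [s for s, _ in causal]
        missing = set(snps) - set(genotypes.snp_ids)
        if missing:
            raise ValueError(f"causal SNPs absent from genotypes: {sorted(missing)[:5]}")
        effects = np.array([e for _, e in causal])
        dos = genotypes.dosage.loc[:, snps].to_numpy(dtype=float)
        dos = np.nan_to_num(dos, nan=1.0)  # missing -> mean dosage in an F2
        g = dos @ effects

    g = g - g.mean()
    var_g = float(g.var())
    if heritability == 1.0 or var_g == 0.0:
        e = np.zeros_like(g)
    elif heritability == 0.0:
        g = np.zeros_like(g)
        e = rng.normal(0.0, 1.0, size=len(g))
    else:
        var_e = var_g * (1.0 - heritability) / heritability
        e = rng.normal(0.0, np.sqrt(var_e), size=len(g))
    oi = g + e
    oi -= oi.mean()
    return pd.Series(oi, index=genotypes.sample_ids, name="oi")


def select_profiling_groups(oi: pd.Series, group_size: int) -> pd.Series:
    """Selective expression profiling: label the ``group_size`` lowest-OI
    animals lean, the highest obese, and the ``group_size`` nearest the
    median intermediate.  Ties broken by sample id order.
    """
    n = len(oi)
    if n < 3 * group_size:
        raise ValueError(
            f"population of {n} too small for 3 groups of {group_size}"
        )
    order = oi.reset_index()
    order.columns = ["sample_id", "oi"]
    order = order.sort_values(["oi", "sample_id"], kind="mergesort")
    lean = list(order["sample_id"].iloc[:group_size])
    obese = list(order["sample_id"].iloc[-group_size:])
    taken = set(lean) | set(obese)
    rest = order[~order["sample_id"].isin(taken)].copy()
    med = float(oi.median())
    rest["dist"] = (rest["oi"] - med).abs()
    rest = rest.sort_values(["dist", "sample_id"], kind="mergesort")
    intermediate = list(rest["sample_id"].iloc[:group_size])

    group = pd.Series("none", index=oi.index, name="group")
    group.loc[lean] = "lean"
    group.loc[intermediate] = "intermediate"
    group.loc[obese] = "obese"
    return group


# ---------------------------------------------------------------------------
# expression


def _place_genes(
    config: SimulationConfig,
    snp_meta: pd.DataFrame,
    cis_snps: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Assign gene coordinates; the first len(cis_snps) genes are placed
    within the cis window of their paired SNP."""
    gene_ids = [f"gene_{i + 1:05d}" for i in range(config.n_genes)]
    chroms = np.empty(config.n_genes, dtype=object)
    tss = np.empty(config.n_genes, dtype=np.int64)
    for j, snp in enumerate(cis_snps):
        pos = int(snp_meta.at[snp, "pos_bp"])
        offset = int(rng.integers(-CIS_WINDOW_BP // 2, CIS_WINDOW_BP // 2 + 1))
        t = min(max(pos + offset, 1), config.chrom_length_bp)
        if abs(pos - t) >= CIS_WINDOW_BP:
            raise RuntimeError("planted cis pair fell outside the cis window")
        chroms[j] = snp_meta.at[snp, "chrom"]
        tss[j] = t
    n_rest = config.n_genes - len(cis_snps)
    chroms[len(cis_snps):] = [
        f"chr{c}" for c in rng.integers(1, config.n_chrom + 1, size=n_rest)
    ]
    tss[len(cis_snps):] = rng.integers(1, config.chrom_length_bp + 1, size=n_rest)
    strand = rng.choice(["+", "-"], size=config.n_genes)
    return pd.DataFrame(
        {"chrom": chroms, "tss_bp": tss, "strand": strand},
        index=pd.Index(gene_ids, name="gene_id"),
    )


def simulate_expression(
    genotypes: GenotypeMatrix,
    samples: SampleTable,
    truth: TruthRecord,
    config: SimulationConfig,
    gene_meta: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> ExpressionCounts:
    """Negative-binomial counts from an additive log2-scale mean model.

    Per gene g and sample i the log2 mean is
    baseline_g + sum(eQTL effect x dosage) + slope_g x OI_std_i
    + sex_effect_g x sex_i + loading_g x factor_m(i),
    where OI_std is the OI standardized to unit variance over the profiled
    samples, module factors are unit-variance latent variables (equal to
    scaled OI for OI-driven modules), and counts are drawn NB with shared
    dispersion and per-sample library size.
    """
    if rng is None:
        rng = np.random.default_rng()
    sample_ids = samples.sample_ids
    n, g = len(sample_ids), config.n_genes
    gene_ids = list(gene_meta.index)
    gene_pos = {gid: k for k, gid in enumerate(gene_ids)}

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=g)
    log2_mu = np.tile(baseline[:, None], (1, n))

    dosage = genotypes.dosage.loc[sample_ids]
    for snp, gene, eff in truth.planted_cis + truth.planted_trans:
        d = np.nan_to_num(dosage[snp].to_numpy(dtype=float), nan=1.0)
        log2_mu[gene_pos[gene]] += eff * d

    oi = samples.oi.to_numpy()
    oi_sd = oi.std()
    oi_std = (oi - oi.mean()) / (oi_sd if oi_sd > 0 else 1.0)
    for gene, slope in truth.de_genes:
        log2_mu[gene_pos[gene]] += slope * oi_std

    sex = samples.sex_numeric.to_numpy()
    sex_eff = rng.normal(0.0, config.sex_effect_sd, size=g)
    log2_mu += sex_eff[:, None] * sex[None, :]

    module_ids = sorted(set(truth.module_labels.values()))
    for mod in module_ids:
        if mod in truth.oi_driven_modules:
            factor = oi_std
        else:
            factor = rng.normal(0.0, 1.0, size=n)
        members = [gid for gid, m in truth.module_labels.items() if m == mod]
        signs = rng.choice([1.0, -1.0], size=len(members))
        for gid, s in zip(members, signs):
            log2_mu[gene_pos[gid]] += s * config.module_cor * factor

    rel = np.exp2(log2_mu)
    base_total = float(np.exp2(baseline).sum())
    libsize = rng.uniform(*config.libsize_range, size=n)
    mu = rel * (libsize[None, :] / base_total)

    r = 1.0 / config.nb_dispersion  # NB size: var = mu + mu^2 / r
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    return ExpressionCounts(
        counts=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        gene_meta=gene_meta,
    )


def simulate_module_expression(
    module_sizes: list[int],
    n_noise: int,
    n_samples: int,
    within_cor: float = 0.7,
    factors: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Gaussian expression with exact planted within-module correlation.

    Each module gene is sqrt(within_cor) x factor + sqrt(1 - within_cor) x
    noise, so the expected gene-gene correlation inside a module equals
    ``within_cor``.  ``factors`` (modules x samples) may be supplied to
    drive a module with an external trait (e.g. the OI); otherwise unit
    Gaussian factors are drawn.  Returns values (genes x samples) and the
    true gene -> module labels (0 = noise).
    """
    if rng is None:
        rng = np.random.default_rng()
    if factors is None:
        factors = rng.normal(size=(len(module_sizes), n_samples))
    lam = np.sqrt(within_cor)
    rows, labels = [], {}
    k = 0
    for m, size in enumerate(module_sizes, start=1):
        f = factors[m - 1]
        f = (f - f.mean()) / f.std()
        for _ in range(size):
            k += 1
            gid = f"gene_{k:05d}"
            rows.append(lam * f + np.sqrt(1 - within_cor) * rng.normal(size=n_samples))
            labels[gid] = m
    for _ in range(n_noise):
        k += 1
        gid = f"gene_{k:05d}"
        rows.append(rng.normal(size=n_samples))
        labels[gid] = 0
    values = pd.DataFrame(
        np.asarray(rows),
        index=list(labels.keys()),
        columns=[f"S{j + 1:03d}" for j in range(n_samples)],
    )
    return values, labels


# ---------------------------------------------------------------------------
# PPI


def simulate_ppi(
    genes: list[str],
    module_labels: dict[str, int],
    p_within: float = 0.3,
    p_background: float = 0.01,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Undirected PPI edge list enriched within true modules.

    Each unordered gene pair receives an edge with probability
    ``p_within`` when both genes share a (nonzero) module and
    ``p_background`` otherwise; no self-loops or duplicates.
    """
    if not genes:
        raise ValueError("gene list is empty")
    if rng is None:
        rng = np.random.default_rng()
    genes = list(genes)
    n = len(genes)
    labels = np.array([module_labels.get(g, 0) for g in genes])
    edges_a, edges_b = [], []
    u = rng.random((n, n))
    same = (labels[:, None] == labels[None, :]) & (labels[:, None] != 0)
    prob = np.where(same, p_within, p_background)
    iu = np.triu_indices(n, k=1)
    hit = u[iu] < prob[iu]
    for i, j in zip(iu[0][hit], iu[1][hit]):
        edges_a.append(genes[i])
        edges_b.append(genes[j])
    return pd.DataFrame({"gene_a": edges_a, "gene_b": edges_b})


# ---------------------------------------------------------------------------
# whole-study orchestration


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate a full synthetic study from one seed: genotypes, OI,
    profiling-group selection, expression counts for the profiled samples,
    PPI edges, and the complete truth record."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genotypes, pedigree = simulate_f2_genotypes(config, rng)

    snp_ids = genotypes.snp_ids
    causal_idx = rng.choice(len(snp_ids), size=config.n_causal_oi_snps, replace=False)
    causal = [(snp_ids[i], float(rng.normal(0.0, 0.15))) for i in sorted(causal_idx)]
    oi = simulate_obesity_index(genotypes, causal, config.oi_heritability, rng)

    sex = np.where(rng.random(config.n_f2) < 0.5, "male", "female")
    if config.profile_group_size is not None:
        group = select_profiling_groups(oi, config.profile_group_size)
        profiled = list(group.index[group != "none"])
    else:
        group = pd.Series("none", index=oi.index)
        profiled = list(oi.index)
    full_table = pd.DataFrame(
        {"sex": sex, "oi": oi, "group": group},
        index=pd.Index(genotypes.sample_ids, name="sample_id"),
    )
    samples = SampleTable(full_table.loc[profiled].copy())

    # plant eQTLs: cis genes are placed next to their SNP, trans genes get
    # a SNP on another chromosome
    eqtl_snp_idx = rng.choice(
        len(snp_ids), size=config.n_cis_eqtl + config.n_trans_eqtl, replace=False
    )
    cis_snps = [snp_ids[i] for i in eqtl_snp_idx[: config.n_cis_eqtl]]
    trans_snps = [snp_ids[i] for i in eqtl_snp_idx[config.n_cis_eqtl:]]
    gene_meta = _place_genes(config, genotypes.snp_meta, cis_snps, rng)
    gene_ids = list(gene_meta.index)

    truth = TruthRecord()
    for j, snp in enumerate(cis_snps):
        if config.cis_effect_fixed is not None:
            eff = float(config.cis_effect_fixed * rng.choice([-1.0, 1.0]))
        else:
            eff = float(rng.normal(0.0, config.cis_effect_sd))
            eff = float(np.sign(eff) * max(abs(eff), 0.2 * config.cis_effect_sd))
        truth.planted_cis.append((snp, gene_ids[j], eff))
    # trans targets: genes on a different chromosome than their SNP
    free = [g for g in gene_ids[config.n_cis_eqtl:]]
    rng.shuffle(free)
    for snp in trans_snps:
        snp_chrom = genotypes.snp_meta.at[snp, "chrom"]
        target = next(
            (g for g in free if gene_meta.at[g, "chrom"] != snp_chrom), None
        )
        if target is None:
            continue
        free.remove(target)
        if config.trans_effect_fixed is not None:
            eff = float(config.trans_effect_fixed * rng.choice([-1.0, 1.0]))
        else:
            eff = float(rng.normal(0.0, config.trans_effect_sd))
            eff = float(np.sign(eff) * max(abs(eff), 0.2 * config.trans_effect_sd))
        truth.planted_trans.append((snp, target, eff))
    truth.oi_causal_snps = causal

    # DE genes: avoid the cis-eQTL genes so planted signals stay separable
    de_pool = [g for g in gene_ids[config.n_cis_eqtl:]]
    de_idx = rng.choice(len(de_pool), size=config.n_de_genes, replace=False)
    lo, hi = config.de_effect_range
    for i in sorted(de_idx):
        slope = float(rng.uniform(lo, hi) * rng.choice([-1.0, 1.0]))
        truth.de_genes.append((de_pool[i], slope))

    # modules among genes not already carrying planted cis/DE signal
    used = truth.cis_genes | truth.de_gene_ids
    pool = [g for g in gene_ids if g not in used]
    sizes = list(config.module_sizes[: config.n_modules])
    need = sum(sizes)
    if need > len(pool):
        raise ValueError("not enough signal-free genes for the requested modules")
    chosen = list(rng.choice(len(pool), size=need, replace=False))
    k = 0
    for m, size in enumerate(sizes, start=1):
        for _ in range(size):
            truth.module_labels[pool[chosen[k]]] = m
            k += 1
    truth.oi_driven_modules = set(range(1, min(config.n_oi_driven_modules, len(sizes)) + 1))

    counts = simulate_expression(genotypes, samples, truth, config, gene_meta, rng)
    ppi = simulate_ppi(gene_ids, truth.module_labels, rng=rng)
    return SimulatedStudy(
        genotypes=genotypes,
        counts=counts,
        samples=samples,
        ppi_edges=ppi,
        truth=truth,
        pedigree=pedigree,
    )
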