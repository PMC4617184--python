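# eqtlnet

Integrative systems genetics of obesity in an F2 pig intercross:
differential expression against a continuous **Obesity Index (OI)**,
**cis/trans eQTL mapping** with permutation-based FDR, supervised
**weighted gene co-expression network analysis**, and integration of
eQTLs, co-expression modules and protein–protein interactions (PPI).

## Who this is for

Quantitative geneticists and computational biologists analysing
expression data from experimental crosses — in particular designs where
two divergent founder lines are intercrossed, an aggregate genetic index
summarizes the phenotype of interest, and only phenotypic extremes plus a
mid-range group are expression-profiled (selective profiling, e.g. 12
lean / 12 intermediate / 12 obese animals out of 279 F2s). Because such
genotype data are rarely public, the package ships a first-class
synthetic-study generator with planted truth, so every stage can be
validated end to end by recovery of known signals.

## The models at the core

**Differential expression.** For gene *j* and animal *i*,

    y_ij = b0_j + beta_OI,j * OI_i + beta_sex,j * sex_i + e_ij

is fitted by (weighted) least squares on voom-style log2-CPM values.
Residual variances are shrunk toward a shared prior (d0, s0²) estimated
by matching the digamma/trigamma moments of log sample variances; the
moderated t statistic beta/(s̃_g √v_g) has d0 + d_g degrees of freedom.
Genes with Benjamini–Hochberg adjusted p below 0.05 are called DE;
positive beta_OI means up-regulated in obese animals.

**eQTL mapping.** SNPs pass QC at call rate > 0.95, MAF > 0.05 and exact
Hardy–Weinberg P > 1e-4 (all strict). Expression is quantile-normalized,
log2-transformed, gene-centered, z-scored per sample, and the leading
expression principal components are projected out (four by default;
components under genetic control are protected, see `docs/methods.md`).
Association is Spearman rank correlation between alternate-allele dosage
and expression; a pair is **cis** when SNP and transcription start site
are on the same chromosome less than 1 Mb apart, **trans** otherwise.
Significance comes from an empirical FDR: sample labels of the expression
matrix are permuted (10 times by default, preserving gene–gene
correlation), the identical mapping is re-run, and FDR(t) = mean permuted
discovery count / real discovery count, monotonized; records with
FDR < 0.05 are reported, plus the strongest effect per gene.

**Co-expression network.** On the union of DE and cis-eQTL genes the
adjacency is |Pearson r|^β with β the smallest power reaching scale-free
fit R² ≥ 0.90; the topological overlap measure (TOM) feeds average-linkage
clustering of 1 − TOM; clusters of ≥ 25 genes become modules. Each module
is summarized by its eigengene (first principal component); module–trait
relationships (MTR) with |r| > 0.5 and p < 0.05 select modules; gene
membership is filtered on kME (own-module > 0.6, cross-module < 0.6) and
hub genes are the most connected members (or any member with kME > 0.8
and |gene–trait r| > 0.6).

**Integration.** Per-module cis-eQTL content is tested with the
upper-tail hypergeometric distribution; a selected module's TOM edges are
merged with a PPI edge list into one graph analysed with betweenness
centrality and greedy modularity community clustering.

## Worked example

```python
from eqtlnet import SimulationConfig, RunConfig, simulate_study
from eqtlnet.pipeline import run_pipeline, evaluate_cis_recovery

cfg = SimulationConfig(
    n_f2=200, n_chrom=2, n_snps_per_chrom=500, n_genes=300,
    n_cis_eqtl=30, cis_effect_fixed=0.8, n_trans_eqtl=0,
    n_de_genes=30, n_modules=2, module_sizes=[40, 30],
    profile_group_size=None, seed=7,
)
study = simulate_study(cfg)
res = run_pipeline(study.genotypes, study.counts, study.samples,
                   study.ppi_edges, RunConfig(seed=7, eqtl_mode="cis"))
print(f"DE genes (BH FDR < 0.05):       {len(res.de_genes)}")
print(f"significant cis-eQTL records:   {res.cis_count}")
print(f"genes with a cis-eQTL:          {res.top_per_gene['gene_id'].nunique()}")
ev = evaluate_cis_recovery(res.significant_eqtls, study.truth)
print(f"recall of planted cis effects:  {ev['recall']:.2f}")
print(f"soft threshold beta:            {res.beta}")
print(f"modules detected:               {len(set(res.module_labels) - {0})}")
print(f"max |module-OI correlation|:    {res.mtr['oi'].abs().max():.2f}")
```

prints

```
DE genes (BH FDR < 0.05):       123
significant cis-eQTL records:   685
genes with a cis-eQTL:          72
recall of planted cis effects:  1.00
soft threshold beta:            8
modules detected:               1
max |module-OI correlation|:    0.96
```

All 30 planted cis effects (0.8 log2 units per allele) are recovered.
The 685 significant records collapse to 72 genes because F2 crosses carry
chromosome-scale linkage: many markers tag each signal. The 123 DE calls
include the 30 planted OI-slope genes plus members of the OI-driven
module, whose expression genuinely follows the OI. The detected module
tracks the OI with eigengene correlation 0.96.

The same stages are exposed on the command line over standard formats
(PLINK PED/MAP or VCF, TSV counts, BED annotation, TSV sample table):

```bash
eqtlnet simulate --out study/ --seed 7
eqtlnet eqtl --geno study/genotypes.ped --counts study/counts.tsv \
             --annot study/genes.bed --samples study/samples.tsv --out results/
eqtlnet run-all --seed 7 --out results/
```

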