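# Methods

This note documents the models, parameter choices and numerical decisions
behind `eqtlnet`, and what the synthetic-study validation does and does
not establish about real data.

## The synthetic F2 study

The generator (`eqtlnet.simulate`) emulates an intercross of two founder
breeds divergent for obesity, expression-profiled under selective
profiling.

**Genotypes.** Founders are inbred lines fixed for alternate alleles by
default (a polymorphic founder-frequency mode exists). F1 animals carry
one haplotype from each line; F2 gametes are produced by crossovers
placed as a Poisson process along the genetic map (default 1 cM/Mb), so
the recombination fraction between two markers d Morgans apart is the
Haldane value (1 − e^(−2d))/2 by construction. Family structure is
approximated by drawing each F2 from one of `n_f1_pairs` matings
(default 93, about three full sibs per family); it is not enforced
exactly. Missing genotypes can be injected at a configurable rate
(default 0).

**Obesity Index.** OI_i = Σ effect × dosage over `n_causal_oi_snps`
causal markers plus Gaussian noise scaled so var(genetic)/var(OI) equals
the configured heritability (default 0.5); the OI is centered. Units are
arbitrary: the expression model standardizes the OI internally, so
planted differential-expression slopes are in log2 units **per OI
standard deviation** (default range 0.5–1.5, random sign). Selective
profiling labels the `group_size` lowest-OI animals lean, the highest
obese and the `group_size` animals nearest the median intermediate
(default 12/12/12 out of 279); sex is Bernoulli(1/2) and selection does
not balance it.

**Expression.** Per gene and sample the log2 mean is baseline
(log-normal, default mean 8 sd 2 on the log2 scale) + cis/trans eQTL
effects × dosage + DE slope × standardized OI + sex effect + module
loading × latent factor; counts are negative-binomial with shared
dispersion (default 0.1) and a per-sample library size (default 0.8–1.2
million over ~1,000 genes, i.e. desk-scale depth). Module latent factors
are unit Gaussians except for OI-driven modules, whose factor is the
standardized OI. Planted cis genes are placed within ±0.5 Mb of their
SNP so every planted pair lies inside the 1-Mb cis window. cis/trans
effect sizes default to N(0, sd) draws (floored away from 0); a
fixed-magnitude mode (`cis_effect_fixed`) plants equal |effects|, used by
the recovery analyses (0.8 log2/allele). A separate Gaussian helper
(`simulate_module_expression`) plants modules with an exact
within-correlation for network-stage validation.

**PPI.** Unordered gene pairs receive an edge with probability 0.3 inside
a true module and 0.01 otherwise (no self-loops/duplicates).

**What the generator does not emulate:** read-level sequencing artefacts,
batch effects, gene-length bias, gene–gene regulatory cascades beyond the
single-factor modules, dominance/epistasis, and real genome coordinates.
Passing recovery tests therefore demonstrates the correctness and
calibration of the estimators under the stated generative model, not
performance on any particular real dataset.

## Preprocessing

Two stacks, reflecting two readings of the low-count rule:

* **DE stack** — filter genes whose counts are ≤ 5 in every sample
  (`total` mode); DESeq-style median-of-ratios size factors (genes with a
  zero anywhere excluded from the reference); voom-style values
  log2((count + 0.5)/(L_j + 1) × 1e6). The effective library size L_j is
  the size factor times the mean column sum, *not* the sample's own
  column sum times its factor: the median-of-ratios factor is robust to
  composition, and re-introducing the raw column total lets strongly
  OI-regulated, high-abundance genes bias every other gene's log-CPM
  toward the OI (measured as a ~0.35 correlation between log(colsum/sf)
  and the OI in simulations, inflating the DE false-discovery rate to
  0.26 in single seeds; with the factor-only library it is ~0.04).
  Precision weights come from a lowess trend of √(per-gene SD) against
  mean log2 count, evaluated at signal-independent fitted log counts
  (gene mean log2-CPM plus sample library offset) and raised to −4;
  evaluating the trend at each observation's own count would leak noise
  into the weights.
* **eQTL stack** — filter genes with any count < 5 (`any_sample` mode);
  quantile normalization (ties get the mean of the reference values at
  their tied ranks, so columns share one multiset up to ties); log2;
  per-gene centering; per-sample z-transform; removal of leading
  expression principal components.

**PC removal.** Four components are removed by default (the yield-
maximizing choice can be scanned with `scan_pc_removal`). At desk scale,
strong planted cis effects on few genes plus F2 linkage make the leading
expression components *genetically driven*, and removing them deletes
most cis signal (32/40 planted genes lost genome-significant association
in a measured example). The pipeline therefore protects genetically
controlled components by default: a component whose sample loadings
associate with any SNP at a Bonferroni-corrected Spearman p < 0.05 is
kept, and the first four non-genetic components are removed — the same
practice as the rank-based eQTL pipeline this stage follows. Plain top-k
removal remains available (`RunConfig.protect_genetic_pcs = False`) and
is the sensible choice when genotype-driven expression variance is a
negligible share of the total, as in full-transcriptome data.

Sex is handled inside the DE design (not regressed out beforehand); the
WGCNA/eQTL paths work on matrices without explicit sex regression since
the per-sample z-transform and PC removal absorb global sex shifts. A
`regress_out_covariate` step exists and can be inserted via
`RunConfig.de_sex_regression` if the regress-first variant is wanted.

## Differential expression

The design is [intercept, OI, sex(0/1, female = 0)] — an intercept is
included although the headline model is often written without one, since
a slope on non-centered expression is meaningless otherwise. The shared
variance prior (d0, s0²) is estimated in closed form from
e_g = log s_g² − ψ(d_g/2) + log(d_g/2): var(e) − mean ψ′(d_g/2) is
inverted through the trigamma function for d0 (Newton iteration;
non-positive excess dispersion ⇒ d0 = ∞, complete shrinkage with a
warning), and s0² = exp(mean(e) + ψ(d0/2) − log(d0/2)). Sample variances
are floored at 1e-12. The moderated t uses d0 + d_g df (normal when d0 is
infinite). The B statistic (log posterior odds, prior DE proportion 0.01,
slope-variance inflation estimated by quantile matching on the most
extreme t values) is reported but never used for calling. The
implementation is cross-checked in the test suite against R limma's
`lmFit`/`eBayes` on a fixture (t, p, d0 and s0² agree to ≤ 1e-4 relative)
and against hand-rolled normal equations.

## eQTL mapping

Spearman rank correlation with average ranks for ties; p from
t = ρ√((n−2)/(1−ρ²)) on n − 2 df. Tests are vectorized as matrix products
of row-standardized ranks; SNPs with missing calls fall back to per-pair
pairwise-complete tests (never imputed), with `n_used` recorded.
QC thresholds are strict: a SNP exactly at call rate 0.95, MAF 0.05 or
HWE p 1e-4 is removed. The HWE test is the exact conditional test
(recurrence over heterozygote counts of fixed parity), verified against
full enumeration for every genotype configuration up to n = 50.

cis assignment uses the TSS (BED intervals are converted to a 1-based TSS
on read: start+1 on '+', end on '−'); a pair at exactly 1 Mb is trans.
Permutations shuffle the expression sample labels once per permutation
globally, preserving the gene–gene correlation that makes pooled
empirical FDR valid. FDR(t) is the mean permuted discovery count over the
real count; reported q-values take the minimum estimate over thresholds
at or above the record's own p (the raw pointwise estimator is exposed as
`estimate_fdr_at` for calibration work, since the monotonized q-value is
downward-biased under a global null). FDR is estimated separately for cis
and trans scopes by default because their test counts differ by orders of
magnitude; a joint mode exists.

**Scoring recovery on synthetic data** (`evaluate_cis_recovery`): recall
is gene-level (a planted gene is recovered when any significant record
targets it) and empirical FDR is record-level with gene-based truth —
markers in linkage with a planted SNP tag the same signal and are not
counted as false. This scoring is only meaningful in designs whose only
genetic expression signal is the planted cis effects; when OI-responsive
genes are also planted, SNPs linked to OI-causal loci acquire *genuine*
OI-mediated associations that a planted-cis truth table would miscount as
false.

## Co-expression network

Unsigned adjacency |r|^β (signed option available). The scale-free fit is
the squared correlation of log10 p(k) vs log10(mean k) over 10
equal-width connectivity bins, negated when the slope is positive, and
set to 0 when fewer than 8 bins are occupied — an excessive power
collapses the connectivity distribution into few bins and would otherwise
fake a perfect fit. β is the smallest power with R² ≥ 0.90; when no power
qualifies (common for planted-module data, which is not scale-free), the
fallback is the best-fitting β among those with mean connectivity ≥ 1,
because the unrestricted argmax monotonically drifts to the largest
candidate power as the network degenerates (measured: argmax 20 with
module recovery ARI ≈ 0, versus fallback 6–10 with ARI ≈ 0.99).

TOM_ij = (L_ij + a_ij)/(min(k_i, k_j) + 1 − a_ij); modules come from
average-linkage clustering of 1 − TOM with a deterministic static cut at
0.99 × the maximum merge height and minimum size 25 — a reproducible
stand-in for the adaptive dynamic tree cut, whose full algorithm is
deliberately not replicated. Labels are assigned by decreasing module
size; sub-threshold clusters are unassigned (label 0).

Eigengenes are the first right singular vector of the standardized module
matrix, unit-variance, sign-oriented so the mean correlation with module
genes is non-negative; constant genes are dropped from the PCA with a
log message. MTR selection needs |r| > 0.5 *and* p < 0.05 (the
significance level attached to the published 0.5 rule is not stated;
0.05 is assumed and configurable). The gene-retention rule is implemented
as own-module kME > 0.6 and cross-module |kME| < 0.6; the literal
published phrasing ("with other modules > 0.6") is almost certainly a
typo but is available behind `literal_other_rule=True`. Hub genes:
highest intramodular connectivity (lexicographic tie-break), plus a
hub-eligible list by the kME > 0.8 and |gene–trait r| > 0.6 rule (strict
inequalities).

## Integration

Module–eQTL content uses the upper-tail hypergeometric test
P(X ≥ overlap) with the analysed gene set as the universe. Co-expression
edges with TOM ≥ 0.1 (configurable; no published cutoff exists) are
merged with the PPI edge list; proteins mapping to module genes fuse into
the gene node, many-to-many mappings keep the first entry and log the
conflict. The merged graph is treated as undirected and unweighted for
betweenness centrality (normalized by (n−1)(n−2)/2) and for community
detection by greedy modularity maximization — a deterministic substitute
for GUI-based community clustering tools, validated on small graphs
against exhaustive modularity search over all partitions.

## Problem sizes used in validation

The recovery analyses run at desk scale, chosen to finish in minutes on
one CPU while keeping each statistical question well-posed: eQTL recovery
uses 200 F2 animals, 2,000 SNPs on 2 chromosomes, 300 genes and 40 planted
cis effects of 0.8 log2/allele over 10 seeds (null calibration: the same
design with nothing planted, 20 seeds); DE recovery uses the full
selective-profiling design (279 animals, 36 profiled) with 100 planted
slopes among 1,000 genes over 20 seeds; module recovery uses 3 modules of
60/50/40 genes at within-correlation 0.7 plus 150 noise genes under 36
samples over 20 seeds; prior recovery uses 2,000 genes from a scaled
inverse-chi-square(4, 0.05) prior with 10 residual df over 50 replicates.

## Known limitations

* The static-cut module detection under-segments when module
  similarities are very unequal; the cut quantile is exposed but the
  adaptive branch-based cut is not implemented.
* The permutation FDR is test-level; the per-gene best-association mode
  common in cis-only pipelines is available (`scope`/gene-level modes)
  but the default follows the pooled estimator.
* All-pairs trans mapping is quadratic in SNPs × genes; at chip ×
  transcriptome scale the intended usage is the restricted universes
  (DE genes, index-associated SNPs) the pipeline exposes as subsets.
* The B-statistic's slope-variance inflation uses a simplified quantile
  matching; it tracks limma closely on fixtures but is reported only.
* Betweenness and communities ignore edge weights by design; weights are
  kept as attributes for downstream use.
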