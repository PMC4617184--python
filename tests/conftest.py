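import numpy as np
import pandas as pd
import pytest

from eqtlnet.datatypes import ExpressionCounts, GenotypeMatrix, SampleTable
from eqtlnet.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    return SimulationConfig(
        n_f2=80,
        n_chrom=2,
        n_snps_per_chrom=60,
        n_genes=150,
        n_causal_oi_snps=10,
        n_cis_eqtl=12,
        n_trans_eqtl=3,
        n_de_genes=15,
        n_modules=2,
        module_sizes=[30, 25],
        profile_group_size=12,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    return simulate_study(tiny_config)


@pytest.fixture
def small_genotypes() -> GenotypeMatrix:
    rng = np.random.default_rng(5)
    n, m = 40, 8
    dosage = rng.integers(0, 3, size=(n, m)).astype(float)
    snp_ids = [f"s{j}" for j in range(m)]
    meta = pd.DataFrame(
        {
            "chrom": ["chr1"] * (m // 2) + ["chr2"] * (m - m // 2),
            "pos_bp": np.arange(1, m + 1) * 10_000,
            "allele_ref": ["A"] * m,
            "allele_alt": ["G"] * m,
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    return GenotypeMatrix(
        dosage=pd.DataFrame(dosage, index=[f"i{i}" for i in range(n)], columns=snp_ids),
        snp_meta=meta,
    )


@pytest.fixture
def small_counts() -> ExpressionCounts:
    rng = np.random.default_rng(7)
    genes, samples = 30, 12
    counts = rng.negative_binomial(10, 0.05, size=(genes, samples)) + 6
    gene_ids = [f"g{k}" for k in range(genes)]
    meta = pd.DataFrame(
        {
            "chrom": ["chr1"] * genes,
            "tss_bp": np.arange(1, genes + 1) * 50_000,
            "strand": ["+"] * genes,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return ExpressionCounts(
        counts=pd.DataFrame(
            counts, index=gene_ids, columns=[f"i{i}" for i in range(samples)]
        ),
        gene_meta=meta,
    )


@pytest.fixture
def small_samples(small_counts) -> SampleTable:
    rng = np.random.default_rng(9)
    ids = small_counts.sample_ids
    tab = pd.DataFrame(
        {
            "sex": rng.choice(["male", "female"], size=len(ids)),
            "oi": rng.normal(size=len(ids)),
            "group": ["none"] * len(ids),
        },
        index=pd.Index(ids, name="sample_id"),
    )
    return SampleTable(tab)
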