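"""Core in-memory containers shared across the pipeline stages.

All matrices are stored as pandas DataFrames so that sample/gene/SNP
identifiers travel with the numbers.  Conventions fixed here:

* genotype dosage = count of the alternate allele, in {0, 1, 2}; missing
  genotypes are NaN;
* all genomic positions are 1-based (BED input is converted on read);
* expression count matrices are genes x samples; genotype matrices are
  samples x SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "ExpressionCounts",
    "SampleTable",
    "ProcessedExpression",
]

SNP_META_COLUMNS = ["chrom", "pos_bp", "allele_ref", "allele_alt"]
GENE_META_COLUMNS = ["chrom", "tss_bp", "strand"]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs alternate-allele dosage matrix with SNP metadata.

    ``dosage`` is a float DataFrame (index = sample ids, columns = SNP ids)
    holding values in {0, 1, 2} with NaN for missing calls.  ``snp_meta``
    is indexed by SNP id with columns chrom, pos_bp (1-based), allele_ref,
    allele_alt.
    """

    dosage: pd.DataFrame
    snp_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.dosage.columns) != list(self.snp_meta.index):
            raise ValueError("snp_meta index must match dosage columns")
        missing = [c for c in SNP_META_COLUMNS if c not in self.snp_meta.columns]
        if missing:
            raise ValueError(f"snp_meta missing columns: {missing}")
        vals = self.dosage.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosage values must be 0/1/2 or missing (NaN)")
        if (self.snp_meta["pos_bp"] <= 0).any():
            raise ValueError("SNP positions must be positive (1-based)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosage.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosage.columns)

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosage=self.dosage.loc[:, snp_ids],
            snp_meta=self.snp_meta.loc[snp_ids],
        )

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosage=self.dosage.loc[sample_ids], snp_meta=self.snp_meta
        )


@dataclass
class ExpressionCounts:
    """Genes x samples raw count matrix plus gene coordinates.

    ``counts`` is an integer DataFrame (index = gene ids, columns = sample
    ids).  ``gene_meta`` is indexed by gene id with columns chrom, tss_bp
    (1-based), strand; genes lacking annotation carry NaN there and are
    excluded from cis/trans classification downstream.
    """

    counts: pd.DataFrame
    gene_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups)[:5]}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        # align meta to the count matrix, NaN rows for unannotated genes
        self.gene_meta = self.gene_meta.reindex(self.counts.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def unannotated_genes(self) -> list[str]:
        mask = self.gene_meta["chrom"].isna() | self.gene_meta["tss_bp"].isna()
        return list(self.gene_meta.index[mask])

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionCounts":
        return ExpressionCounts(
            counts=self.counts.loc[gene_ids], gene_meta=self.gene_meta.loc[gene_ids]
        )

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionCounts":
        return ExpressionCounts(
            counts=self.counts.loc[:, sample_ids], gene_meta=self.gene_meta
        )


@dataclass
class SampleTable:
    """Per-sample covariates: sex, the continuous Obesity Index (OI),
    optional obesity phenotypes, and the profiling group label.

    ``table`` is indexed by sample id with at least columns ``sex``
    ({"male", "female"}), ``oi`` (finite float) and ``group``
    ({"lean", "intermediate", "obese", "none"}); any further numeric
    columns are treated as phenotypes.
    """

    table: pd.DataFrame

    REQUIRED = ("sex", "oi", "group")

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("sample ids must be unique")
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"sample table missing column {col!r}")
        if not np.isfinite(self.table["oi"].to_numpy(dtype=float)).all():
            raise ValueError("OI must be finite")
        bad_sex = set(self.table["sex"]) - {"male", "female"}
        if bad_sex:
            raise ValueError(f"unknown sex labels: {bad_sex}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def oi(self) -> pd.Series:
        return self.table["oi"].astype(float)

    @property
    def sex_numeric(self) -> pd.Series:
        """Sex coded 0/1 with female = 0 (affects the sex coefficient only)."""
        return (self.table["sex"] == "male").astype(float)

    @property
    def phenotype_columns(self) -> list[str]:
        skip = set(self.REQUIRED)
        return [
            c
            for c in self.table.columns
            if c not in skip and pd.api.types.is_numeric_dtype(self.table[c])
        ]

    def subset(self, sample_ids: list[str]) -> "SampleTable":
        return SampleTable(self.table.loc[sample_ids].copy())


@dataclass
class ProcessedExpression:
    """Continuous genes x samples expression after a normalization stack.

    ``weights``, when present, are positive per-observation precision
    weights of the same shape as ``values``.  ``provenance`` records the
    ordered list of transforms applied; ``removed_pcs`` how many sample
    space principal components were projected out.
    """

    values: pd.DataFrame
    weights: pd.DataFrame | None = None
    provenance: list[str] = field(default_factory=list)
    removed_pcs: int = 0
    gene_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("processed expression must be finite")
        if self.weights is not None:
            if self.weights.shape != self.values.shape:
                raise ValueError("weights shape must match values")
            if (self.weights.to_numpy() <= 0).any():
                raise ValueError("weights must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def evolve(
        self,
        values: pd.DataFrame,
        step: str,
        weights: pd.DataFrame | None = None,
        removed_pcs: int | None = None,
    ) -> "ProcessedExpression":
        """Return a copy with new values and the provenance extended."""
        return ProcessedExpression(
            values=values,
            weights=self.weights if weights is None else weights,
            provenance=[*self.provenance, step],
            removed_pcs=self.removed_pcs if removed_pcs is None else removed_pcs,
            gene_meta=self.gene_meta,
        )
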