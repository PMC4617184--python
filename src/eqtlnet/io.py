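"""Readers and writers for the standard formats the pipeline touches.

Genotypes: PLINK PED/MAP and VCF v4.2 (dosage = alternate-allele count,
missing preserved).  Expression: TSV count matrix plus BED-like gene
annotation (0-based half-open intervals converted to a 1-based TSS on
read; TSS = start for '+', end for '-').  Sample table, PPI edge list and
truth files are plain TSV.  Result writers emit TSVs with a stable column
and row order (byte-identical on rerun) and GraphML for graphs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import ExpressionCounts, GenotypeMatrix, SampleTable
from .simulate import SimulatedStudy, TruthRecord

__all__ = [
    "read_genotypes",
    "read_ped_map",
    "read_vcf",
    "write_ped_map",
    "write_vcf",
    "read_counts_and_annotation",
    "write_counts",
    "write_annotation_bed",
    "read_sample_table",
    "write_sample_table",
    "read_ppi",
    "write_results",
    "write_graphml",
    "write_study",
    "read_study",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path, fmt: str | None = None) -> GenotypeMatrix:
    """Dispatch on format: 'pedmap' (pass the .ped path or the shared
    prefix) or 'vcf'.  Guessed from the suffix when ``fmt`` is None."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in (".vcf", ".gz") else "pedmap"
    if fmt == "pedmap":
        prefix = path.with_suffix("") if path.suffix in (".ped", ".map") else path
        return read_ped_map(prefix.with_suffix(".ped"), prefix.with_suffix(".map"))
    if fmt == "vcf":
        return read_vcf(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Read PLINK text PED/MAP.  MAP columns: chrom, snp id, cM, bp
    position (column 4), optionally alt and ref alleles (bim-style columns
    5-6, as written by :func:`write_ped_map`).  PED: FID IID PAT MAT SEX
    PHENO then two alleles per SNP; '0 0' is missing.  Dosage counts the
    alternate allele; without allele columns the minor allele is taken as
    alternate (lexicographic tie-break).  An allele matching neither of a
    SNP's two alleles is a parse error."""
    map_rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise ValueError(f"{map_path}: malformed MAP line {ln}")
            alleles = (parts[4], parts[5]) if len(parts) >= 6 else None
            map_rows.append((parts[0], parts[1], int(parts[3]), alleles))
    snp_ids = [r[1] for r in map_rows]
    n_snps = len(snp_ids)

    sample_ids = []
    geno_pairs = []  # list of (a1, a2) tuples per sample
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise ValueError(
                    f"{ped_path}: line {ln} has {len(parts)} fields, expected "
                    f"{6 + 2 * n_snps}"
                )
            sample_ids.append(parts[1])
            alleles = parts[6:]
            geno_pairs.append(
                [(alleles[2 * j], alleles[2 * j + 1]) for j in range(n_snps)]
            )

    dosage = np.full((len(sample_ids), n_snps), np.nan)
    allele_alt = [""] * n_snps
    allele_ref = [""] * n_snps
    for j in range(n_snps):
        if map_rows[j][3] is not None:
            alt, ref = map_rows[j][3]
        else:
            counts: dict[str, int] = {}
            for i in range(len(sample_ids)):
                for a in geno_pairs[i][j]:
                    if a != "0":
                        counts[a] = counts.get(a, 0) + 1
            seen = sorted(counts, key=lambda a: (counts[a], a))
            if len(seen) > 2:
                raise ValueError(
                    f"{ped_path}: SNP {snp_ids[j]} has >2 alleles: {seen}"
                )
            alt = seen[0] if seen else "A"
            ref = seen[-1] if len(seen) > 1 else ("B" if alt != "B" else "A")
        allele_alt[j], allele_ref[j] = alt, ref
        for i in range(len(sample_ids)):
            a1, a2 = geno_pairs[i][j]
            if a1 == "0" or a2 == "0":
                continue
            for a in (a1, a2):
                if a not in (ref, alt):
                    raise ValueError(
                        f"{ped_path}: sample {sample_ids[i]} SNP {snp_ids[j]}: "
                        f"allele {a!r} matches neither of {ref}/{alt}"
                    )
            dosage[i, j] = (a1 == alt) + (a2 == alt)

    snp_meta = pd.DataFrame(
        {
            "chrom": [r[0] for r in map_rows],
            "pos_bp": [r[2] for r in map_rows],
            "allele_ref": allele_ref,
            "allele_alt": allele_alt,
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    return GenotypeMatrix(
        dosage=pd.DataFrame(dosage, index=sample_ids, columns=snp_ids),
        snp_meta=snp_meta,
    )


def write_ped_map(geno: GenotypeMatrix, prefix) -> tuple[Path, Path]:
    """Write PLINK text PED/MAP; the MAP carries bim-style allele columns
    (alt, ref) so dosage orientation round-trips; missing becomes '0 0'."""
    prefix = Path(prefix)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    meta = geno.snp_meta
    with open(map_path, "w") as fh:
        for snp in geno.snp_ids:
            chrom = str(meta.at[snp, "chrom"])  # kept verbatim for consistency
            fh.write(
                f"{chrom}\t{snp}\t0\t{int(meta.at[snp, 'pos_bp'])}\t"
                f"{meta.at[snp, 'allele_alt']}\t{meta.at[snp, 'allele_ref']}\n"
            )
    dosage = geno.dosage.to_numpy(dtype=float)
    refs = meta["allele_ref"].to_numpy()
    alts = meta["allele_alt"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(geno.sample_ids):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for j in range(geno.n_snps):
                d = dosage[i, j]
                if np.isnan(d):
                    fields += ["0", "0"]
                else:
                    n_alt = int(d)
                    fields += [alts[j]] * n_alt + [refs[j]] * (2 - n_alt)
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


def write_vcf(geno: GenotypeMatrix, path) -> Path:
    """Write a minimal VCF v4.2 with GT fields."""
    path = Path(path)
    meta = geno.snp_meta
    dosage = geno.dosage.to_numpy(dtype=float)
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(meta["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.sample_ids)
            + "\n"
        )
        order = np.lexsort(
            (meta["pos_bp"].to_numpy(), meta["chrom"].astype(str).to_numpy())
        )
        for j in order:
            snp = geno.snp_ids[j]
            gts = [
                "./." if np.isnan(dosage[i, j]) else gt_of[int(dosage[i, j])]
                for i in range(geno.n_samples)
            ]
            fh.write(
                f"{meta.at[snp, 'chrom']}\t{int(meta.at[snp, 'pos_bp'])}\t{snp}\t"
                f"{meta.at[snp, 'allele_ref']}\t{meta.at[snp, 'allele_alt']}\t.\t"
                "PASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )
    return path


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into a dosage matrix via cyvcf2; non-biallelic records
    are skipped with a warning."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    snp_ids, chroms, positions, refs, alts = [], [], [], [], []
    rows = []
    for var in vcf:
        if len(var.ALT) != 1:
            log.warning("skipping non-biallelic record %s:%d", var.CHROM, var.POS)
            continue
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = np.asarray(var.gt_types, dtype=float)
        dos = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        rows.append(dos)
        snp_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        positions.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
    dosage = np.array(rows).T if rows else np.empty((len(sample_ids), 0))
    snp_meta = pd.DataFrame(
        {"chrom": chroms, "pos_bp": positions, "allele_ref": refs, "allele_alt": alts},
        index=pd.Index(snp_ids, name="snp_id"),
    )
    return GenotypeMatrix(
        dosage=pd.DataFrame(dosage, index=sample_ids, columns=snp_ids),
        snp_meta=snp_meta,
    )


# ---------------------------------------------------------------------------
# expression counts + annotation


def read_counts_and_annotation(counts_path, annot_path=None) -> ExpressionCounts:
    """Read a genes x samples TSV count matrix and BED-like annotation.

    The BED file is 0-based half-open (chrom, start, end, gene id, score,
    strand); the TSS is start+1 on '+' and end on '-'.  Genes present in
    the counts but absent from the annotation are retained un-annotated
    (excluded from cis/trans classification downstream)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if counts.index.has_duplicates:
        dups = counts.index[counts.index.duplicated()].unique()
        raise ValueError(f"duplicate gene ids in counts: {list(dups)[:5]}")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("counts matrix must be numeric")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be integers")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    counts = counts.astype(np.int64)

    if annot_path is None:
        gene_meta = pd.DataFrame(
            index=counts.index, columns=["chrom", "tss_bp", "strand"]
        )
    else:
        bed = pd.read_csv(annot_path, sep="\t", header=None, comment="#")
        if bed.shape[1] < 4:
            raise ValueError("annotation needs >= 4 BED columns")
        bed.columns = ["chrom", "start", "end", "gene_id", "score", "strand"][
            : bed.shape[1]
        ]
        if "strand" not in bed.columns:
            bed["strand"] = "+"
        tss = np.where(bed["strand"] == "-", bed["end"], bed["start"] + 1)
        gene_meta = pd.DataFrame(
            {"chrom": bed["chrom"].to_numpy(), "tss_bp": tss, "strand": bed["strand"].to_numpy()},
            index=pd.Index(bed["gene_id"], name="gene_id"),
        )
        missing = set(counts.index) - set(gene_meta.index)
        if missing:
            log.warning("%d genes lack annotation; flagged un-annotatable", len(missing))
    ec = ExpressionCounts(counts=counts, gene_meta=gene_meta)
    return ec


def write_counts(counts: ExpressionCounts, path) -> Path:
    path = Path(path)
    counts.counts.to_csv(path, sep="\t", index_label="gene_id")
    return path


def write_annotation_bed(counts: ExpressionCounts, path) -> Path:
    """Write gene annotation as BED6 (0-based half-open, 1-bp TSS feature
    placed so that reading it back recovers the same TSS)."""
    path = Path(path)
    with open(path, "w") as fh:
        for gid, row in counts.gene_meta.iterrows():
            if pd.isna(row["chrom"]) or pd.isna(row["tss_bp"]):
                continue
            tss = int(row["tss_bp"])
            strand = row["strand"] if pd.notna(row["strand"]) else "+"
            start, end = (tss - 1, tss)  # 1-bp interval works for both strands
            fh.write(f"{row['chrom']}\t{start}\t{end}\t{gid}\t0\t{strand}\n")
    return path


# ---------------------------------------------------------------------------
# samples, PPI, truth


def read_sample_table(path) -> SampleTable:
    tab = pd.read_csv(path, sep="\t", index_col=0)
    return SampleTable(tab)


def write_sample_table(samples: SampleTable, path) -> Path:
    path = Path(path)
    samples.table.to_csv(path, sep="\t", index_label="sample_id")
    return path


def read_ppi(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("PPI edge list needs two columns")
    return df


# ---------------------------------------------------------------------------
# results


def write_results(tables: dict[str, pd.DataFrame], out_dir) -> dict[str, Path]:
    """Write result tables as TSVs with a stable column and row order.

    Tables carrying 'p'-like columns are sorted by p then identifiers so a
    rerun on identical input is byte-identical."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in tables.items():
        df = df.copy()
        sort_cols = [
            c for c in ("p", "p_value", "p_adj", "p_hypergeom") if c in df.columns
        ]
        id_cols = [c for c in ("gene_id", "snp_id", "module") if c in df.columns]
        if sort_cols:
            df = df.sort_values(sort_cols[:1] + id_cols, kind="mergesort")
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.8g")
        written[name] = path
    return written


def write_graphml(graph: nx.Graph, path) -> Path:
    path = Path(path)
    nx.write_graphml(graph, path)
    return path


def _truth_frame(truth: TruthRecord) -> pd.DataFrame:
    rows = []
    for snp, gene, eff in truth.planted_cis:
        rows.append({"kind": "cis", "snp_id": snp, "gene_id": gene, "value": eff})
    for snp, gene, eff in truth.planted_trans:
        rows.append({"kind": "trans", "snp_id": snp, "gene_id": gene, "value": eff})
    for snp, eff in truth.oi_causal_snps:
        rows.append({"kind": "oi_causal", "snp_id": snp, "gene_id": "", "value": eff})
    for gene, slope in truth.de_genes:
        rows.append({"kind": "de", "snp_id": "", "gene_id": gene, "value": slope})
    for gene, mod in truth.module_labels.items():
        rows.append({"kind": "module", "snp_id": "", "gene_id": gene, "value": mod})
    for mod in sorted(truth.oi_driven_modules):
        rows.append({"kind": "oi_module", "snp_id": "", "gene_id": "", "value": mod})
    return pd.DataFrame(rows, columns=["kind", "snp_id", "gene_id", "value"])


def write_study(study: SimulatedStudy, out_dir, vcf: bool = False) -> dict[str, Path]:
    """Write a simulated study in the exact formats the pipeline reads."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    ped, mp = write_ped_map(study.genotypes, out_dir / "genotypes")
    paths["ped"], paths["map"] = ped, mp
    if vcf:
        paths["vcf"] = write_vcf(study.genotypes, out_dir / "genotypes.vcf")
    paths["counts"] = write_counts(study.counts, out_dir / "counts.tsv")
    paths["annotation"] = write_annotation_bed(study.counts, out_dir / "genes.bed")
    paths["samples"] = write_sample_table(study.samples, out_dir / "samples.tsv")
    study.ppi_edges.to_csv(out_dir / "ppi.tsv", sep="\t", index=False)
    paths["ppi"] = out_dir / "ppi.tsv"
    _truth_frame(study.truth).to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    paths["truth"] = out_dir / "truth.tsv"
    return paths


def read_study(out_dir) -> tuple[GenotypeMatrix, ExpressionCounts, SampleTable, pd.DataFrame]:
    """Read back the study files written by :func:`write_study` (the truth
    file is for tests; it is not consumed by the analysis stages)."""
    out_dir = Path(out_dir)
    geno = read_ped_map(out_dir / "genotypes.ped", out_dir / "genotypes.map")
    counts = read_counts_and_annotation(out_dir / "counts.tsv", out_dir / "genes.bed")
    samples = read_sample_table(out_dir / "samples.tsv")
    ppi = read_ppi(out_dir / "ppi.tsv")
    return geno, counts, samples, ppi
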