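"""eQTL stage: exact Hardy-Weinberg test, SNP QC boundaries, cis/trans
classification, rank association, pair enumeration, permutation FDR and
summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

from eqtlnet.datatypes import GenotypeMatrix, ProcessedExpression
from eqtlnet.eqtl import (
    classify_pair,
    hwe_exact_test,
    map_eqtls,
    permutation_fdr,
    rank_association,
    snp_qc,
    summarize_eqtls,
    top_eqtl_per_gene,
)


def hwe_enumeration_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Direct enumeration of the conditional heterozygote distribution
    using log-factorial probabilities."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    n_rare = min(n_a, n_b)
    if n_rare == 0:
        return 1.0

    def log_prob(het):
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        return (
            gammaln(n + 1)
            - gammaln(hom_r + 1)
            - gammaln(het + 1)
            - gammaln(hom_c + 1)
            + het * np.log(2)
            + gammaln(n_a + 1)
            + gammaln(n_b + 1)
            - gammaln(2 * n + 1)
        )

    hets = range(n_rare % 2, n_rare + 1, 2)
    logs = {h: log_prob(h) for h in hets if (n_rare - h) // 2 + h <= n}
    mx = max(logs.values())
    probs = {h: np.exp(v - mx) for h, v in logs.items()}
    total = sum(probs.values())
    obs = probs[n_ab] / total
    return min(sum(v for v in probs.values() if v / total <= obs * (1 + 1e-12)) / total, 1.0)


class TestHweExactTest:
    def test_monomorphic_returns_one(self):
        assert hwe_exact_test(10, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 7) == 1.0

    @pytest.mark.parametrize(
        "counts", [(3, 5, 2), (10, 1, 10), (0, 10, 0), (7, 2, 1), (4, 4, 4)]
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), abs=1e-12
        )

    def test_extreme_het_deficit_fails_threshold(self):
        assert hwe_exact_test(25, 0, 25) < 1e-4

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


def _geno(dosage_cols: dict[str, list], positions=None, chrom="chr1"):
    snps = list(dosage_cols)
    n = len(next(iter(dosage_cols.values())))
    meta = pd.DataFrame(
        {
            "chrom": chrom,
            "pos_bp": positions or np.arange(1, len(snps) + 1) * 1000,
            "allele_ref": "A",
            "allele_alt": "G",
        },
        index=pd.Index(snps, name="snp_id"),
    )
    return GenotypeMatrix(
        dosage=pd.DataFrame(
            {k: [float(x) if x is not None else np.nan for x in v] for k, v in dosage_cols.items()},
            index=[f"s{i}" for i in range(n)],
        ),
        snp_meta=meta,
    )


class TestSnpQc:
    def test_boundary_values_are_removed(self):
        n = 100
        rng = np.random.default_rng(0)
        good = list(rng.choice([0, 1, 2], size=n, p=[0.25, 0.5, 0.25]))
        # call rate exactly 0.95
        cr_bound = good.copy()
        for i in range(5):
            cr_bound[i] = None
        # MAF exactly 0.05: 10 alt alleles in 200 -> 10 hets
        maf_bound = [1] * 10 + [0] * 90
        geno = _geno({"ok": good, "cr": cr_bound, "maf": maf_bound})
        kept, reports = snp_qc(geno)
        by_id = {r.snp_id: r for r in reports}
        assert by_id["cr"].call_rate == pytest.approx(0.95)
        assert not by_id["cr"].passed and "call_rate" in by_id["cr"].reasons
        assert by_id["maf"].maf == pytest.approx(0.05)
        assert not by_id["maf"].passed and "maf" in by_id["maf"].reasons
        assert "ok" in kept.snp_ids

    def test_hwe_violation_removed(self):
        bad = [0] * 25 + [2] * 25  # no hets at 50/50 alleles
        ok = [0, 1, 1, 2] * 12 + [1, 0]
        geno = _geno({"bad": bad, "ok": ok})
        kept, reports = snp_qc(geno)
        by_id = {r.snp_id: r for r in reports}
        assert "hwe" in by_id["bad"].reasons
        assert "bad" not in kept.snp_ids

    def test_all_fail_raises(self):
        geno = _geno({"m": [0] * 20})
        with pytest.raises(ValueError):
            snp_qc(geno)


class TestClassifyPair:
    @pytest.mark.parametrize(
        "snp_pos, tss, expected",
        [
            (1_900_000, 1_000_000, "cis"),  # 900 kb
            (2_000_000, 1_000_000, "trans"),  # exactly 1 Mb
            (1_000_001, 2_000_000, "cis"),  # 999,999 bp
        ],
    )
    def test_same_chromosome_window(self, snp_pos, tss, expected):
        kind, dist = classify_pair("chr1", snp_pos, "chr1", tss)
        assert kind == expected
        assert dist == snp_pos - tss

    def test_cross_chromosome_is_trans(self):
        kind, dist = classify_pair("chr1", 5, "chr2", 5)
        assert kind == "trans" and np.isnan(dist)

    def test_nonpositive_position_rejected(self):
        with pytest.raises(ValueError):
            classify_pair("chr1", 0, "chr1", 10)


class TestRankAssociation:
    def test_matches_tie_corrected_spearman(self):
        d = [0, 1, 2, 2, 1, 0, 1]
        e = [1.0, 2.0, 3.0, 4.0, 2.5, 0.5, 1.5]
        rho, p, n = rank_association(d, e)
        ref = stats.spearmanr(d, e)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert n == 7 and rho > 0

    def test_perfect_antimonotone(self):
        rho, p, _ = rank_association([0, 1, 2, 0, 1, 2], [6, 5, 1, 6.5, 4, 2])
        assert rho == pytest.approx(-1.0) or rho < -0.9

    def test_constant_dosage_skipped(self):
        with pytest.raises(ValueError):
            rank_association([1, 1, 1, 1], [1.0, 2.0, 3.0, 4.0])

    def test_missing_dropped_pairwise(self):
        rho, p, n = rank_association(
            [0, 1, 2, None, 1], [1.0, 2.0, 3.0, 99.0, 1.5]
        )
        assert n == 4


def _expr_from(mat, gene_meta):
    return ProcessedExpression(
        values=pd.DataFrame(
            np.asarray(mat, dtype=float),
            index=list(gene_meta.index),
            columns=[f"s{i}" for i in range(np.asarray(mat).shape[1])],
        ),
        provenance=["test"],
        gene_meta=gene_meta,
    )


class TestMapEqtls:
    def _setup(self):
        rng = np.random.default_rng(1)
        n = 20
        geno = _geno(
            {"snpA": list(rng.integers(0, 3, n)), "snpB": list(rng.integers(0, 3, n))},
            positions=[100_000, 5_000_000],
        )
        gene_meta = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "tss_bp": [150_000, 9_000_000], "strand": "+"},
            index=pd.Index(["geneX", "geneY"], name="gene_id"),
        )
        expr = _expr_from(rng.normal(size=(2, n)), gene_meta)
        return geno, expr

    def test_cis_mode_enumerates_window_pairs_only(self):
        geno, expr = self._setup()
        recs = map_eqtls(geno, expr, mode="cis")
        assert len(recs) == 1
        assert recs.iloc[0]["snp_id"] == "snpA" and recs.iloc[0]["gene_id"] == "geneX"
        both = map_eqtls(geno, expr, mode="both")
        assert len(both) == 4
        assert (both["kind"] == "cis").sum() == 1

    def test_gene_subset_filters_records(self):
        geno, expr = self._setup()
        recs = map_eqtls(geno, expr, mode="both", gene_subset=["geneY"])
        assert set(recs["gene_id"]) == {"geneY"}
        with pytest.raises(ValueError):
            map_eqtls(geno, expr, gene_subset=["nope"])

    def test_unannotated_gene_excluded(self):
        geno, expr = self._setup()
        meta = expr.gene_meta.copy()
        meta.loc["geneY", ["chrom", "tss_bp"]] = [np.nan, np.nan]
        expr2 = ProcessedExpression(
            values=expr.values, provenance=["test"], gene_meta=meta
        )
        recs = map_eqtls(geno, expr2, mode="both")
        assert set(recs["gene_id"]) == {"geneX"}

    def test_matches_scalar_spearman(self):
        geno, expr = self._setup()
        recs = map_eqtls(geno, expr, mode="both")
        for _, r in recs.iterrows():
            rho, p, n = rank_association(
                geno.dosage[r["snp_id"]], expr.values.loc[r["gene_id"]]
            )
            assert r["rho"] == pytest.approx(rho, abs=1e-12)
            assert r["p_value"] == pytest.approx(p, rel=1e-9)

    def test_sample_order_permutation_invariance(self):
        geno, expr = self._setup()
        recs = map_eqtls(geno, expr, mode="both")
        perm = np.random.default_rng(2).permutation(len(expr.sample_ids))
        ids = [expr.sample_ids[i] for i in perm]
        geno_p = geno.subset_samples(ids)
        expr_p = ProcessedExpression(
            values=expr.values[ids], provenance=["test"], gene_meta=expr.gene_meta
        )
        recs_p = map_eqtls(geno_p, expr_p, mode="both")
        merged = recs.merge(recs_p, on=["snp_id", "gene_id"], suffixes=("", "_p"))
        np.testing.assert_allclose(merged["rho"], merged["rho_p"], atol=1e-12)

    def test_cis_trans_partition_exhaustive_exclusive(self):
        geno, expr = self._setup()
        both = map_eqtls(geno, expr, mode="both")
        cis = map_eqtls(geno, expr, mode="cis")
        trans = map_eqtls(geno, expr, mode="trans")
        assert len(both) == len(cis) + len(trans)
        key = lambda df: set(zip(df["snp_id"], df["gene_id"]))
        assert key(cis) | key(trans) == key(both)
        assert not key(cis) & key(trans)


class TestPermutationFdr:
    def test_estimator_arithmetic(self):
        """100 real hits at t, mean permuted count 5 -> FDR(t) 0.05."""
        from eqtlnet.eqtl import _qvalues

        real_p = np.concatenate([np.full(100, 1e-6), np.linspace(0.5, 1, 900)])
        perm = [
            np.concatenate([np.full(5, 1e-7), np.linspace(0.4, 1, 995)])
            for _ in range(10)
        ]
        q = _qvalues(real_p, perm)
        assert q[0] == pytest.approx(0.05)

    def test_monotone_nondecreasing_in_p(self):
        from eqtlnet.eqtl import _qvalues

        rng = np.random.default_rng(3)
        real_p = rng.uniform(size=300)
        perm = [rng.uniform(size=300) for _ in range(5)]
        q = _qvalues(real_p, perm)
        order = np.argsort(real_p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(4)
        n = 30
        geno = _geno({f"s{j}": list(rng.integers(0, 3, n)) for j in range(6)})
        gene_meta = pd.DataFrame(
            {"chrom": "chr1", "tss_bp": [500, 1500, 2500], "strand": "+"},
            index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
        )
        expr = _expr_from(rng.normal(size=(3, n)), gene_meta)
        recs = map_eqtls(geno, expr, mode="both")
        a = permutation_fdr(geno, expr, recs, n_perm=3, seed=7, fdr_threshold=1.1)
        b = permutation_fdr(geno, expr, recs, n_perm=3, seed=7, fdr_threshold=1.1)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_records_ok(self):
        geno = _geno({"s0": [0, 1, 2, 1]})
        gene_meta = pd.DataFrame(
            {"chrom": "chr1", "tss_bp": [100], "strand": "+"},
            index=pd.Index(["g"], name="gene_id"),
        )
        expr = _expr_from([[1.0, 2.0, 3.0, 4.0]], gene_meta)
        empty = pd.DataFrame(columns=["snp_id", "gene_id", "kind", "p_value"])
        out = permutation_fdr(geno, expr, empty, n_perm=2, seed=0)
        assert out.empty


class TestTopPerGene:
    def _records(self, rows):
        return pd.DataFrame(
            rows, columns=["snp_id", "gene_id", "kind", "distance_bp", "rho", "p_value", "n_used"]
        )

    def test_keeps_min_p(self):
        recs = self._records(
            [
                ["a", "g1", "cis", 100.0, 0.5, 1e-6, 30],
                ["b", "g1", "cis", 200.0, 0.4, 1e-4, 30],
            ]
        )
        top = top_eqtl_per_gene(recs)
        assert list(top["snp_id"]) == ["a"]

    def test_tie_broken_by_distance_then_id(self):
        recs = self._records(
            [
                ["far", "g1", "cis", 500_000.0, 0.5, 1e-5, 30],
                ["near", "g1", "cis", 5_000.0, 0.5, 1e-5, 30],
                ["aaa", "g2", "cis", 100.0, 0.5, 1e-5, 30],
                ["bbb", "g2", "cis", -100.0, 0.5, 1e-5, 30],
            ]
        )
        top = top_eqtl_per_gene(recs).set_index("gene_id")
        assert top.loc["g1", "snp_id"] == "near"
        assert top.loc["g2", "snp_id"] == "aaa"

    def test_single_record_returned(self):
        recs = self._records([["a", "g1", "trans", np.nan, 0.2, 0.5, 20]])
        pd.testing.assert_frame_equal(top_eqtl_per_gene(recs), recs)


class TestSummaries:
    def test_counts_and_tables(self):
        recs = pd.DataFrame(
            {
                "snp_id": ["a", "a", "a", "b", "c"],
                "gene_id": ["g1", "g2", "g3", "g4", "g5"],
                "kind": ["trans", "trans", "trans", "cis", "trans"],
                "distance_bp": [np.nan, 2e6, 3e6, 0.0, np.nan],
                "rho": 0.5,
                "p_value": 1e-4,
                "n_used": 30,
            }
        )
        out = summarize_eqtls(recs)
        assert out["counts"]["cis"] == 1
        assert out["counts"]["trans"] == 4
        assert out["counts"]["trans_cross_chrom"] == 2
        assert out["trans_targets"]["a"] == 3
        hist = out["cis_distance_hist"]
        assert hist["count"].sum() == 1

    def test_empty_input(self):
        out = summarize_eqtls(pd.DataFrame(columns=["snp_id", "gene_id", "kind", "distance_bp"]))
        assert out["counts"]["cis"] == 0 and out["trans_targets"].empty
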