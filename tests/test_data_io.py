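import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coexgwas import data_io
from coexgwas.data_io import (
    ExpressionMatrix,
    GeneLocus,
    SnpRecord,
    exclude_mhc,
    filter_expressed_genes,
    normalize_expression,
    read_gwas_summary,
    write_gwas_summary,
)
from tests.conftest import make_expr


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadGwasSummary:
    def test_valid_rows_parsed(self, tmp_path):
        p = _write(
            tmp_path,
            "gwas.tsv",
            "SNP\tCHR\tBP\tA1\tA2\tP\tN\n"
            "rs1\t1\t100\tA\tG\t0.5\t1000\n"
            "rs2\t1\t200\tC\tT\t0.01\t1000\n"
            "rs3\t2\t300\tG\tA\t1.0\t1000\n",
        )
        recs = read_gwas_summary(p)
        assert len(recs) == 3
        assert recs[1] == SnpRecord("rs2", "1", 200, "C", "T", 0.01, 1000)

    def test_p_zero_row_dropped(self, tmp_path, caplog):
        p = _write(
            tmp_path, "gwas.tsv",
            "SNP\tCHR\tBP\tP\nrs1\t1\t100\t0.0\nrs2\t1\t200\t0.3\n",
        )
        recs = read_gwas_summary(p)
        assert [r.snp_id for r in recs] == ["rs2"]

    def test_column_map_shuffled_order(self, tmp_path):
        canonical = _write(
            tmp_path, "a.tsv", "SNP\tCHR\tBP\tP\nrs1\t1\t100\t0.5\n"
        )
        shuffled = _write(
            tmp_path, "b.tsv", "pval\tmarker\tposition\tchrom\n0.5\trs1\t100\t1\n"
        )
        a = read_gwas_summary(canonical)
        b = read_gwas_summary(
            shuffled,
            column_map={"snp": "marker", "chrom": "chrom", "pos": "position", "p": "pval"},
        )
        assert a == b

    def test_missing_mandatory_column_is_hard_error(self, tmp_path):
        p = _write(tmp_path, "gwas.tsv", "SNP\tCHR\tBP\nrs1\t1\t100\n")
        with pytest.raises(ValueError, match="P"):
            read_gwas_summary(p)

    def test_empty_file_is_hard_error(self, tmp_path):
        p = _write(tmp_path, "gwas.tsv", "SNP\tCHR\tBP\tP\n")
        with pytest.raises(Exception):
            read_gwas_summary(p)

    def test_round_trip(self, tmp_path):
        recs = [
            SnpRecord("rs1", "1", 100, "A", "G", 0.25, 500),
            SnpRecord("rs2", "12", 999, "C", "T", 1e-8, 500),
        ]
        path = tmp_path / "out.tsv"
        write_gwas_summary(recs, path)
        assert read_gwas_summary(path) == recs


class TestGeneLoci:
    def test_tsv_round_trip(self, tmp_path):
        genes = [GeneLocus("g1", "1", 100, 500, "+"), GeneLocus("g2", "2", 10, 20, "-")]
        path = tmp_path / "genes.tsv"
        data_io.write_gene_loci(genes, path)
        assert data_io.read_gene_loci(path) == genes

    def test_bed_coordinates_converted_to_one_based(self, tmp_path):
        p = _write(tmp_path, "genes.bed", "chr1\t99\t500\tg1\t0\t+\n")
        (g,) = data_io.read_gene_loci(p, fmt="bed")
        assert (g.start, g.end) == (100, 500)

    def test_invalid_strand_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            GeneLocus("g1", "1", 1, 10, "*")

    def test_length_inclusive(self):
        assert GeneLocus("g", "1", 10, 19, "+").length_bp == 10


class TestEqtlAndGmt:
    def test_eqtl_round_trip(self, tmp_path):
        pairs = [data_io.EqtlPair("g1", "rs1", "Cortex", 1e-6, 0.01)]
        path = tmp_path / "eqtl.tsv"
        data_io.write_eqtl_pairs(pairs, path)
        assert data_io.read_eqtl_pairs(path) == pairs

    def test_gmt_round_trip(self, tmp_path):
        sets = {"pathA": ["g1", "g2"], "pathB": ["g3"]}
        path = tmp_path / "sets.gmt"
        data_io.write_gene_sets(sets, path)
        assert data_io.read_gene_sets(path) == sets


class TestFilterExpressedGenes:
    def make(self, rpkm, reads):
        expr = make_expr(rpkm)
        counts = pd.DataFrame(
            np.asarray(reads, dtype=float), index=expr.data.index, columns=expr.data.columns
        )
        return expr, counts

    def test_gene_passing_both_thresholds_retained(self):
        expr, counts = self.make(np.full((1, 12), 0.2), np.full((1, 12), 10))
        out = filter_expressed_genes(expr, counts)
        assert out.gene_ids == ["g0"]

    def test_nine_qualifying_samples_is_below_min_donors(self):
        rpkm = np.zeros((1, 12))
        rpkm[0, :9] = 0.2
        reads = np.full((1, 12), 10)
        expr, counts = self.make(rpkm, reads)
        assert filter_expressed_genes(expr, counts).n_genes == 0

    def test_all_removed_returns_empty_matrix(self):
        expr, counts = self.make(np.zeros((3, 12)), np.zeros((3, 12)))
        out = filter_expressed_genes(expr, counts)
        assert out.n_genes == 0

    def test_monotone_in_min_donors(self, rng):
        rpkm = rng.exponential(0.2, size=(50, 20))
        reads = rng.poisson(8, size=(50, 20))
        expr, counts = self.make(rpkm, reads)
        previous = None
        for d in (5, 10, 15):
            kept = set(filter_expressed_genes(expr, counts, min_donors=d).gene_ids)
            if previous is not None:
                assert kept <= previous
            previous = kept

    def test_dimension_mismatch_is_hard_error(self):
        expr, counts = self.make(np.ones((2, 12)), np.ones((2, 12)))
        with pytest.raises(ValueError):
            filter_expressed_genes(expr, counts.iloc[:, :-1])


def latin_square_matrix(values):
    """Genes x samples matrix where column j holds ``values`` cyclically
    shifted by j.  Every column has the same value multiset (the quantile
    step is then the identity) and every gene has distinct cross-sample
    ranks (the inverse-normal step is tie-free)."""
    G = len(values)
    return np.array([[values[(g + j) % G] for j in range(G)] for g in range(G)])


class TestNormalizeExpression:
    def test_inverse_normal_closed_form_n3(self):
        expr = make_expr(latin_square_matrix([1.0, 2.0, 3.0]))
        out = normalize_expression(expr)
        expected = stats.norm.ppf([1 / 6, 3 / 6, 5 / 6])
        # g0 holds (1, 2, 3): cross-sample ranks 1, 2, 3
        np.testing.assert_allclose(out.data.loc["g0"], expected, atol=1e-12)
        # g1 holds (2, 3, 1): ranks 2, 3, 1
        np.testing.assert_allclose(out.data.loc["g1"], expected[[1, 2, 0]], atol=1e-12)

    def test_per_gene_mean_zero_for_tie_free_input(self, rng):
        X = latin_square_matrix(np.sort(rng.normal(size=15)))
        out = normalize_expression(make_expr(X))
        assert np.abs(out.data.mean(axis=1)).max() < 1e-9

    def test_rank_preservation_and_idempotence(self, rng):
        X = latin_square_matrix(np.sort(rng.normal(size=12)))
        once = normalize_expression(make_expr(X))
        twice = normalize_expression(once)
        np.testing.assert_allclose(once.data.values, twice.data.values, atol=1e-12)
        for g in range(12):
            assert (
                np.argsort(once.data.values[g]).tolist()
                == np.argsort(X[g]).tolist()
            )

    def test_permuted_samples_share_post_quantile_multiset(self, rng):
        # two samples that are permutations of the same values map onto
        # identical value multisets after the quantile step
        vals = np.sort(rng.normal(size=6))
        X = np.column_stack([vals, rng.permutation(vals), rng.permutation(vals)])
        Xq = data_io.quantile_normalize(X)
        cols = [np.sort(Xq[:, j]) for j in range(3)]
        np.testing.assert_allclose(cols[0], cols[1], atol=1e-12)
        np.testing.assert_allclose(cols[0], cols[2], atol=1e-12)

    def test_constant_gene_dropped(self):
        X = np.array([
            [5.0, 5.0, 5.0],   # middle rank in every sample -> constant
            [1.0, 6.0, 1.0],
            [9.0, 1.0, 9.0],
        ])
        out = normalize_expression(make_expr(X))
        assert "g0" not in out.gene_ids
        assert {"g1", "g2"} <= set(out.gene_ids)


class TestExcludeMhc:
    def test_gene_inside_region_removed(self):
        g = GeneLocus("g", "6", 30_000_000, 31_000_000, "+")
        assert exclude_mhc([g]) == []

    def test_gene_outside_region_kept(self):
        g = GeneLocus("g", "6", 40_000_000, 40_001_000, "+")
        assert exclude_mhc([g]) == [g]

    def test_boundary_straddling_gene_removed(self):
        g = GeneLocus("g", "chr6", 25_900_000, 26_100_000, "+")
        assert exclude_mhc([g]) == []

    def test_other_chromosome_untouched(self):
        g = GeneLocus("g", "16", 30_000_000, 31_000_000, "+")
        assert exclude_mhc([g]) == [g]


class TestExpressionMatrix:
    def test_duplicate_gene_ids_rejected(self):
        df = pd.DataFrame(np.ones((2, 3)), index=["g", "g"], columns=list("abc"))
        with pytest.raises(ValueError, match="duplicated"):
            ExpressionMatrix(df)

    def test_expression_round_trip(self, tmp_path, rng):
        expr = make_expr(rng.normal(size=(4, 3)))
        path = tmp_path / "expr.tsv"
        data_io.write_expression(expr, path)
        back = data_io.read_expression(path)
        np.testing.assert_allclose(back.data.values, expr.data.values)
        assert back.gene_ids == expr.gene_ids
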