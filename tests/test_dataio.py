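import numpy as np
import pandas as pd
import pytest

from flightsift.dataio import (
    MISSING,
    CategoryScheme,
    DataValidationError,
    GeneModel,
    GenotypeMatrix,
    GOTerm,
    Locus,
    read_category_scheme,
    read_gene_table,
    read_go_tables,
    read_sample_table,
    read_tables,
    read_vcf,
    validate_sample_table,
    write_category_scheme,
    write_gene_table,
    write_go_tables,
    write_sample_table,
    write_vcf,
)

from conftest import make_matrix, make_table


class TestLocus:
    def test_is_snp(self):
        assert Locus("c", 1, "A", "G").is_snp
        assert not Locus("c", 1, "AT", "G").is_snp
        assert not Locus("c", 1, "A", "GC").is_snp

    def test_position_must_be_positive(self):
        with pytest.raises(DataValidationError):
            Locus("c", 0, "A", "G")

    def test_identical_alleles_rejected(self):
        with pytest.raises(DataValidationError):
            Locus("c", 5, "A", "A")


class TestGenotypeMatrix:
    def test_shape_mismatch(self):
        with pytest.raises(DataValidationError, match="shape"):
            GenotypeMatrix(["a", "b"], [Locus("c", 1, "A", "G")],
                           np.zeros((2, 2)), np.zeros((2, 2)))

    def test_bad_dosage_value(self):
        with pytest.raises(DataValidationError, match="dosage"):
            make_matrix([[3]])

    def test_negative_depth(self):
        with pytest.raises(DataValidationError, match="depth"):
            make_matrix([[1]], depth=[[-1]])

    def test_duplicate_samples(self):
        with pytest.raises(DataValidationError, match="sample"):
            make_matrix([[0], [1]], samples=["a", "a"])

    def test_duplicate_loci(self):
        with pytest.raises(DataValidationError, match="duplicate"):
            GenotypeMatrix(["a"], [Locus("c", 1, "A", "G"), Locus("c", 1, "C", "T")],
                           np.zeros((1, 2), dtype=np.int16), np.zeros((1, 2)))

    def test_take_loci_bool_and_int(self):
        m = make_matrix([[0, 1, 2], [2, MISSING, 0]])
        sub_bool = m.take_loci(np.array([True, False, True]))
        sub_int = m.take_loci([0, 2])
        assert sub_bool == sub_int
        assert sub_bool.n_loci == 2
        assert sub_bool.loci == [m.loci[0], m.loci[2]]

    def test_take_samples(self):
        m = make_matrix([[0, 1], [2, 0], [1, 1]])
        sub = m.take_samples([2, 0])
        assert sub.samples == ["s2", "s0"]
        assert np.array_equal(sub.dosage, m.dosage[[2, 0]])

    def test_sample_index_unknown_id(self):
        m = make_matrix([[0], [1]])
        assert list(m.sample_index(["s1", "s0"])) == [1, 0]
        with pytest.raises(DataValidationError, match="unknown sample"):
            m.sample_index(["nope"])

    def test_alt_freq_and_maf(self):
        m = make_matrix([[0, 2, MISSING], [1, 2, MISSING], [1, 2, MISSING]])
        freq = m.alt_freq()
        assert freq[0] == pytest.approx(2 / 6)
        assert freq[1] == pytest.approx(1.0)
        assert np.isnan(freq[2])
        maf = m.maf()
        assert maf[1] == pytest.approx(0.0)

    def test_observed(self):
        m = make_matrix([[0, MISSING]])
        assert m.observed().tolist() == [[True, False]]


class TestVCF:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, size=(6, 15)).astype(np.int16)
        d[rng.random((6, 15)) < 0.2] = MISSING
        m = make_matrix(d, depth=rng.poisson(20, (6, 15)),
                        contigs=[f"ctg{j % 3}" for j in range(15)])
        path = tmp_path / "x.vcf"
        write_vcf(m, path)
        assert read_vcf(path) == m

    def test_empty_matrix_round_trip(self, tmp_path):
        m = GenotypeMatrix(["a", "b"], [], np.zeros((2, 0), dtype=np.int16),
                           np.zeros((2, 0), dtype=np.int32))
        path = tmp_path / "empty.vcf"
        write_vcf(m, path)
        back = read_vcf(path)
        assert back.n_loci == 0 and back.samples == ["a", "b"]

    def test_multiallelic_rejected(self, tmp_path):
        path = tmp_path / "multi.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\n"
            "ctg0\t100\t.\tA\tG,T\t.\tPASS\t.\tGT\t0/1\n"
        )
        with pytest.raises(DataValidationError, match="biallelic"):
            read_vcf(path)

    def test_missing_dp_maps_to_zero(self, tmp_path):
        path = tmp_path / "nodp.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\n"
            "ctg0\t100\t.\tA\tG\t.\tPASS\t.\tGT\t./.\n"
        )
        m = read_vcf(path)
        assert m.dosage[0, 0] == MISSING
        assert m.depth[0, 0] == 0


class TestSampleTable:
    def test_missing_required_column(self):
        with pytest.raises(DataValidationError, match="colony"):
            validate_sample_table(pd.DataFrame({"sample_id": ["a"], "lineage": ["ESM"]}))

    def test_duplicate_ids(self):
        with pytest.raises(DataValidationError, match="duplicate"):
            make_table(["a", "a"])

    def test_bad_lineage(self):
        with pytest.raises(DataValidationError, match="lineage"):
            make_table(["a"], lineage=["XXX"])

    def test_flight_score_range(self):
        with pytest.raises(DataValidationError, match="flight_score"):
            make_table(["a"], flight=[6])
        with pytest.raises(DataValidationError, match="flight_score"):
            make_table(["a"], flight=[2.5])

    def test_flight_score_na_ok(self):
        t = make_table(["a"], flight=[pd.NA])
        assert t["flight_score"].isna().all()

    def test_forewing_positive(self):
        with pytest.raises(DataValidationError, match="forewing"):
            make_table(["a"], forewing=[-1.0])

    def test_role_default_and_validation(self):
        t = validate_sample_table(pd.DataFrame(
            {"sample_id": ["a"], "colony": ["UC"], "lineage": ["ESM"]}))
        assert t["role"].tolist() == ["cohort"]
        with pytest.raises(DataValidationError, match="role"):
            make_table(["a"], role=["boss"])

    def test_round_trip(self, tmp_path):
        t = make_table(["a", "b"], flight=[0, 5], forewing=[24.0, np.nan])
        path = tmp_path / "pheno.tsv"
        write_sample_table(t, path)
        back = read_sample_table(path)
        assert back["sample_id"].tolist() == ["a", "b"]
        assert back["flight_score"].tolist() == [0, 5]


class TestAnnotationIO:
    def test_gene_model_validation(self):
        with pytest.raises(DataValidationError, match="start"):
            GeneModel("g", "c", 10, 5)

    def test_gene_table_round_trip(self, tmp_path):
        genes = [GeneModel("g1", "c1", 1, 100), GeneModel("g2", "c2", 50, 60)]
        path = tmp_path / "genes.tsv"
        write_gene_table(genes, path)
        back = read_gene_table(path)
        assert [(g.gene_id, g.contig, g.start, g.end) for g in back] == \
               [("g1", "c1", 1, 100), ("g2", "c2", 50, 60)]

    def test_bed_coordinates_converted(self, tmp_path):
        path = tmp_path / "genes.bed"
        path.write_text("c1\t0\t100\tg1\n")
        g = read_gene_table(path, bed=True)[0]
        assert (g.start, g.end) == (1, 100)

    def test_go_tables_round_trip_and_validation(self, tmp_path):
        terms = [GOTerm("GO:1", "name one", "def one", frozenset({"g1", "g2"})),
                 GOTerm("GO:2", "name two", "def two", frozenset({"g2"}))]
        mp, tp = tmp_path / "map.tsv", tmp_path / "terms.tsv"
        write_go_tables(terms, mp, tp)
        back = read_go_tables(mp, tp, {"g1", "g2"})
        assert {t.term_id: t.genes for t in back} == {t.term_id: t.genes for t in terms}
        with pytest.raises(DataValidationError, match="unknown gene"):
            read_go_tables(mp, tp, {"g1"})

    def test_read_tables_attaches_terms_to_genes(self, tmp_path):
        genes = [GeneModel("g1", "c1", 1, 10), GeneModel("g2", "c1", 20, 30)]
        terms = [GOTerm("GO:1", "n", "d", frozenset({"g1"}))]
        scheme = CategoryScheme(categories=[("movement", ["locomotion"])])
        write_gene_table(genes, tmp_path / "g.tsv")
        write_go_tables(terms, tmp_path / "m.tsv", tmp_path / "t.tsv")
        write_category_scheme(scheme, tmp_path / "c.json")
        write_sample_table(make_table(["a"]), tmp_path / "p.tsv")
        _, genes2, _, scheme2 = read_tables(tmp_path / "p.tsv", tmp_path / "g.tsv",
                                            tmp_path / "m.tsv", tmp_path / "t.tsv",
                                            tmp_path / "c.json")
        assert genes2[0].go_terms == frozenset({"GO:1"})
        assert genes2[1].go_terms == frozenset()
        assert scheme2.names == ["movement"]


class TestCategoryScheme:
    def test_empty_keywords_rejected(self):
        with pytest.raises(DataValidationError, match="no keywords"):
            CategoryScheme(categories=[("x", [])])

    def test_uppercase_keywords_rejected(self):
        with pytest.raises(DataValidationError, match="lower-case"):
            CategoryScheme(categories=[("x", ["Wing"])])

    def test_round_trip(self, tmp_path):
        scheme = CategoryScheme(categories=[("a", ["x"]), ("b", ["y", "z"])])
        path = tmp_path / "cats.json"
        write_category_scheme(scheme, path)
        assert read_category_scheme(path).categories == scheme.categories
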