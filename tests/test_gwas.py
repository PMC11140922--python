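import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flightsift.dataio import MISSING, GeneModel
from flightsift.gwas import (
    AssocResult,
    CandidateGeneSet,
    adjust_p,
    backward_select_pcs,
    bin_flight,
    candidate_overlap,
    ld_annotate,
    model_grid,
    score_test_scan,
)

from conftest import make_matrix


class TestBinFlight:
    def test_mapping(self):
        assert bin_flight([0, 1, 2, 3, 4, 5]).tolist() == [0, 0, 0, 1, 1, 1]

    def test_rejects_missing_and_out_of_range(self):
        with pytest.raises(ValueError, match="missing"):
            bin_flight([1.0, np.nan])
        with pytest.raises(ValueError, match="0..5"):
            bin_flight([6])
        with pytest.raises(ValueError, match="0..5"):
            bin_flight([2.5])

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.integers(0, 5), min_size=1, max_size=30))
    def test_threshold_property(self, scores):
        out = bin_flight(scores)
        assert all((s >= 3) == bool(o) for s, o in zip(scores, out))


class TestAdjustP:
    def test_bonferroni_closed_form(self):
        p = np.array([0.01, 0.2, 0.5])
        assert np.allclose(adjust_p(p, method="bonferroni"), np.minimum(p * 3, 1.0))

    def test_bh_monotone_and_bounded(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        q = adjust_p(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_range_validation(self):
        with pytest.raises(ValueError):
            adjust_p([1.5])

    def test_empty(self):
        assert adjust_p(np.array([])).size == 0


def _null_scan_matrix(rng, n=150, m=60):
    p = rng.uniform(0.2, 0.8, size=m)
    d = rng.binomial(2, p, size=(n, m)).astype(np.int16)
    return make_matrix(d, contigs=[f"ctg{j % 6}" for j in range(m)])


class TestScoreTestScan:
    def test_gaussian_intercept_only_equals_n_r_squared(self):
        # with an intercept-only null and MLE dispersion the score statistic
        # reduces to n * r^2 (squared Pearson correlation)
        rng = np.random.default_rng(2)
        m = _null_scan_matrix(rng, n=100, m=5)
        y = rng.standard_normal(100)
        res = score_test_scan(m, y, None, link="gaussian")
        for j in range(5):
            r = np.corrcoef(m.dosage[:, j], y)[0, 1]
            assert res.table["stat"][j] == pytest.approx(100 * r**2, rel=1e-8)

    def test_planted_effect_found(self):
        rng = np.random.default_rng(3)
        m = _null_scan_matrix(rng, n=200, m=40)
        y = 0.8 * m.dosage[:, 7].astype(float) + rng.standard_normal(200)
        res = score_test_scan(m, y, None, link="gaussian")
        assert int(res.table["p"].idxmin()) == 7
        assert res.table["sign"][7] > 0

    def test_missing_phenotype_dropped(self):
        rng = np.random.default_rng(4)
        m = _null_scan_matrix(rng, n=50, m=10)
        y = rng.standard_normal(50)
        y[:10] = np.nan
        res = score_test_scan(m, y, None, link="gaussian")
        assert res.n_samples == 40

    def test_missing_genotypes_use_observed_subset(self):
        rng = np.random.default_rng(5)
        m = _null_scan_matrix(rng, n=80, m=4)
        d = m.dosage.copy()
        d[:40, 2] = MISSING
        m2 = make_matrix(d, contigs=[l.contig for l in m.loci])
        y = rng.standard_normal(80)
        res = score_test_scan(m2, y, None, link="gaussian")
        # locus 2 statistic equals a fresh scan restricted to the observed rows
        sub = m2.take_samples(np.arange(40, 80)).take_loci([2])
        res_sub = score_test_scan(sub, y[40:], None, link="gaussian")
        assert res.table["stat"][2] == pytest.approx(res_sub.table["stat"][0])

    def test_too_few_observed_calls_gives_nan(self):
        rng = np.random.default_rng(6)
        m = _null_scan_matrix(rng, n=30, m=3)
        d = m.dosage.copy()
        d[2:, 1] = MISSING  # only 2 observed calls
        m2 = make_matrix(d, contigs=[l.contig for l in m.loci])
        res = score_test_scan(m2, rng.standard_normal(30), None, link="gaussian")
        assert np.isnan(res.table["stat"][1])

    def test_binomial_gif_and_qq(self):
        rng = np.random.default_rng(7)
        m = _null_scan_matrix(rng, n=200, m=300)
        y = rng.integers(0, 2, size=200).astype(float)
        res = score_test_scan(m, y, None, link="binomial")
        assert res.converged
        assert 0.7 < res.gif < 1.3
        assert len(res.qq) == 300
        # both QQ columns run most-significant first
        assert (np.diff(res.qq["observed"]) <= 1e-12).all()
        assert (np.diff(res.qq["expected"]) <= 1e-12).all()

    def test_degenerate_binomial_not_converged(self):
        rng = np.random.default_rng(8)
        m = _null_scan_matrix(rng, n=40, m=5)
        y = np.ones(40)  # constant outcome: fitted probabilities pinned at 1
        res = score_test_scan(m, y, None, link="binomial")
        assert not res.converged

    def test_unknown_link(self):
        m = _null_scan_matrix(np.random.default_rng(9), n=20, m=2)
        with pytest.raises(ValueError, match="link"):
            score_test_scan(m, np.zeros(20), None, link="poisson")

    def test_outliers_selection(self):
        table = pd.DataFrame({"contig": ["c"] * 3, "position": [1, 2, 3],
                              "stat": [1, 2, 3], "p": [0.01, 0.2, 0.04],
                              "p_adj": [0.03, 0.6, 0.12], "sign": [1, 1, -1]})
        res = AssocResult("gaussian", "", table, 0.0, 1.0, True, 10)
        assert len(res.outliers(0.05)) == 2
        assert len(res.outliers(0.05, adjusted=True)) == 1


class TestModelGrid:
    def test_selects_largest_converged(self):
        rng = np.random.default_rng(10)
        m = _null_scan_matrix(rng, n=120, m=30)
        y = rng.standard_normal(120)
        pcs = rng.standard_normal((120, 4))
        results, sel = model_grid(m, y, pcs, [0, 2, 4], link="gaussian")
        assert len(results) == 3
        assert sel == 2
        assert results[sel].covariate_spec == "4 PCs"

    def test_kinship_covariates_in_spec(self):
        rng = np.random.default_rng(11)
        m = _null_scan_matrix(rng, n=60, m=10)
        y = rng.standard_normal(60)
        pcs = rng.standard_normal((60, 2))
        kc = rng.standard_normal((60, 1))
        results, sel = model_grid(m, y, pcs, [0, 2], link="gaussian",
                                  kinship_covariates=kc)
        assert "kinship factors" in results[sel].covariate_spec

    def test_all_unresolved_raises(self):
        rng = np.random.default_rng(12)
        m = _null_scan_matrix(rng, n=40, m=5)
        y = np.ones(40)
        pcs = rng.standard_normal((40, 2))
        with pytest.raises(RuntimeError, match="resolved"):
            model_grid(m, y, pcs, [0, 2], link="binomial")

    def test_empty_grid(self):
        m = _null_scan_matrix(np.random.default_rng(13), n=20, m=2)
        with pytest.raises(ValueError, match="empty PC grid"):
            model_grid(m, np.zeros(20), np.zeros((20, 2)), [], link="gaussian")


class TestBackwardSelect:
    def test_keeps_informative_pc(self):
        rng = np.random.default_rng(14)
        pcs = rng.standard_normal((300, 4))
        y = 2.0 * pcs[:, 1] + rng.standard_normal(300)
        kept = backward_select_pcs(y, pcs, link="gaussian")
        assert 1 in kept
        assert len(kept) < 4


class TestLDAnnotate:
    def _setup(self):
        rng = np.random.default_rng(15)
        base = rng.integers(0, 3, size=60).astype(np.int16)
        d = np.column_stack([
            base,                              # locus 0: outlier, outside genes
            base,                              # locus 1: inside gene A, r=1 with locus 0
            rng.integers(0, 3, size=60),       # locus 2: inside gene B, unlinked
            rng.integers(0, 3, size=60),       # locus 3: inside gene C, itself an outlier
        ])
        m = make_matrix(d, contigs=["ctg0"] * 4, start_pos=100, spacing=1000)
        # positions: 100, 1100, 2100, 3100
        genes = [GeneModel("A", "ctg0", 1050, 1150),
                 GeneModel("B", "ctg0", 2050, 2150),
                 GeneModel("C", "ctg0", 3050, 3150)]
        table = pd.DataFrame({
            "contig": ["ctg0"] * 4, "position": [100, 1100, 2100, 3100],
            "stat": [9.0, 1.0, 1.0, 7.0], "p": [0.001, 0.5, 0.5, 0.01],
            "p_adj": [0.004, 0.6, 0.6, 0.02], "sign": [1.0] * 4})
        assoc = AssocResult("binomial", "0 PCs", table, 0.0, 1.0, True, 60)
        return m, genes, assoc

    def test_assignment_rules(self):
        m, genes, assoc = self._setup()
        cset = ld_annotate(m, assoc, genes, "flight_capability", r_min=0.9, p_max=0.05)
        assert cset.gene_ids == {"A", "C"}
        assert cset.genes["A"]["r"] == pytest.approx(1.0)
        assert cset.genes["A"]["marker"] == "ctg0:100"
        assert cset.genes["C"]["marker"] == "ctg0:3100"  # in-gene outlier, r = 1

    def test_r_min_threshold_excludes_weak_ld(self):
        m, genes, assoc = self._setup()
        # perturb locus 1 so correlation with locus 0 drops below 1
        d = m.dosage.copy()
        d[:20, 1] = (2 - d[:20, 1])
        m2 = make_matrix(d, contigs=["ctg0"] * 4, start_pos=100, spacing=1000)
        cset = ld_annotate(m2, assoc, genes, "flight_capability", r_min=0.99, p_max=0.05)
        assert "A" not in cset.gene_ids

    def test_use_adjusted_pvalues(self):
        m, genes, assoc = self._setup()
        cset = ld_annotate(m, assoc, genes, "x", r_min=0.9, p_max=0.01, use_adjusted=True)
        assert cset.gene_ids == {"A"}


class TestCandidateOverlap:
    def test_counts(self):
        a = CandidateGeneSet("flight_capability", {"g1": {}, "g2": {}})
        b = CandidateGeneSet("forewing_length", {"g2": {}, "g3": {}})
        c = CandidateGeneSet("inbred", {"g2": {}})
        df = candidate_overlap([a, b, c])
        pair = df[(df.set_a == "flight_capability") & (df.set_b == "forewing_length")]
        assert pair["intersection"].iloc[0] == 1
        assert df[df.set_a == "ALL"]["intersection"].iloc[0] == 1

    def test_needs_two_sets(self):
        with pytest.raises(ValueError):
            candidate_overlap([CandidateGeneSet("x", {})])
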