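from math import comb

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from flightsift.dataio import CategoryScheme, GOTerm
from flightsift.enrichment import (
    build_term_graph,
    categorize_terms,
    category_overrepresentation,
    describe_clusters,
    mcl_cluster,
    term_enrichment,
)


def term(tid, genes, name="term name", definition="term definition"):
    return GOTerm(tid, name, definition, frozenset(genes))


class TestTermEnrichment:
    def test_hypergeometric_extreme_overlap(self):
        universe = {f"g{i}" for i in range(20)}
        t = term("GO:1", {f"g{i}" for i in range(5)})
        rep = term_enrichment({f"g{i}" for i in range(5)}, [t], universe=universe)
        assert rep.table["p"][0] == pytest.approx(1 / comb(20, 5), abs=1e-15)

    def test_zero_overlap_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        t = term("GO:1", {"g0", "g1"})
        rep = term_enrichment({"g8", "g9"}, [t], universe=universe)
        assert rep.table["p"][0] == pytest.approx(1.0)

    def test_matches_scipy_hypergeom(self):
        universe = {f"g{i}" for i in range(30)}
        t = term("GO:1", {f"g{i}" for i in range(8)})
        cand = {f"g{i}" for i in range(4, 10)}  # overlap 4, candidates 6
        rep = term_enrichment(cand, [t], universe=universe)
        assert rep.table["p"][0] == pytest.approx(stats.hypergeom.sf(3, 30, 8, 6))

    def test_default_universe_is_union(self):
        t1 = term("GO:1", {"a", "b"})
        t2 = term("GO:2", {"c"})
        rep = term_enrichment({"a"}, [t1, t2])
        # universe = {a, b, c}: P(overlap >= 1) for term of 2 in draw of 1 = 2/3
        assert rep.table["p"][0] == pytest.approx(2 / 3)

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError, match="empty candidate"):
            term_enrichment(set(), [term("GO:1", {"a"})])

    def test_enriched_selection(self):
        universe = {f"g{i}" for i in range(40)}
        hit = term("GO:1", {f"g{i}" for i in range(5)})
        miss = term("GO:2", {"g30", "g31"})
        rep = term_enrichment({f"g{i}" for i in range(5)}, [hit, miss],
                              universe=universe)
        assert rep.enriched(0.05)["term_id"].tolist() == ["GO:1"]


class TestCategorize:
    scheme = CategoryScheme(categories=[
        ("movement", ["locomotion", "flight"]),
        ("morphology", ["wing", "muscle"]),
    ])

    def test_name_and_definition_both_searched(self):
        terms = [term("GO:1", set(), name="flight behavior", definition="nothing"),
                 term("GO:2", set(), name="plain", definition="muscle assembly"),
                 term("GO:3", set(), name="plain", definition="nothing at all")]
        cats = categorize_terms(terms, self.scheme)
        assert cats == {"GO:1": ["movement"], "GO:2": ["morphology"], "GO:3": []}

    def test_multi_category(self):
        t = term("GO:1", set(), definition="wing muscle flight apparatus")
        cats = categorize_terms([t], self.scheme)
        assert cats["GO:1"] == ["movement", "morphology"]

    def test_word_boundary_option(self):
        t = term("GO:1", set(), definition="winged locomotionless")
        assert categorize_terms([t], self.scheme)["GO:1"] == ["movement", "morphology"]
        assert categorize_terms([t], self.scheme, word_boundary=True)["GO:1"] == []

    def test_case_insensitive(self):
        t = term("GO:1", set(), name="Flight Muscle")
        assert set(categorize_terms([t], self.scheme)["GO:1"]) == {"movement",
                                                                   "morphology"}


class TestCategoryOverrepresentation:
    scheme = CategoryScheme(categories=[("movement", ["locomotion"]),
                                        ("rhythm", ["circadian"])])

    def _reference(self, n=100, k_move=20):
        ref = [term(f"R:{i}", set(), definition="locomotion related")
               for i in range(k_move)]
        ref += [term(f"R:{i}", set(), definition="unrelated filler")
                for i in range(k_move, n)]
        return ref

    def test_matches_scipy_binomial(self):
        ref = self._reference()
        enr = [term(f"E:{i}", set(), definition="locomotion related") for i in range(6)]
        enr += [term(f"E:{i}", set(), definition="filler") for i in range(6, 10)]
        rep = category_overrepresentation(enr, ref, self.scheme)
        row = rep.table.set_index("category").loc["movement"]
        assert row["p"] == pytest.approx(stats.binom.sf(5, 10, 0.2))
        assert row["observed"] == 6
        assert row["background_proportion"] == pytest.approx(0.2)

    def test_degenerate_category_flagged(self):
        ref = self._reference()  # no circadian terms in the reference
        enr = [term("E:1", set(), definition="circadian clock")]
        rep = category_overrepresentation(enr, ref, self.scheme)
        row = rep.table.set_index("category").loc["rhythm"]
        assert row["p"] == 0.0 and bool(row["degenerate"])

    def test_bh_across_categories(self):
        ref = self._reference()
        enr = [term("E:1", set(), definition="locomotion")]
        rep = category_overrepresentation(enr, ref, self.scheme)
        p = rep.table["p"].to_numpy()
        from flightsift.gwas import adjust_p
        assert np.allclose(rep.table["p_adj"].to_numpy(), adjust_p(p))


class TestTermGraph:
    def test_overlap_coefficient_weights(self):
        a = term("GO:1", {"x", "y", "z"})
        b = term("GO:2", {"y", "z"})  # overlap 2 / min(3,2) = 1.0
        c = term("GO:3", {"x", "q", "r", "s"})  # overlap with a: 1/3 < 0.5
        g = build_term_graph([a, b, c], min_weight=0.5)
        assert g.has_edge("GO:1", "GO:2")
        assert g["GO:1"]["GO:2"]["weight"] == pytest.approx(1.0)
        assert not g.has_edge("GO:1", "GO:3")
        assert g.number_of_nodes() == 3

    def test_empty_gene_sets_no_edge(self):
        g = build_term_graph([term("GO:1", set()), term("GO:2", set())])
        assert g.number_of_edges() == 0


class TestMCL:
    def test_two_cliques_two_clusters(self):
        g = nx.Graph()
        for block in (["a", "b", "c"], ["x", "y", "z"]):
            for i in range(3):
                for j in range(i + 1, 3):
                    g.add_edge(block[i], block[j], weight=1.0)
        g.add_edge("c", "x", weight=0.05)
        clusters = mcl_cluster(g)
        assert sorted(map(sorted, clusters)) == [["a", "b", "c"], ["x", "y", "z"]]

    def test_singletons_allowed(self):
        g = nx.Graph()
        g.add_node("lonely")
        g.add_edge("a", "b", weight=1.0)
        clusters = mcl_cluster(g)
        assert {"lonely"} in clusters
        assert {"a", "b"} in clusters

    def test_errors(self):
        with pytest.raises(ValueError, match="empty graph"):
            mcl_cluster(nx.Graph())
        g = nx.Graph()
        g.add_edge("a", "b")
        with pytest.raises(ValueError, match="inflation"):
            mcl_cluster(g, inflation=1.0)


class TestDescribeClusters:
    def test_descriptor_and_support(self):
        terms = [
            term("GO:1", {"g1", "g2", "g3", "g4", "g5"},
                 definition="flight muscle fiber assembly process"),
            term("GO:2", {"g1"},
                 definition="flight muscle tension regulation process"),
        ]
        catmap = {"GO:1": ["movement"], "GO:2": ["movement", "morphology"]}
        out = describe_clusters([{"GO:1", "GO:2"}], terms, catmap)
        c = out[0]
        # frequency 2: flight, muscle, process; ties broken alphabetically
        assert c.descriptor == ["flight", "muscle", "process", "assembly"]
        assert c.category_hits == {"movement": 2, "morphology": 1}
        assert c.gene_support_range == (1, 5)
        assert c.well_supported  # a member term has >= 5 supporting genes

    def test_stopwords_excluded(self):
        terms = [term("GO:1", {"g"}, definition="the regulation of the response")]
        out = describe_clusters([{"GO:1"}], terms, {"GO:1": []})
        assert "the" not in out[0].descriptor
        assert "of" not in out[0].descriptor
        assert "regulation" in out[0].descriptor  # GO boilerplate kept

    def test_well_supported_by_category_hits(self):
        terms = [term(f"GO:{i}", {"g"}, definition="w") for i in range(10)]
        catmap = {f"GO:{i}": ["movement"] for i in range(10)}
        out = describe_clusters([{f"GO:{i}" for i in range(10)}], terms, catmap)
        assert out[0].well_supported  # 10 category hits, only 1 gene

    def test_not_well_supported(self):
        terms = [term("GO:1", {"g1", "g2"}, definition="w")]
        out = describe_clusters([{"GO:1"}], terms, {"GO:1": ["movement"]})
        assert not out[0].well_supported
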