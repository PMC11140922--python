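"""GO-term enrichment, flight-category over-representation, and MCL
clustering of enriched-term networks.

Per-term enrichment of a candidate gene set uses the hypergeometric
upper tail within the annotated gene universe (enriched at p < 0.05).
Enriched terms are binned into the 12 flight-relevant keyword
categories, and each category is tested for over-representation against
its share of the reference annotation with a one-tailed binomial test
(BH-adjusted across categories, FDR 5%).  Enriched terms are then
clustered with the Markov Cluster algorithm on a gene-overlap graph,
and each cluster is summarized by the four most common definition
words, its per-category hit counts, and its gene support.

GO is treated as a flat term set: no hierarchy propagation is applied,
since the category statistic only needs term-level gene sets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .dataio import CategoryScheme, GOTerm
from .gwas import adjust_p

__all__ = [
    "EnrichmentReport",
    "TermCluster",
    "term_enrichment",
    "categorize_terms",
    "category_overrepresentation",
    "build_term_graph",
    "mcl_cluster",
    "describe_clusters",
]

#: Minimal English stopword list for cluster descriptors.  GO boilerplate
#: such as "process" and "regulation" is deliberately kept: those words
#: are informative in flat term vocabularies.
STOPWORDS = frozenset(
    "a an and are as at be by for from has have in into is it its of on or "
    "that the their this to via with within".split()
)


@dataclass
class EnrichmentReport:
    tag: str
    level: str  # {"term", "category"}
    table: pd.DataFrame

    def enriched(self, alpha: float = 0.05, adjusted: bool = False) -> pd.DataFrame:
        col = "p_adj" if adjusted else "p"
        return self.table[self.table[col] < alpha]


def term_enrichment(candidates, terms: list[GOTerm], universe=None, tag: str = "") -> EnrichmentReport:
    """Hypergeometric upper-tail enrichment of each GO term.

    ``universe`` defaults to the union of all term gene sets.  A term
    with zero candidate overlap has p = 1 (the upper tail at 0 spans the
    whole distribution).
    """
    candidates = set(candidates)
    if not candidates:
        raise ValueError("empty candidate gene set")
    if universe is None:
        universe = set().union(*(t.genes for t in terms))
    universe = set(universe)
    cand = candidates & universe
    m_total = len(universe)
    n_cand = len(cand)
    rows = []
    for t in terms:
        term_genes = t.genes & universe
        k = len(term_genes & cand)
        p = float(stats.hypergeom.sf(k - 1, m_total, len(term_genes), n_cand))
        rows.append({"term_id": t.term_id, "name": t.name, "term_size": len(term_genes),
                     "overlap": k, "p": p})
    table = pd.DataFrame(rows)
    table["p_adj"] = adjust_p(table["p"].to_numpy())
    return EnrichmentReport(tag=tag, level="term", table=table)


def categorize_terms(
    terms: list[GOTerm], scheme: CategoryScheme, word_boundary: bool = False
) -> dict[str, list[str]]:
    """Assign terms to categories by case-insensitive keyword matching
    against the term name and definition.  Multi-category membership is
    allowed; unmatched terms map to an empty list.  Categorization is
    blind to which analysis produced the term."""
    out: dict[str, list[str]] = {}
    for t in terms:
        text = f"{t.name} {t.definition}".lower()
        cats = []
        for name, keywords in scheme.categories:
            for kw in keywords:
                hit = (re.search(rf"\b{re.escape(kw)}\b", text) if word_boundary
                       else kw in text)
                if hit:
                    cats.append(name)
                    break
        out[t.term_id] = cats
    return out


def category_overrepresentation(
    enriched_terms: list[GOTerm],
    reference_terms: list[GOTerm],
    scheme: CategoryScheme,
    tag: str = "",
) -> EnrichmentReport:
    """One-tailed binomial test of category counts among enriched terms.

    The null is that the enriched-term count in a category occurs in the
    same proportion as in the reference annotation: with p0 the
    reference proportion and k of n enriched terms in the category,
    p = P(Binomial(n, p0) >= k).  BH adjustment runs across the
    categories of one analysis.
    """
    ref_cats = categorize_terms(reference_terms, scheme)
    enr_cats = categorize_terms(enriched_terms, scheme)
    n_ref = len(reference_terms)
    n_enr = len(enriched_terms)
    rows = []
    for name, _ in scheme.categories:
        ref_k = sum(1 for cats in ref_cats.values() if name in cats)
        k = sum(1 for cats in enr_cats.values() if name in cats)
        p0 = ref_k / n_ref if n_ref else 0.0
        if p0 == 0.0:
            p = 0.0 if k > 0 else 1.0
            degenerate = k > 0
        else:
            p = float(stats.binom.sf(k - 1, n_enr, p0))
            degenerate = False
        rows.append({"category": name, "observed": k, "n_enriched": n_enr,
                     "background_count": ref_k, "background_proportion": p0,
                     "p": p, "degenerate": degenerate})
    table = pd.DataFrame(rows)
    table["p_adj"] = adjust_p(table["p"].to_numpy())
    return EnrichmentReport(tag=tag, level="category", table=table)


def build_term_graph(enriched_terms: list[GOTerm], min_weight: float = 0.5) -> nx.Graph:
    """Weighted term network: nodes are enriched terms, edge weight the
    overlap coefficient |A & B| / min(|A|, |B|) of their gene sets;
    edges below ``min_weight`` are omitted."""
    g = nx.Graph()
    for t in enriched_terms:
        g.add_node(t.term_id)
    for i, a in enumerate(enriched_terms):
        for b in enriched_terms[i + 1:]:
            denom = min(len(a.genes), len(b.genes))
            if denom == 0:
                continue
            w = len(a.genes & b.genes) / denom
            if w >= min_weight and w > 0:
                g.add_edge(a.term_id, b.term_id, weight=w)
    return g


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 2.0,
    prune: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> list[set]:
    """Markov clustering of a weighted graph.

    Self-loops are added with each node's maximum incident edge weight
    (1 for isolated nodes); the column-stochastic matrix is then
    alternately expanded (squared) and inflated (elementwise power,
    renormalized) with pruning of small entries until the matrix is
    stable.  Clusters are the connected components of the converged
    attractor structure; singletons are allowed.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if inflation <= 1:
        raise ValueError("inflation must exceed 1")
    nodes = sorted(graph.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = data.get("weight", 1.0)
        m[index[a], index[b]] = w
        m[index[b], index[a]] = w
    loop = m.max(axis=0)
    loop[loop == 0] = 1.0
    m[np.diag_indices(n)] = loop
    m /= m.sum(axis=0, keepdims=True)

    for _ in range(max_iter):
        expanded = m @ m
        inflated = expanded**inflation
        inflated[inflated < prune] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        inflated /= colsum
        if np.abs(inflated - m).max() < tol:
            m = inflated
            break
        m = inflated

    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(m > prune * 10)
    support.add_edges_from(zip(rows.tolist(), cols.tolist()))
    return [{nodes[i] for i in comp} for comp in nx.connected_components(support)]


@dataclass
class TermCluster:
    members: set
    descriptor: list[str] = field(default_factory=list)  # up to 4 words
    category_hits: dict = field(default_factory=dict)  # category -> member-term count
    gene_support_range: tuple[int, int] = (0, 0)  # min-max supporting genes per term
    well_supported: bool = False

    @property
    def n_category_hits(self) -> int:
        return sum(self.category_hits.values())


def describe_clusters(
    clusters: list[set],
    terms: list[GOTerm],
    categorization: dict[str, list[str]],
    min_category_hits: int = 10,
    min_genes: int = 5,
    stopwords=STOPWORDS,
) -> list[TermCluster]:
    """Summarize MCL clusters.

    The descriptor is the four most frequent non-stopword tokens across
    member definitions (ties by frequency, then alphabetical; shorter if
    the vocabulary is exhausted).  A cluster is well-supported if it
    receives at least ``min_category_hits`` category hits or any member
    term is supported by at least ``min_genes`` genes.
    """
    by_id = {t.term_id: t for t in terms}
    out = []
    for members in clusters:
        counts: dict[str, int] = {}
        for tid in members:
            for token in re.findall(r"[a-z0-9']+", by_id[tid].definition.lower()):
                if token not in stopwords:
                    counts[token] = counts.get(token, 0) + 1
        ordered = sorted(counts, key=lambda w: (-counts[w], w))
        descriptor = ordered[:4]
        cat_hits: dict[str, int] = {}
        for tid in members:
            for cat in categorization.get(tid, []):
                cat_hits[cat] = cat_hits.get(cat, 0) + 1
        gene_counts = [len(by_id[tid].genes) for tid in members]
        rng = (min(gene_counts), max(gene_counts)) if gene_counts else (0, 0)
        cluster = TermCluster(
            members=set(members),
            descriptor=descriptor,
            category_hits=cat_hits,
            gene_support_range=rng,
            well_supported=(sum(cat_hits.values()) >= min_category_hits or rng[1] >= min_genes),
        )
        out.append(cluster)
    return out
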