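"""Overrepresentation analysis and the kappa-linked functional annotation map.

Network proteins are tested against flat term gene sets (GMT) with a
right-tailed hypergeometric test and Benjamini-Hochberg correction.  Pairs
of enriched terms whose gene memberships agree (Cohen's kappa over the gene
universe at or above a threshold, 0.3 by default) are linked into a term
map; connected components form annotation groups, each led by its most
significant term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network_core import TermGeneSet, _normalize_symbol

DEFAULT_KAPPA_THRESHOLD = 0.3


@dataclass(frozen=True)
class EnrichedTerm:
    """Hypergeometric enrichment result for one term."""

    term_id: str
    name: str
    overlap: int  # k: query genes annotated to the term
    term_size: int  # K: term genes inside the universe
    query_size: int  # n
    universe_size: int  # N
    p_value: float
    adjusted_p: float

    def __post_init__(self) -> None:
        if self.overlap > min(self.term_size, self.query_size):
            raise ValueError("overlap exceeds term or query size")


def hypergeometric_enrichment(
    query: set[str],
    universe: set[str],
    terms: Sequence[TermGeneSet],
    alpha: float | None = None,
) -> list[EnrichedTerm]:
    """Right-tail hypergeometric overrepresentation of each term in the query.

    Each term is intersected with the universe first; p = P(X >= k) for an
    overlap of k out of a query of n drawn from N genes of which K carry the
    term.  Results carry BH-adjusted p-values and are sorted ascending by
    raw p (ties: term id).  ``alpha`` optionally filters on adjusted p;
    the default reports every term.
    """
    query = {_normalize_symbol(g) for g in query}
    universe = {_normalize_symbol(g) for g in universe}
    if not query or not universe:
        raise ValueError("query and universe must be nonempty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    n, n_universe = len(query), len(universe)
    results = []
    for term in terms:
        term_genes = term.genes & universe
        if not term_genes:
            continue
        k = len(term_genes & query)
        big_k = len(term_genes)
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n))
        results.append((term, k, big_k, min(p, 1.0)))
    if not results:
        return []
    adjusted = multipletests([p for *_, p in results], method="fdr_bh")[1]
    enriched = [
        EnrichedTerm(
            term_id=term.term_id,
            name=term.name,
            overlap=k,
            term_size=big_k,
            query_size=n,
            universe_size=n_universe,
            p_value=p,
            adjusted_p=float(adj),
        )
        for (term, k, big_k, p), adj in zip(results, adjusted)
    ]
    enriched.sort(key=lambda t: (t.p_value, t.term_id))
    if alpha is not None:
        enriched = [t for t in enriched if t.adjusted_p <= alpha]
    return enriched


def kappa_score(term_a: set[str], term_b: set[str], universe: set[str]) -> float:
    """Cohen's kappa agreement of two gene sets' membership over a universe.

    With 2x2 counts a (in both), b (A only), c (B only), d (neither):
    po = (a + d)/N, pe = ((a+b)(a+c) + (c+d)(b+d))/N^2 and
    kappa = (po - pe)/(1 - pe).  Identical sets score exactly 1 (including
    the degenerate empty/full cases); a degenerate pe = 1 with unequal sets
    is an error.
    """
    set_a = {_normalize_symbol(g) for g in term_a} & universe
    set_b = {_normalize_symbol(g) for g in term_b} & universe
    n = len(universe)
    if n == 0:
        raise ValueError("empty universe")
    if set_a == set_b:
        return 1.0
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = n - a - b - c
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    if pe == 1.0:
        raise ValueError("degenerate membership table with unequal sets")
    return (po - pe) / (1.0 - pe)


@dataclass
class TermMap:
    """Kappa-linked network of enriched terms grouped into components."""

    graph: nx.Graph
    threshold: float
    groups: list[dict[str, object]]

    @property
    def n_terms(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_links(self) -> int:
        return self.graph.number_of_edges()


def build_term_map(
    enriched: Sequence[EnrichedTerm],
    terms: Sequence[TermGeneSet],
    universe: set[str],
    threshold: float = DEFAULT_KAPPA_THRESHOLD,
) -> TermMap:
    """Link enriched terms whose gene-set kappa meets the threshold.

    Groups are the connected components; each group's leading term has the
    smallest adjusted p (ties broken by larger overlap, then term id).
    """
    if not enriched:
        raise ValueError("no enriched terms to map")
    universe = {_normalize_symbol(g) for g in universe}
    gene_sets = {t.term_id: t.genes for t in terms}
    by_id = {t.term_id: t for t in enriched}
    graph = nx.Graph()
    ids = sorted(by_id)
    graph.add_nodes_from(ids)
    for i, id_a in enumerate(ids):
        for id_b in ids[i + 1 :]:
            kappa = kappa_score(gene_sets[id_a], gene_sets[id_b], universe)
            if kappa >= threshold:
                graph.add_edge(id_a, id_b, kappa=kappa)
    groups = []
    for component in sorted(nx.connected_components(graph), key=lambda c: sorted(c)):
        members = sorted(component)
        leader = min(
            members,
            key=lambda t: (by_id[t].adjusted_p, -by_id[t].overlap, t),
        )
        groups.append({"leading_term": leader, "members": members})
    return TermMap(graph=graph, threshold=threshold, groups=groups)
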