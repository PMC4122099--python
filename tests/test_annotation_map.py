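"""Hypergeometric enrichment, Cohen's kappa and the kappa-linked term map."""

import itertools
import math

import numpy as np
import pytest

import ppinet as pp
from ppinet import TermGeneSet


def enumeration_p_at_least(universe: set, term: set, n_query: int, k: int) -> float:
    """P(X >= k) by exhaustive enumeration of all size-n draws from the universe."""
    draws = list(itertools.combinations(sorted(universe), n_query))
    hits = sum(1 for d in draws if len(set(d) & term) >= k)
    return hits / len(draws)


class TestHypergeometricEnrichment:
    def test_term_equals_universe_gives_p_one(self):
        universe = {f"g{i}" for i in range(8)}
        terms = [TermGeneSet("T1", "all", frozenset(universe))]
        result = pp.hypergeometric_enrichment({"G0", "G1"}, universe, terms)
        assert result[0].p_value == pytest.approx(1.0)

    def test_worked_example_one_third(self):
        universe = {f"g{i}" for i in range(10)}
        term = frozenset(f"g{i}" for i in range(4))
        query = {"G0", "G1", "G4"}  # overlap k = 2
        result = pp.hypergeometric_enrichment(
            query, universe, [TermGeneSet("T1", "t", term)]
        )
        assert result[0].overlap == 2
        assert result[0].p_value == pytest.approx(1 / 3, abs=1e-12)

    def test_zero_overlap_gives_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        terms = [TermGeneSet("T1", "t", frozenset({"g8", "g9"}))]
        result = pp.hypergeometric_enrichment({"G0", "G1"}, universe, terms)
        assert result[0].p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_oracle_small_universe(self, seed):
        rng = np.random.default_rng(seed)
        n_universe = int(rng.integers(6, 13))
        universe = {f"g{i}" for i in range(n_universe)}
        term = set(rng.choice(sorted(universe), size=int(rng.integers(2, n_universe)), replace=False))
        n_query = int(rng.integers(2, n_universe - 1))
        query = set(rng.choice(sorted(universe), size=n_query, replace=False))
        result = pp.hypergeometric_enrichment(
            query, universe, [TermGeneSet("T1", "t", frozenset(term))]
        )
        k = len({g.upper() for g in term} & {g.upper() for g in query})
        expected = enumeration_p_at_least(
            {g.upper() for g in universe}, {g.upper() for g in term}, n_query, k
        )
        assert result[0].p_value == pytest.approx(expected, abs=1e-12)

    def test_bh_adjustment_monotone_with_raw_p(self):
        rng = np.random.default_rng(0)
        universe = {f"g{i}" for i in range(40)}
        terms = [
            TermGeneSet(f"T{i}", "t", frozenset(rng.choice(sorted(universe), size=8, replace=False)))
            for i in range(12)
        ]
        query = set(rng.choice(sorted(universe), size=10, replace=False))
        result = pp.hypergeometric_enrichment(query, universe, terms)
        raws = [t.p_value for t in result]
        adjusted = [t.adjusted_p for t in result]
        assert raws == sorted(raws)
        assert adjusted == sorted(adjusted)  # BH step-up never inverts the order
        assert all(a >= r for a, r in zip(adjusted, raws))

    def test_empty_query_errors(self):
        with pytest.raises(ValueError):
            pp.hypergeometric_enrichment(set(), {"G1"}, [])


class TestKappaScore:
    def test_identical_sets_score_one(self):
        universe = {f"g{i}" for i in range(10)}
        assert pp.kappa_score({"g1", "g2"}, {"g1", "g2"}, {g.upper() for g in universe}) == 1.0

    def test_worked_two_by_two(self):
        universe = {f"G{i}" for i in range(1, 11)}
        a = {f"G{i}" for i in range(1, 6)}
        b = {f"G{i}" for i in range(4, 9)}
        # a=2, b=3, c=3, d=2 -> po=0.4, pe=0.5, kappa=-0.2
        assert pp.kappa_score(a, b, universe) == pytest.approx(-0.2, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_symmetry_and_sklearn_cross_check(self, seed):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(seed)
        universe = {f"G{i}" for i in range(30)}
        a = set(rng.choice(sorted(universe), size=10, replace=False))
        b = set(rng.choice(sorted(universe), size=12, replace=False))
        kappa = pp.kappa_score(a, b, universe)
        assert kappa == pytest.approx(pp.kappa_score(b, a, universe), abs=1e-12)
        members = sorted(universe)
        va = [g in a for g in members]
        vb = [g in b for g in members]
        if a != b:
            assert kappa == pytest.approx(cohen_kappa_score(va, vb), abs=1e-12)
        assert -1.0 <= kappa <= 1.0

    def test_kappa_one_only_for_identical_sets(self):
        universe = {f"G{i}" for i in range(10)}
        a = {"G1", "G2", "G3"}
        b = {"G1", "G2", "G4"}
        assert pp.kappa_score(a, b, universe) < 1.0


class TestTermMap:
    def make_enriched(self, terms, universe, query):
        return pp.hypergeometric_enrichment(query, universe, terms)

    def test_single_term_single_group(self):
        universe = {f"G{i}" for i in range(10)}
        terms = [TermGeneSet("T1", "t", frozenset({"G1", "G2"}))]
        enriched = self.make_enriched(terms, universe, {"G1", "G3"})
        tmap = pp.build_term_map(enriched, terms, universe)
        assert tmap.n_terms == 1 and tmap.n_links == 0
        assert len(tmap.groups) == 1

    def test_identical_gene_sets_linked(self):
        universe = {f"G{i}" for i in range(10)}
        genes = frozenset({"G1", "G2", "G3"})
        terms = [TermGeneSet("T1", "a", genes), TermGeneSet("T2", "b", genes)]
        enriched = self.make_enriched(terms, universe, {"G1", "G2"})
        tmap = pp.build_term_map(enriched, terms, universe)
        assert tmap.graph.has_edge("T1", "T2")
        assert tmap.graph.edges["T1", "T2"]["kappa"] == 1.0

    def test_transitive_linkage_forms_one_group(self):
        universe = {f"G{i}" for i in range(12)}
        t1 = TermGeneSet("T1", "a", frozenset({"G1", "G2", "G3", "G4"}))
        t2 = TermGeneSet("T2", "b", frozenset({"G2", "G3", "G4", "G5"}))
        t3 = TermGeneSet("T3", "c", frozenset({"G3", "G4", "G5", "G6"}))
        terms = [t1, t2, t3]
        universe_u = {g.upper() for g in universe}
        k12 = pp.kappa_score(set(t1.genes), set(t2.genes), universe_u)
        k23 = pp.kappa_score(set(t2.genes), set(t3.genes), universe_u)
        k13 = pp.kappa_score(set(t1.genes), set(t3.genes), universe_u)
        assert k12 >= 0.3 and k23 >= 0.3 and k13 < 0.3
        enriched = self.make_enriched(terms, universe, {"G1", "G3", "G5"})
        tmap = pp.build_term_map(enriched, terms, universe)
        assert len(tmap.groups) == 1
        assert tmap.groups[0]["members"] == ["T1", "T2", "T3"]
        assert not tmap.graph.has_edge("T1", "T3")

    def test_raising_threshold_never_adds_edges(self):
        rng = np.random.default_rng(2)
        universe = {f"G{i}" for i in range(30)}
        terms = [
            TermGeneSet(f"T{i}", "t", frozenset(rng.choice(sorted(universe), size=8, replace=False)))
            for i in range(8)
        ]
        query = set(rng.choice(sorted(universe), size=10, replace=False))
        enriched = self.make_enriched(terms, universe, query)
        counts = [
            pp.build_term_map(enriched, terms, universe, threshold=t).n_links
            for t in (0.0, 0.3, 0.6, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_leading_term_has_smallest_adjusted_p(self):
        universe = {f"G{i}" for i in range(20)}
        genes = frozenset({"G1", "G2", "G3", "G4"})
        terms = [TermGeneSet("T1", "a", genes),
                 TermGeneSet("T2", "b", frozenset({"G1", "G2", "G3", "G9"}))]
        enriched = self.make_enriched(terms, universe, {"G1", "G2", "G3", "G4"})
        tmap = pp.build_term_map(enriched, terms, universe)
        by_id = {t.term_id: t for t in enriched}
        for group in tmap.groups:
            leader = group["leading_term"]
            assert all(by_id[leader].adjusted_p <= by_id[m].adjusted_p for m in group["members"])


class TestPlantedEnrichmentRecovery:
    def test_planted_term_most_significant_in_nearly_all_replicates(self):
        """The constructed enrichment signal should dominate background terms."""
        wins = 0
        n_reps = 100
        for seed in range(n_reps):
            cfg = pp.SimulationConfig(n_nodes=250, m=2, n_up=40, n_down=10,
                                      n_terms=20, term_size_range=(10, 25), seed=seed)
            net = pp.generate_parent_network(cfg)
            terms, query = pp.generate_annotations(net, cfg)
            universe = set(net.nodes())
            enriched = pp.hypergeometric_enrichment(query & universe, universe, terms)
            if enriched[0].term_id == "T_PLANTED":
                wins += 1
        assert wins >= 0.95 * n_reps
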