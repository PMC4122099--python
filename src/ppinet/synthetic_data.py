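"""Seeded generators for desk-scale inputs with the structure the analysis assumes.

A preferential-attachment parent network stands in for a curated human PPI
database (scale-free degree distribution, single connected component); a
planted differential-expression profile is exactly recoverable at the
2-fold threshold; localization labels cover the 8 subcellular layers; and a
GMT annotation collection carries one term with planted enrichment in a
designated query set.  Everything is deterministic per seed.

The in-study toy graph — the union of the nine published shortest paths
between the EZR seed protein and the ATF3 transcription factor — is exposed
as :func:`table2_fixture` together with the localization labels of its 14
members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .network_core import PPINetwork, LocalizationTable, TermGeneSet, clean_network

#: default planted DEG census: 199 genes up, 45 down (a 244-gene profile)
DEFAULT_N_UP = 199
DEFAULT_N_DOWN = 45


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic input bundle.

    Fold-change magnitudes of planted DEGs are log-uniform in
    ``fc_range = [2, 8]``; null genes draw strictly inside (1/2, 2) so the
    2-fold filter recovers the plant exactly.  ``layer_probs`` are the
    per-node probabilities of the 8 subcellular layers, upstream first.
    """

    n_nodes: int = 900
    m: int = 3  # preferential-attachment edges per new node
    n_up: int = DEFAULT_N_UP
    n_down: int = DEFAULT_N_DOWN
    fc_range: tuple[float, float] = (2.0, 8.0)
    layer_probs: tuple[float, ...] = (
        0.05,
        0.05,
        0.15,
        0.10,
        0.25,
        0.10,
        0.20,
        0.10,
    )
    n_terms: int = 30
    term_size_range: tuple[int, int] = (10, 40)
    enrichment_factor: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes <= self.m or self.m < 1:
            raise ValueError("need n_nodes > m >= 1")
        if self.n_up < 0 or self.n_down < 0:
            raise ValueError("planted DEG counts must be non-negative")
        if self.n_up + self.n_down > self.n_nodes:
            raise ValueError("more planted DEGs than nodes")
        if abs(sum(self.layer_probs) - 1.0) > 1e-9 or len(self.layer_probs) != 8:
            raise ValueError("layer_probs must be 8 probabilities summing to 1")
        if not (self.fc_range[0] >= 2.0 and self.fc_range[1] >= self.fc_range[0]):
            raise ValueError("planted fold-change range must lie at or above 2")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(self.seed * 1000 + salt)


def _symbol(i: int) -> str:
    return f"G{i:04d}"


def generate_parent_network(cfg: SimulationConfig) -> PPINetwork:
    """Connected preferential-attachment network with gene-symbol node names.

    Barabasi-Albert growth yields the heavy-tailed, hub-dominated degree
    distribution characteristic of curated PPI databases; the output is
    already clean (simple, loop-free, no singletons).
    """
    graph = nx.barabasi_albert_graph(cfg.n_nodes, cfg.m, seed=cfg.seed)
    relabeled = nx.relabel_nodes(graph, {i: _symbol(i) for i in graph.nodes})
    return clean_network(PPINetwork(graph=relabeled, name="synthetic_parent"))


def planted_deg_sets(net: PPINetwork, cfg: SimulationConfig) -> tuple[set[str], set[str]]:
    """The (up, down) gene sets a profile generated from ``cfg`` plants."""
    rng = cfg.rng(salt=1)
    chosen = rng.choice(net.nodes(), size=cfg.n_up + cfg.n_down, replace=False)
    return set(chosen[: cfg.n_up]), set(chosen[cfg.n_up :])


def generate_deg_profile(net: PPINetwork, cfg: SimulationConfig) -> pd.DataFrame:
    """Raw expression rows (symbol, fold_change) with planted DEGs.

    Planted genes receive signed fold changes of magnitude log-uniform in
    ``cfg.fc_range`` (positive for up, negative for down); every other gene
    draws a null value strictly inside (1/2, 2), mapped to the signed linear
    convention, so thresholding at 2 recovers the plant exactly.
    """
    up, down = planted_deg_sets(net, cfg)
    rng = cfg.rng(salt=2)
    lo, hi = np.log(cfg.fc_range[0]), np.log(cfg.fc_range[1])
    rows = []
    for symbol in net.nodes():
        if symbol in up or symbol in down:
            magnitude = float(np.exp(rng.uniform(lo, hi)))
            fc = magnitude if symbol in up else -magnitude
        else:
            null = float(rng.uniform(0.5, 2.0))
            while null in (0.5, 2.0):  # open interval
                null = float(rng.uniform(0.5, 2.0))
            fc = null if null >= 1.0 else -1.0 / null
        rows.append({"symbol": symbol, "fold_change": fc})
    return pd.DataFrame(rows)


#: keyword sets that assign_layer maps back onto each layer index
_LAYER_KEYWORDS: tuple[frozenset[str], ...] = (
    frozenset({"Secreted"}),
    frozenset({"Secreted", "Membrane"}),
    frozenset({"Membrane"}),
    frozenset({"Cytoskeleton", "Cytoplasm"}),
    frozenset({"Cytoplasm"}),
    frozenset({"Cytoplasm", "Nucleus"}),
    frozenset({"Nucleus"}),
    frozenset(),  # unknown location -> Downstream genes
)


def generate_localizations(net: PPINetwork, cfg: SimulationConfig) -> LocalizationTable:
    """Per-node keyword sets consistent with exactly one layer each."""
    rng = cfg.rng(salt=3)
    layers = rng.choice(8, size=net.n_nodes, p=cfg.layer_probs)
    return {
        symbol: set(_LAYER_KEYWORDS[layer])
        for symbol, layer in zip(net.nodes(), layers)
    }


def generate_annotations(
    net: PPINetwork,
    cfg: SimulationConfig,
    query: set[str] | None = None,
) -> tuple[list[TermGeneSet], set[str]]:
    """Flat annotation terms with one term enriched in a designated query.

    The query defaults to the planted DEG set.  Background terms sample
    genes uniformly from the network; the planted term ``T_PLANTED`` draws
    ``enrichment_factor`` times the null expectation of its overlap from the
    query (capped by the term size) and the remainder from outside.  Returns
    the term collection and the query set used.
    """
    rng = cfg.rng(salt=4)
    universe = net.nodes()
    if query is None:
        up, down = planted_deg_sets(net, cfg)
        query = up | down
    query = set(query) & set(universe)
    terms = []
    for i in range(cfg.n_terms):
        size = int(rng.integers(cfg.term_size_range[0], cfg.term_size_range[1] + 1))
        genes = rng.choice(universe, size=size, replace=False)
        terms.append(
            TermGeneSet(
                term_id=f"T{i:03d}", name=f"background term {i}", genes=frozenset(genes)
            )
        )
    size = int(rng.integers(cfg.term_size_range[0], cfg.term_size_range[1] + 1))
    null_overlap = size * len(query) / len(universe)
    n_from_query = min(
        size, len(query), max(1, int(np.ceil(cfg.enrichment_factor * null_overlap)))
    )
    if not query:
        n_from_query = 0
    inside = (
        rng.choice(sorted(query), size=n_from_query, replace=False)
        if n_from_query
        else np.array([], dtype=object)
    )
    outside_pool = sorted(set(universe) - query)
    outside = rng.choice(outside_pool, size=size - n_from_query, replace=False)
    planted = frozenset(inside) | frozenset(outside)
    terms.append(
        TermGeneSet(term_id="T_PLANTED", name="planted enriched term", genes=planted)
    )
    return terms, query


# ---------------------------------------------------------------------------
# in-study toy graph
# ---------------------------------------------------------------------------

#: the nine published shortest paths from EZR to ATF3
TABLE2_PATHS: tuple[tuple[str, ...], ...] = (
    ("EZR", "FAS", "C1ORF103", "ATF3"),
    ("EZR", "CTNNB1", "SMAD3", "ATF3"),
    ("EZR", "ACTB", "SMAD3", "ATF3"),
    ("EZR", "PRKAR2A", "SMAD3", "ATF3"),
    ("EZR", "CTNNB1", "NFKB1", "ATF3"),
    ("EZR", "WWOX", "TP53", "ATF3"),
    ("EZR", "CDK5", "TP53", "ATF3"),
    ("EZR", "PRKCA", "TP53", "ATF3"),
    ("EZR", "PTK2", "TP53", "ATF3"),
)


def table2_fixture() -> PPINetwork:
    """Toy graph whose edges are the consecutive pairs of the nine paths.

    14 proteins, 21 interactions; EZR and ATF3 are not adjacent, so every
    EZR-ATF3 shortest path has three edges.
    """
    graph = nx.Graph()
    for path in TABLE2_PATHS:
        nx.add_path(graph, path)
    return PPINetwork(graph=graph, name="table2_fixture")


#: synthetic but biologically plausible subcellular keywords for the
#: toy-graph members, for exercising the layer stages on the fixture
TABLE2_LOCALIZATIONS: dict[str, set[str]] = {
    "EZR": {"Cytoskeleton", "Cytoplasm"},
    "FAS": {"Membrane"},
    "C1ORF103": {"Nucleus"},
    "ATF3": {"Nucleus"},
    "CTNNB1": {"Cytoplasm", "Nucleus"},
    "SMAD3": {"Cytoplasm", "Nucleus"},
    "ACTB": {"Cytoskeleton", "Cytoplasm"},
    "PRKAR2A": {"Cytoplasm"},
    "NFKB1": {"Cytoplasm", "Nucleus"},
    "WWOX": {"Cytoplasm", "Nucleus"},
    "TP53": {"Cytoplasm", "Nucleus"},
    "CDK5": {"Cytoplasm"},
    "PRKCA": {"Cytoplasm"},
    "PTK2": {"Cytoplasm"},
}
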