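"""DEG-seeded subnetwork constructions from a parent PPI network.

Four constructions mirror the standard knockdown-profile workflow: the
first-neighbor subnetworks of the down-, up- and total DEG sets, a
seed-central "axis" subnetwork tracing seed-neighbor-DEG-neighbor paths, and
the internal DEG-DEG interaction subnetwork.  All of them return cleaned
networks whose edges are a subset of the parent's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx

from .network_core import PPINetwork, clean_network, _normalize_symbol


@dataclass(frozen=True)
class SubnetworkSpec:
    """Declarative description of a subnetwork construction."""

    seed_symbols: frozenset[str]
    mode: str  # one of {"first_neighbor", "axis", "internal"}
    center: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in {"first_neighbor", "axis", "internal"}:
            raise ValueError(f"unknown subnetwork mode: {self.mode!r}")
        if self.mode == "axis" and not self.center:
            raise ValueError("axis mode requires a center symbol")
        if self.mode in {"first_neighbor", "internal"} and not self.seed_symbols:
            raise ValueError(f"{self.mode} mode requires a nonempty seed set")


def _present(parent: PPINetwork, symbols: set[str]) -> set[str]:
    normalized = {_normalize_symbol(s) for s in symbols}
    present = normalized & set(parent.graph.nodes)
    missing = normalized - present
    if missing:
        warnings.warn(
            f"{len(missing)} of {len(normalized)} seed symbols absent from parent "
            f"network (e.g. {sorted(missing)[:5]})"
        )
    return present


def first_neighbor_subnetwork(
    parent: PPINetwork,
    seeds: set[str],
    name: str = "first_neighbor",
    incident_only: bool = False,
) -> PPINetwork:
    """Subnetwork on the seeds plus their direct interaction partners.

    By default the full induced subgraph is extracted, so neighbor-neighbor
    edges are retained (the select-then-extract semantics of interactive
    graph tools).  ``incident_only=True`` keeps only edges incident to a
    seed.
    """
    present = _present(parent, set(seeds))
    if not present:
        if seeds:
            warnings.warn("no seed present in parent network; returning empty network")
        return PPINetwork(graph=nx.Graph(), name=name)
    node_set = set(present)
    for seed in present:
        node_set.update(parent.graph.neighbors(seed))
    if incident_only:
        sub = nx.Graph()
        sub.add_edges_from(
            (a, b)
            for a, b in parent.graph.edges(node_set)
            if a in present or b in present
        )
    else:
        sub = parent.graph.subgraph(node_set).copy()
    return clean_network(PPINetwork(graph=sub, name=name))


def axis_subnetwork(
    parent: PPINetwork,
    center: str,
    degs: set[str],
    name: str = "axis",
) -> PPINetwork:
    """Seed-central subnetwork of center-x-DEG(-y) path patterns.

    Retains every simple path of the templates ``center-x-d`` and
    ``center-x-d-y`` with ``d`` a DEG (``x`` and ``y`` unrestricted), plus
    direct ``center-d`` edges.  Nodes and edges lying on no such path are
    excluded.
    """
    center = _normalize_symbol(center)
    if center not in parent.graph:
        raise KeyError(f"center symbol {center!r} not in parent network")
    deg_set = {_normalize_symbol(d) for d in degs}
    g = parent.graph
    sub = nx.Graph()
    for d in deg_set & set(g.neighbors(center)):
        sub.add_edge(center, d)
    for x in g.neighbors(center):
        if x == center:
            continue
        for d in set(g.neighbors(x)) & deg_set:
            if d == center or d == x:
                continue
            sub.add_edge(center, x)
            sub.add_edge(x, d)
            for y in g.neighbors(d):
                if y not in {center, x, d}:
                    sub.add_edge(d, y)
    return clean_network(PPINetwork(graph=sub, name=name))


def internal_deg_subnetwork(
    parent: PPINetwork, degs: set[str], name: str = "internal"
) -> PPINetwork:
    """Induced subgraph on the DEGs themselves; singletons removed."""
    present = _present(parent, set(degs))
    sub = parent.graph.subgraph(present).copy()
    return clean_network(PPINetwork(graph=sub, name=name))


def build_subnetwork(parent: PPINetwork, spec: SubnetworkSpec) -> PPINetwork:
    if spec.mode == "first_neighbor":
        return first_neighbor_subnetwork(parent, set(spec.seed_symbols))
    if spec.mode == "axis":
        return axis_subnetwork(parent, spec.center, set(spec.seed_symbols))
    return internal_deg_subnetwork(parent, set(spec.seed_symbols))


def summarize(net: PPINetwork, degs: set[str] | None = None) -> dict[str, object]:
    """Node/edge/DEG counts and a connected-component size census.

    The census maps component size to the number of components of that size,
    so two disjoint DEG-DEG edges report ``{2: 2}`` ("two two-DEG
    interactions").
    """
    deg_set = {_normalize_symbol(d) for d in degs} if degs else set()
    census: dict[int, int] = {}
    for component in nx.connected_components(net.graph):
        census[len(component)] = census.get(len(component), 0) + 1
    return {
        "name": net.name,
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "n_degs": len(deg_set & set(net.graph.nodes)),
        "component_census": dict(sorted(census.items())),
    }
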