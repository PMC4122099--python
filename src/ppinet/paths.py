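"""Shortest-path enumeration between two proteins and layer-based filtering.

Signal transduction between a membrane/cytoskeleton protein and a nuclear
transcription factor is assumed to follow the most economical routes through
the interaction network, so all minimum-length simple paths between the two
query proteins are enumerated.  A configurable plausibility filter then
keeps the paths whose intermediate proteins progress monotonically from the
cell periphery toward the nucleus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx

from .network_core import PPINetwork, _normalize_symbol
from .layers import LAYER_INDEX, layer_trace

logger = logging.getLogger("ppinet")


@dataclass(frozen=True)
class ProteinPath:
    """An ordered simple path of gene symbols from source to target."""

    nodes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError(f"path repeats a node: {self.nodes}")

    @property
    def length(self) -> int:
        return len(self.nodes) - 1

    @property
    def intermediates(self) -> tuple[str, ...]:
        return self.nodes[1:-1]

    def arrow(self) -> str:
        return "→".join(self.nodes)

    def trace(self, assignment: dict[str, str]) -> list[int]:
        return layer_trace(list(self.nodes), assignment)


def all_shortest_paths(
    net: PPINetwork, source: str, target: str
) -> list[ProteinPath]:
    """The complete, duplicate-free set of minimum-length simple paths.

    Paths are enumerated by back-tracing the BFS predecessor DAG and returned
    in deterministic lexicographic order of their node symbols.  A
    disconnected pair yields an empty list with a logged notice; an absent
    symbol raises ``KeyError``.
    """
    source, target = _normalize_symbol(source), _normalize_symbol(target)
    for symbol in (source, target):
        if symbol not in net.graph:
            raise KeyError(f"symbol {symbol!r} not in network {net.name!r}")
    if source == target:
        return [ProteinPath(nodes=(source,))]
    try:
        raw = nx.all_shortest_paths(net.graph, source, target)
        paths = sorted({tuple(p) for p in raw})
    except nx.NetworkXNoPath:
        logger.info("%s and %s are disconnected in %s", source, target, net.name)
        return []
    return [ProteinPath(nodes=p) for p in paths]


LayerRuleFn = Callable[[Sequence[int]], bool]


@dataclass(frozen=True)
class LayerRule:
    """Direction rule applied to the layer indices of a path's intermediates.

    The default formalizes "signal flows from cytoplasm to nucleus": the
    intermediate layer indices must be non-decreasing and the final
    intermediate must sit in a nucleus-capable layer (Cytoplasm/Nucleus or
    Nucleus).  Paths without intermediates pass vacuously.  ``predicate``
    replaces the built-in rule entirely when supplied.
    """

    monotone: bool = True
    terminal_layers: frozenset[int] = frozenset(
        {LAYER_INDEX["Cytoplasm/Nucleus"], LAYER_INDEX["Nucleus"]}
    )
    predicate: LayerRuleFn | None = field(default=None, compare=False)

    def accepts(self, intermediate_trace: Sequence[int]) -> bool:
        if self.predicate is not None:
            return self.predicate(intermediate_trace)
        if not intermediate_trace:
            return True
        if self.monotone and any(
            b < a for a, b in zip(intermediate_trace, intermediate_trace[1:])
        ):
            return False
        if self.terminal_layers and intermediate_trace[-1] not in self.terminal_layers:
            return False
        return True


#: rule that keeps every path (identity filter)
PERMISSIVE_RULE = LayerRule(monotone=False, terminal_layers=frozenset())


def filter_paths_by_layers(
    paths: Sequence[ProteinPath],
    assignment: dict[str, str],
    rule: LayerRule = LayerRule(),
) -> list[ProteinPath]:
    """Keep the paths whose intermediate layer trace satisfies the rule."""
    kept = []
    for path in paths:
        trace = [LAYER_INDEX[assignment[n]] for n in path.intermediates]
        if rule.accepts(trace):
            kept.append(path)
    return kept
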