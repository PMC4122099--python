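"""Domain types, file I/O and network cleaning shared by every analysis stage.

The central container is :class:`PPINetwork`, a thin wrapper around a
:mod:`networkx` graph of upper-cased gene symbols.  Freshly read networks are
backed by a multigraph so that duplicate records and self-interactions
survive until :func:`clean_network` collapses them; every downstream stage
requires a cleaned (simple, loop-free, singleton-free) network.

Fold changes follow a single signed linear convention: ``-2.6`` means a
2.6-fold decrease.  Ratio-style inputs (``0.38``) can be converted on read.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger("ppinet")

REGULATION_UP = "up"
REGULATION_DOWN = "down"
REGULATION_UNCHANGED = "unchanged"

#: Default fold-change threshold: |FC| >= 2 calls a gene differentially expressed.
DEFAULT_FOLD_THRESHOLD = 2.0


class ParseError(ValueError):
    """Raised for malformed input records; carries the offending line number."""


def _normalize_symbol(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass(frozen=True)
class Interaction:
    """An undirected protein-protein interaction between two gene symbols."""

    a: str
    b: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", _normalize_symbol(self.a))
        object.__setattr__(self, "b", _normalize_symbol(self.b))

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.a, self.b))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Interaction):
            return NotImplemented
        return self.pair == other.pair

    def __hash__(self) -> int:
        return hash(self.pair)


@dataclass
class PPINetwork:
    """An undirected protein-protein interaction network.

    Parameters
    ----------
    graph
        ``networkx.Graph`` (cleaned) or ``networkx.MultiGraph`` (raw, as
        read from disk).  Node names are upper-cased gene symbols; node
        attributes in use are ``regulation``, ``fold_change``,
        ``localizations``, ``layer`` and ``score``.
    name
        Free-text label used in reports.
    """

    graph: nx.Graph
    name: str = "network"

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def is_clean(self) -> bool:
        if self.graph.is_multigraph():
            return False
        if nx.number_of_selfloops(self.graph) > 0:
            return False
        return all(d > 0 for _, d in self.graph.degree())

    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edges(self) -> set[Interaction]:
        return {Interaction(a, b) for a, b in self.graph.edges()}

    def has_node(self, symbol: str) -> bool:
        return _normalize_symbol(symbol) in self.graph

    def set_node_attribute(self, key: str, values: Mapping[str, object]) -> None:
        nx.set_node_attributes(
            self.graph, {_normalize_symbol(s): v for s, v in values.items()}, key
        )

    def get_node_attribute(self, key: str) -> dict[str, object]:
        return dict(nx.get_node_attributes(self.graph, key))

    def summary(self) -> str:
        return f"{self.name}: {self.n_nodes} nodes, {self.n_edges} edges"


@dataclass
class DEGTable:
    """Differentially expressed genes with signed linear fold changes."""

    frame: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["symbol", "fold_change", "regulation"]
        )
    )

    def __post_init__(self) -> None:
        if self.frame["symbol"].duplicated().any():
            dupes = sorted(self.frame.loc[self.frame["symbol"].duplicated(), "symbol"])
            raise ValueError(f"duplicate gene symbols in DEG table: {dupes}")

    @property
    def symbols(self) -> set[str]:
        return set(self.frame["symbol"])

    @property
    def up(self) -> set[str]:
        return set(self.frame.loc[self.frame["regulation"] == REGULATION_UP, "symbol"])

    @property
    def down(self) -> set[str]:
        return set(
            self.frame.loc[self.frame["regulation"] == REGULATION_DOWN, "symbol"]
        )

    def __len__(self) -> int:
        return len(self.frame)


#: mapping gene symbol -> set of subcellular-location keywords
LocalizationTable = dict[str, set[str]]


@dataclass(frozen=True)
class TermGeneSet:
    """A flat annotation term (e.g. a GO Biological Process) with its gene set."""

    term_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"term {self.term_id} has an empty gene set")
        object.__setattr__(
            self, "genes", frozenset(_normalize_symbol(g) for g in self.genes)
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_edge_list(
    path: str | Path,
    format: str = "tsv",
    hprd_columns: tuple[int, int] = (0, 3),
    name: str | None = None,
) -> PPINetwork:
    """Read an edge list into a raw (uncleaned) network.

    Supported formats: ``tsv`` (two or more tab/space separated columns, the
    first two naming the interactors), ``sif`` (``node relation node``) and
    ``hprd`` (tab-delimited HPRD flat-file export; the interactor-symbol
    columns default to 0 and 3 and are configurable via ``hprd_columns``).

    Duplicate records and self-interactions are preserved until
    :func:`clean_network`; symbols are upper-cased and whitespace-stripped.
    """
    path = Path(path)
    if format not in {"tsv", "sif", "hprd"}:
        raise ValueError(f"unknown edge-list format: {format!r}")
    graph = nx.MultiGraph()
    n_records = 0
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if format == "sif":
                parts = line.split()
                if len(parts) < 3:
                    raise ParseError(
                        f"{path}:{lineno}: SIF record needs 'node relation node'"
                    )
                a, b = parts[0], parts[2]
            elif format == "hprd":
                parts = line.split("\t")
                i, j = hprd_columns
                if len(parts) <= max(i, j):
                    raise ParseError(
                        f"{path}:{lineno}: expected at least {max(i, j) + 1} columns"
                    )
                a, b = parts[i], parts[j]
            else:
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) < 2:
                    raise ParseError(f"{path}:{lineno}: expected two interactor columns")
                a, b = parts[0], parts[1]
            a, b = _normalize_symbol(a), _normalize_symbol(b)
            if not a or not b:
                raise ParseError(f"{path}:{lineno}: empty interactor symbol")
            graph.add_edge(a, b)
            n_records += 1
    if n_records == 0:
        warnings.warn(f"{path}: empty edge list, returning empty network")
    return PPINetwork(graph=graph, name=name or path.stem)


def clean_network(net: PPINetwork) -> PPINetwork:
    """Remove self-interactions, duplicate edges and singleton nodes.

    Idempotent; the returned edge set is a subset of the input's.  Collapsed
    multi-edges are counted in the log.
    """
    simple = nx.Graph()
    simple.add_nodes_from(net.graph.nodes(data=True))
    n_multi = 0
    for a, b in net.graph.edges():
        if a == b:
            continue
        if simple.has_edge(a, b):
            n_multi += 1
            continue
        simple.add_edge(a, b)
    if n_multi:
        logger.info("%s: collapsed %d duplicate edge record(s)", net.name, n_multi)
    simple.remove_nodes_from([n for n, d in simple.degree() if d == 0])
    return PPINetwork(graph=simple, name=net.name)


def deg_filter(
    rows: pd.DataFrame | Iterable[tuple[str, float]],
    threshold: float = DEFAULT_FOLD_THRESHOLD,
    ratio_style: bool = False,
) -> DEGTable:
    """Call differentially expressed genes at a linear fold-change threshold.

    ``rows`` is a DataFrame with ``symbol`` and ``fold_change`` columns or an
    iterable of ``(symbol, fold_change)`` pairs.  A row is kept when
    ``|fold_change| >= threshold`` (inclusive boundary) and assigned
    ``regulation`` by sign.  With ``ratio_style=True``, values ``v`` in (0, 1)
    are first converted to the signed convention ``-1/v``.

    Rows with a missing fold change are skipped with a logged warning.
    """
    if isinstance(rows, pd.DataFrame):
        records = list(rows[["symbol", "fold_change"]].itertuples(index=False))
    else:
        records = list(rows)
    kept: list[dict[str, object]] = []
    for symbol, fc in records:
        symbol = _normalize_symbol(str(symbol))
        if fc is None or pd.isna(fc):
            logger.warning("deg_filter: %s has no fold change, row skipped", symbol)
            continue
        fc = float(fc)
        if ratio_style and 0 < fc < 1:
            fc = -1.0 / fc
        if abs(fc) < threshold:
            continue
        kept.append(
            {
                "symbol": symbol,
                "fold_change": fc,
                "regulation": REGULATION_UP if fc > 0 else REGULATION_DOWN,
            }
        )
    frame = pd.DataFrame(kept, columns=["symbol", "fold_change", "regulation"])
    return DEGTable(frame=frame.sort_values("symbol", ignore_index=True))


def read_deg_table(
    path: str | Path,
    threshold: float = DEFAULT_FOLD_THRESHOLD,
    ratio_style: bool = False,
) -> DEGTable:
    """Read a TSV of (symbol, fold_change) rows and apply :func:`deg_filter`."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    frame.columns = [c.strip().lower() for c in frame.columns]
    if "symbol" not in frame.columns or "fold_change" not in frame.columns:
        frame = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=["symbol", "fold_change"]
        )
    return deg_filter(frame, threshold=threshold, ratio_style=ratio_style)


def read_gmt(path: str | Path) -> list[TermGeneSet]:
    """Parse a GMT file (``term<TAB>description<TAB>gene...`` per line).

    Terms with no genes are skipped with a warning.
    """
    terms: list[TermGeneSet] = []
    with Path(path).open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not any(g.strip() for g in parts[2:]):
                warnings.warn(f"{path}:{lineno}: term with no genes skipped")
                continue
            genes = frozenset(g for g in (p.strip() for p in parts[2:]) if g)
            terms.append(TermGeneSet(term_id=parts[0], name=parts[1], genes=genes))
    return terms


def write_gmt(terms: Sequence[TermGeneSet], path: str | Path) -> None:
    with Path(path).open("w") as handle:
        for term in terms:
            genes = "\t".join(sorted(term.genes))
            handle.write(f"{term.term_id}\t{term.name}\t{genes}\n")


def read_localizations(path: str | Path, delimiter: str = ";") -> LocalizationTable:
    """Read a two-column TSV ``symbol<TAB>keyword;keyword;...``.

    An empty second column yields an empty keyword set (unknown location).
    """
    table: LocalizationTable = {}
    with Path(path).open() as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            symbol = _normalize_symbol(parts[0])
            raw = parts[1] if len(parts) > 1 else ""
            keywords = {k.strip() for k in raw.split(delimiter) if k.strip()}
            table[symbol] = keywords
    return table


def write_localizations(table: LocalizationTable, path: str | Path) -> None:
    with Path(path).open("w") as handle:
        for symbol in sorted(table):
            handle.write(f"{symbol}\t{';'.join(sorted(table[symbol]))}\n")


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

#: node attributes round-tripped through the sidecar TSV
_SIDECAR_KEYS = ("regulation", "fold_change", "layer", "score")


def write_network(
    net: PPINetwork, path: str | Path, format: str = "tsv", attributes: bool = True
) -> None:
    """Write a network as TSV edge list, SIF or GraphML.

    TSV and SIF cannot carry node attributes, so the attributes in
    ``_SIDECAR_KEYS`` are written to a sidecar ``<path>.attrs.tsv``
    (``symbol<TAB>key<TAB>value``); GraphML stores them inline.
    """
    path = Path(path)
    if format == "graphml":
        export = nx.Graph() if not net.graph.is_multigraph() else nx.MultiGraph()
        for node, data in net.graph.nodes(data=True):
            clean = {
                k: v
                for k, v in data.items()
                if v is not None and not isinstance(v, (set, frozenset))
            }
            export.add_node(node, **clean)
        export.add_edges_from(net.graph.edges())
        nx.write_graphml(export, path)
        return
    with path.open("w") as handle:
        for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges()):
            if format == "sif":
                handle.write(f"{a}\tpp\t{b}\n")
            elif format == "tsv":
                handle.write(f"{a}\t{b}\n")
            else:
                raise ValueError(f"unknown network format: {format!r}")
    if attributes:
        write_node_attributes(net, path.with_suffix(path.suffix + ".attrs.tsv"))


def write_node_attributes(net: PPINetwork, path: str | Path) -> None:
    with Path(path).open("w") as handle:
        for node in sorted(net.graph.nodes):
            data = net.graph.nodes[node]
            for key in _SIDECAR_KEYS:
                if data.get(key) is not None:
                    handle.write(f"{node}\t{key}\t{data[key]}\n")


def read_node_attributes(net: PPINetwork, path: str | Path) -> PPINetwork:
    """Load a sidecar attribute TSV onto an existing network, in place."""
    with Path(path).open() as handle:
        for line in handle:
            if not line.strip():
                continue
            symbol, key, value = line.rstrip("\n").split("\t")
            symbol = _normalize_symbol(symbol)
            if symbol not in net.graph:
                continue
            if key in {"fold_change", "score"}:
                net.graph.nodes[symbol][key] = float(value)
            else:
                net.graph.nodes[symbol][key] = value
    return net


def read_graphml(path: str | Path, name: str | None = None) -> PPINetwork:
    graph = nx.read_graphml(Path(path))
    relabeled = nx.relabel_nodes(graph, {n: _normalize_symbol(str(n)) for n in graph})
    return PPINetwork(graph=relabeled, name=name or Path(path).stem)
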