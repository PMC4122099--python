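"""Subcellular-layer stratification of a PPI network.

Proteins are assigned to one of 8 ordered compartment layers running from
the extracellular space down to the nucleus, with proteins of unknown
location collected in a final "Downstream genes" layer.  The layered layout
places each node in the horizontal band of its layer, giving the
pathway-like top-to-bottom rendering used for signal-flow interpretation.
"""

from __future__ import annotations

import logging

import numpy as np

from .network_core import PPINetwork, LocalizationTable, _normalize_symbol

logger = logging.getLogger("ppinet")

#: the 8 ordered layers, most upstream (extracellular) first
LAYER_ORDER: tuple[str, ...] = (
    "Secreted",
    "Secreted/Membrane",
    "Membrane",
    "Cytoskeleton/Cytoplasm",
    "Cytoplasm",
    "Cytoplasm/Nucleus",
    "Nucleus",
    "Downstream genes",
)

LAYER_INDEX: dict[str, int] = {name: i for i, name in enumerate(LAYER_ORDER)}

#: controlled vocabulary of canonical location keywords
CANONICAL_KEYWORDS = ("Secreted", "Membrane", "Cytoskeleton", "Cytoplasm", "Nucleus")

#: home layer of each single canonical keyword
_HOME_LAYER = {
    "Secreted": 0,
    "Membrane": 2,
    "Cytoskeleton": 3,
    "Cytoplasm": 4,
    "Nucleus": 6,
}

#: free-text synonyms mapped onto the controlled vocabulary (lower-cased keys)
KEYWORD_SYNONYMS: dict[str, str] = {
    "secreted": "Secreted",
    "extracellular": "Secreted",
    "extracellular space": "Secreted",
    "extracellular matrix": "Secreted",
    "membrane": "Membrane",
    "cell membrane": "Membrane",
    "plasma membrane": "Membrane",
    "cell surface": "Membrane",
    "cytoskeleton": "Cytoskeleton",
    "actin cytoskeleton": "Cytoskeleton",
    "cell cortex": "Cytoskeleton",
    "cytoplasm": "Cytoplasm",
    "cytosol": "Cytoplasm",
    "nucleus": "Nucleus",
    "nucleoplasm": "Nucleus",
    "nucleolus": "Nucleus",
}


def canonicalize_keywords(keywords: set[str]) -> set[str]:
    """Map free-text location keywords onto the controlled vocabulary.

    Unrecognized keywords are logged and ignored.
    """
    canonical: set[str] = set()
    for keyword in keywords:
        mapped = KEYWORD_SYNONYMS.get(keyword.strip().lower())
        if mapped is None:
            logger.debug("unrecognized localization keyword ignored: %r", keyword)
        else:
            canonical.add(mapped)
    return canonical


def assign_layer(localizations: set[str]) -> str:
    """Deterministically map a keyword set to one of the 8 layers.

    Combination rules, applied in order: no recognized keyword -> Downstream
    genes; Secreted+Membrane -> Secreted/Membrane; any set containing
    Cytoskeleton -> Cytoskeleton/Cytoplasm; Cytoplasm+Nucleus ->
    Cytoplasm/Nucleus; a single keyword -> its own layer; any other
    conflicting combination resolves to the most-upstream (lowest-index)
    matching layer, logged.  Total and order-independent in the input set.
    """
    canonical = canonicalize_keywords(localizations)
    if not canonical:
        return "Downstream genes"
    if {"Secreted", "Membrane"} <= canonical:
        return "Secreted/Membrane"
    if "Cytoskeleton" in canonical:
        return "Cytoskeleton/Cytoplasm"
    if {"Cytoplasm", "Nucleus"} <= canonical:
        return "Cytoplasm/Nucleus"
    if len(canonical) == 1:
        return LAYER_ORDER[_HOME_LAYER[next(iter(canonical))]]
    upstream = min(_HOME_LAYER[k] for k in canonical)
    logger.info(
        "conflicting localizations %s resolved upstream to %s",
        sorted(canonical),
        LAYER_ORDER[upstream],
    )
    return LAYER_ORDER[upstream]


def assign_layers(
    net: PPINetwork, localizations: LocalizationTable
) -> dict[str, str]:
    """Assign every network node a layer; unknown symbols go to Downstream genes.

    The assignment is also stored on the network as the ``layer`` node
    attribute so that it round-trips through GraphML export.
    """
    assignment = {
        node: assign_layer(localizations.get(node, set())) for node in net.graph.nodes
    }
    net.set_node_attribute("layer", assignment)
    return assignment


def layered_layout(
    net: PPINetwork,
    assignment: dict[str, str],
    seed: int = 0,
    band_height: float = 1.0,
) -> dict[str, tuple[float, float]]:
    """Per-node (x, y) coordinates with y fixed by layer band.

    Nodes of one layer share the band's y (layer 0 on top); x positions are
    distinct within a band, centred around 0, with the within-band order
    seeded-shuffled for reproducible but unclustered placement.
    """
    missing = [n for n in net.graph.nodes if n not in assignment]
    if missing:
        raise ValueError(f"nodes without a layer assignment: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    coords: dict[str, tuple[float, float]] = {}
    for layer_name in LAYER_ORDER:
        members = sorted(n for n in net.graph.nodes if assignment[n] == layer_name)
        if not members:
            continue
        order = rng.permutation(len(members))
        y = -LAYER_INDEX[layer_name] * band_height
        for slot, idx in enumerate(order):
            x = slot - (len(members) - 1) / 2.0
            coords[members[idx]] = (float(x), float(y))
    return coords


def layer_trace(path_nodes: list[str], assignment: dict[str, str]) -> list[int]:
    """Ordered layer indices along a path of gene symbols."""
    return [LAYER_INDEX[assignment[_normalize_symbol(n)]] for n in path_nodes]
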