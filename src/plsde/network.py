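"""Interaction subnetwork of selected genes and degree-based hub calling.

A node's degree is its number of distinct interaction partners, counted on
the subnetwork induced by the selected genes (not the full background
graph). Hubs are nodes whose degree meets the cutoff; the default cutoff
of 10 is inclusive, which is the reading that keeps a degree-10 node a hub.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import networkx as nx

from .exceptions import InvalidParameterError

__all__ = ["build_subnetwork", "compute_degrees", "select_hubs"]


def build_subnetwork(selected_genes: Iterable[str], graph: nx.Graph) -> nx.Graph:
    """Induced subgraph on the selected genes present in ``graph``.

    Selected genes absent from the background graph are skipped; present
    genes that lose all their edges remain as degree-0 nodes.
    """
    selected = {str(g).upper() for g in selected_genes}
    nodes = [v for v in graph.nodes if str(v).upper() in selected]
    return nx.Graph(graph.subgraph(nodes))


def compute_degrees(graph: nx.Graph) -> dict[str, int]:
    """Degree (distinct-neighbor count) per node."""
    return {v: int(d) for v, d in graph.degree()}


def select_hubs(degrees: Mapping[str, int], cutoff: int = 10,
                strict: bool = False) -> list[tuple[str, int]]:
    """Hub nodes ordered by descending degree then symbol.

    ``strict=False`` (default) keeps nodes with degree >= cutoff;
    ``strict=True`` applies a literal "over the cutoff" (> cutoff) rule.
    """
    if cutoff < 1:
        raise InvalidParameterError("cutoff must be >= 1")
    keep = ((lambda d: d > cutoff) if strict else (lambda d: d >= cutoff))
    hubs = [(str(v), int(d)) for v, d in degrees.items() if keep(int(d))]
    return sorted(hubs, key=lambda vd: (-vd[1], vd[0]))
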