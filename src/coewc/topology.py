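"""Structural graph metrics on PPI networks.

Degree, local clustering coefficient (Watts–Strogatz), edge clustering
coefficient and common-neighbour counts.  Every metric is total: denominators
that would vanish (leaf nodes, bridge edges) yield the value 0 rather than an
error, so degenerate proteins flow through downstream scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import networkx as nx

from .io_formats import PPINetwork

__all__ = [
    "NodeMetric",
    "EdgeMetric",
    "degree",
    "clustering_coefficient",
    "edge_clustering_coefficient",
    "common_neighbors",
]

EccVariant = Literal["standard", "plus-one"]


@dataclass(frozen=True)
class NodeMetric:
    """A real value per node of the network it was computed on."""

    name: str
    values: dict[str, float]

    def __getitem__(self, u: str) -> float:
        return self.values[u]


@dataclass(frozen=True)
class EdgeMetric:
    """A real value per edge, symmetric in the endpoint pair."""

    name: str
    values: dict[tuple[str, str], float]

    def __getitem__(self, edge: tuple[str, str]) -> float:
        u, v = edge
        return self.values[(u, v) if u <= v else (v, u)]


def degree(net: PPINetwork) -> NodeMetric:
    """Number of distinct interaction partners of each protein."""
    return NodeMetric("degree", {u: float(d) for u, d in net.graph.degree()})


def clustering_coefficient(net: PPINetwork) -> NodeMetric:
    """Local clustering coefficient CC(u) = 2·e(N(u)) / (k_u·(k_u−1)).

    e(N(u)) is the number of edges among u's neighbours.  CC(u) = 0 when
    k_u ≤ 1 (the conventional value for the undefined ratio).
    """
    return NodeMetric("CC", dict(nx.clustering(net.graph)))


def common_neighbors(net: PPINetwork, u: str, v: str) -> int:
    """|N(u) ∩ N(v)|, never counting u or v themselves."""
    shared = net.neighbors(u) & net.neighbors(v)
    shared.discard(u)
    shared.discard(v)
    return len(shared)


def edge_clustering_coefficient(
    net: PPINetwork, variant: EccVariant = "standard"
) -> EdgeMetric:
    """Edge clustering coefficient for every interaction.

    ``standard``: ECC(u,v) = |N(u) ∩ N(v)| / min(k_u − 1, k_v − 1), the
    fraction of possible triangles through the edge that are realised; 0 when
    the denominator vanishes (an endpoint is a leaf).  ``plus-one`` adds 1 to
    the shared-neighbour count (Radicchi et al.'s convention), which breaks
    ties among triangle-free edges but leaves the [0, 1] range of standard
    ECC, so it is not the default.
    """
    g = net.graph
    values: dict[tuple[str, str], float] = {}
    for u, v in g.edges:
        denom = min(g.degree(u), g.degree(v)) - 1
        if denom <= 0:
            ecc = 0.0
        else:
            z = common_neighbors(net, u, v)
            if variant == "plus-one":
                z += 1
            ecc = z / denom
        values[(u, v) if u <= v else (v, u)] = ecc
    return EdgeMetric("ECC", values)
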