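"""The six protein-ranking measures: DC, CC, SoECC, SoPCC, PeC and CoEWC.

CoEWC (co-expression weighted by clustering coefficient) scores a protein u as

    CoEWC(u) = Σ_{v ∈ N(u)} PCC(u, v) · CC(v)

the sum over u's interaction partners of the expression-profile Pearson
correlation with that partner, weighted by the *partner's* local clustering
coefficient.  Weighting by the neighbour's CC — not the protein's own — is
what lets the measure reward both party hubs (whose neighbours sit in the
hub's own dense module) and date hubs (whose neighbours each sit in some
dense module, just not a shared one), while annihilating star-like hubs whose
partners are mutually disconnected singletons.

The comparison measures:

* DC(u)    = degree
* CC(u)    = local clustering coefficient as a ranking score
* SoECC(u) = Σ_{v∈N(u)} ECC(u, v)
* SoPCC(u) = Σ_{v∈N(u)} PCC(u, v)
* PeC(u)   = Σ_{v∈N(u)} ECC(u, v) · PCC(u, v)

All produce a :class:`ScoreTable` with a deterministic ranking: descending
score, ties broken by ascending protein ID.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .coexpression import PairCorrelation, edge_pcc
from .io_formats import ExpressionMatrix, PPINetwork
from .topology import (
    EccVariant,
    NodeMetric,
    clustering_coefficient,
    degree,
    edge_clustering_coefficient,
)

__all__ = [
    "ScoreTable",
    "MEASURES",
    "dc",
    "cc_measure",
    "soecc",
    "sopcc",
    "pec",
    "coewc",
    "combine_coexpression_clustering",
    "compute_measure",
]


@dataclass(frozen=True)
class ScoreTable:
    """Per-protein values for one centrality measure, with a fixed ranking.

    The ranking covers exactly the scored node set, sorted by value
    descending with ties broken by ascending protein ID — every top-k
    evaluation must be reproducible, so ordering is never left to hash order.
    """

    measure: str
    values: dict[str, float]
    ranking: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        order = sorted(self.values, key=lambda pid: (-self.values[pid], pid))
        object.__setattr__(self, "ranking", tuple(order))

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, pid: str) -> float:
        return self.values[pid]

    def top(self, k: int) -> tuple[str, ...]:
        """The first k proteins of the ranking."""
        if not 1 <= k <= len(self.ranking):
            raise ValueError(f"k={k} out of range 1..{len(self.ranking)}")
        return self.ranking[:k]


# ---------------------------------------------------------------------------
# Topology-only measures
# ---------------------------------------------------------------------------

def dc(net: PPINetwork) -> ScoreTable:
    """Degree centrality."""
    return ScoreTable("DC", dict(degree(net).values))


def cc_measure(net: PPINetwork) -> ScoreTable:
    """Local clustering coefficient used directly as a ranking score."""
    return ScoreTable("CC", dict(clustering_coefficient(net).values))


def soecc(net: PPINetwork, ecc_variant: EccVariant = "standard") -> ScoreTable:
    """Sum of edge clustering coefficients over a protein's interactions."""
    ecc = edge_clustering_coefficient(net, variant=ecc_variant)
    values = {
        u: sum(ecc[(u, v)] for v in net.neighbors(u)) for u in net.nodes
    }
    return ScoreTable("SoECC", values)


# ---------------------------------------------------------------------------
# Expression-integrating measures
# ---------------------------------------------------------------------------

def sopcc(net: PPINetwork, expr: ExpressionMatrix) -> ScoreTable:
    """Sum of PCC between a protein and each of its neighbours."""
    corr = edge_pcc(net, expr)
    values = {
        u: sum(corr[(u, v)] for v in net.neighbors(u)) for u in net.nodes
    }
    return ScoreTable("SoPCC", values)


def pec(
    net: PPINetwork,
    expr: ExpressionMatrix,
    ecc_variant: EccVariant = "standard",
) -> ScoreTable:
    """Sum over incident edges of ECC × PCC (probability the pair is both
    co-clustered and co-expressed)."""
    ecc = edge_clustering_coefficient(net, variant=ecc_variant)
    corr = edge_pcc(net, expr)
    values = {
        u: sum(ecc[(u, v)] * corr[(u, v)] for v in net.neighbors(u))
        for u in net.nodes
    }
    return ScoreTable("PeC", values)


def combine_coexpression_clustering(
    net: PPINetwork,
    corr: PairCorrelation | Mapping[tuple[str, str], float],
    neighbor_cc: NodeMetric | Mapping[str, float],
) -> ScoreTable:
    """Evaluate CoEWC(u) = Σ_{v∈N(u)} PCC(u,v)·CC(v) from its two factors.

    The score-combination step, separated from the computation of the factors
    so that externally supplied per-edge correlations and per-node clustering
    coefficients (e.g. values reported for a published network) can be pushed
    through the same code path as internally computed ones.
    """
    if isinstance(corr, PairCorrelation):
        corr_map = corr.values
    else:
        corr_map = {((u, v) if u <= v else (v, u)): r for (u, v), r in corr.items()}
    cc_map = neighbor_cc.values if isinstance(neighbor_cc, NodeMetric) else neighbor_cc

    def edge_key(u: str, v: str) -> tuple[str, str]:
        return (u, v) if u <= v else (v, u)

    values = {
        u: sum(corr_map[edge_key(u, v)] * cc_map[v] for v in net.neighbors(u))
        for u in net.nodes
    }
    return ScoreTable("CoEWC", values)


def coewc(net: PPINetwork, expr: ExpressionMatrix) -> ScoreTable:
    """Co-expression weighted by the neighbour's clustering coefficient.

    Isolated proteins score 0 (empty sum), never NaN.
    """
    corr = edge_pcc(net, expr)
    cc = clustering_coefficient(net)
    return combine_coexpression_clustering(net, corr, cc)


# ---------------------------------------------------------------------------
# Dispatch by measure name (used by the CLI)
# ---------------------------------------------------------------------------

MEASURES: tuple[str, ...] = ("dc", "cc", "soecc", "sopcc", "pec", "coewc")

_NEEDS_EXPRESSION = {"sopcc", "pec", "coewc"}


def compute_measure(
    name: str,
    net: PPINetwork,
    expr: ExpressionMatrix | None = None,
    ecc_variant: EccVariant = "standard",
) -> ScoreTable:
    """Compute one measure by its lower-case name."""
    name = name.lower()
    if name not in MEASURES:
        raise ValueError(f"unknown measure {name!r}; choose from {MEASURES}")
    if name in _NEEDS_EXPRESSION and expr is None:
        raise ValueError(f"measure {name!r} requires an expression matrix")
    if name == "dc":
        return dc(net)
    if name == "cc":
        return cc_measure(net)
    if name == "soecc":
        return soecc(net, ecc_variant)
    if name == "sopcc":
        return sopcc(net, expr)
    if name == "pec":
        return pec(net, expr, ecc_variant)
    return coewc(net, expr)
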