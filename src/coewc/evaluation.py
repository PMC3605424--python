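"""Ranking evaluation against a reference set of essential proteins.

Top-k true-positive counts, jackknife cumulative curves with trapezoidal AUC,
seeded random-ranking baselines, between-measure overlap/difference analysis,
and rank-based reference values.  Proteins not in the reference list are
non-essential by definition; there is no "unknown" class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .centrality import ScoreTable
from .io_formats import EssentialSet, PPINetwork

__all__ = [
    "TopKResult",
    "JackknifeCurve",
    "OverlapReport",
    "top_k",
    "jackknife",
    "random_baseline",
    "overlap_analysis",
    "reference_value",
]


@dataclass(frozen=True)
class TopKResult:
    measure: str
    k: int
    predicted: tuple[str, ...]
    true_positive_count: int

    @property
    def precision(self) -> float:
        return self.true_positive_count / self.k


@dataclass(frozen=True)
class JackknifeCurve:
    """Cumulative essential counts along a ranking, ranks 1..max_rank.

    ``cumulative[r-1]`` is the number of essential proteins among the top r;
    the sequence is nondecreasing with unit increments.  ``auc`` is the
    trapezoidal area under the step curve over the rank axis 1..max_rank.
    """

    label: str
    cumulative: tuple[int, ...]

    @property
    def auc(self) -> float:
        if len(self.cumulative) < 2:
            return 0.0
        return float(np.trapezoid(self.cumulative))


def _curve(label: str, ranking, ess: EssentialSet, max_rank: int) -> JackknifeCurve:
    cum = []
    count = 0
    for pid in ranking[:max_rank]:
        count += pid in ess
        cum.append(count)
    return JackknifeCurve(label=label, cumulative=tuple(cum))


def top_k(table: ScoreTable, ess: EssentialSet, k: int) -> TopKResult:
    """Count reference essential proteins among the top k of a ranking."""
    predicted = table.top(k)  # validates 1 <= k <= len
    tp = sum(pid in ess for pid in predicted)
    return TopKResult(
        measure=table.measure, k=k, predicted=predicted, true_positive_count=tp
    )


def jackknife(table: ScoreTable, ess: EssentialSet, max_rank: int) -> JackknifeCurve:
    """Cumulative essential-protein counts along the ranking's top max_rank."""
    if not 1 <= max_rank <= len(table.ranking):
        raise ValueError(
            f"max_rank={max_rank} out of range 1..{len(table.ranking)}"
        )
    return _curve(table.measure, table.ranking, ess, max_rank)


def random_baseline(
    net: PPINetwork,
    ess: EssentialSet,
    max_rank: int,
    n_shuffles: int = 10,
    seed: int = 0,
) -> list[JackknifeCurve]:
    """Jackknife curves for uniformly shuffled protein orderings.

    Each curve is built from an independent uniform permutation of the node
    list; the whole batch is reproducible from ``seed``.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    nodes = sorted(net.nodes)
    if not 1 <= max_rank <= len(nodes):
        raise ValueError(f"max_rank={max_rank} out of range 1..{len(nodes)}")
    rng = np.random.default_rng(seed)
    curves = []
    for i in range(n_shuffles):
        order = [nodes[j] for j in rng.permutation(len(nodes))]
        curves.append(_curve(f"random-{i + 1}", order, ess, max_rank))
    return curves


@dataclass(frozen=True)
class OverlapReport:
    """Set relations between the top-k predictions of two measures."""

    measure_a: str
    measure_b: str
    k: int
    common: frozenset[str]
    only_a: frozenset[str]
    only_b: frozenset[str]
    essential_fraction_only_a: float
    essential_fraction_only_b: float

    @property
    def common_count(self) -> int:
        return len(self.common)


def overlap_analysis(
    table_a: ScoreTable, table_b: ScoreTable, ess: EssentialSet, k: int
) -> OverlapReport:
    """Overlap/difference of two top-k sets plus essential fractions of the
    measure-specific (symmetric-difference) predictions."""
    set_a = set(table_a.top(k))
    set_b = set(table_b.top(k))
    only_a = set_a - set_b
    only_b = set_b - set_a

    def frac(s: set[str]) -> float:
        return sum(p in ess for p in s) / len(s) if s else 0.0

    return OverlapReport(
        measure_a=table_a.measure,
        measure_b=table_b.measure,
        k=k,
        common=frozenset(set_a & set_b),
        only_a=frozenset(only_a),
        only_b=frozenset(only_b),
        essential_fraction_only_a=frac(only_a),
        essential_fraction_only_b=frac(only_b),
    )


def reference_value(table: ScoreTable, rank: int) -> float:
    """Score of the rank-th protein in descending order (1-based).

    Used to place an absolute threshold on otherwise incomparable measure
    scales, e.g. the score of the protein at the rank equal to the number of
    reference essential proteins.
    """
    if not 1 <= rank <= len(table.ranking):
        raise ValueError(f"rank={rank} out of range 1..{len(table.ranking)}")
    return table.values[table.ranking[rank - 1]]
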