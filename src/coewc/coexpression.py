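"""Pearson correlation of expression profiles for interacting protein pairs.

The probability that two interacting proteins are co-expressed is summarised
by the Pearson correlation coefficient (PCC) of their expression profiles
across samples.  A profile with zero variance — in particular the all-zero
vector standing in for a protein with no measured transcript — has PCC 0 with
every partner; this is the only convention that keeps such proteins scoreable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ExpressionMatrix, PPINetwork

__all__ = ["PairCorrelation", "pcc", "edge_pcc"]


@dataclass(frozen=True)
class PairCorrelation:
    """PCC per unordered protein pair; symmetric, values in [−1, 1]."""

    values: dict[tuple[str, str], float]

    def __getitem__(self, edge: tuple[str, str]) -> float:
        u, v = edge
        return self.values[(u, v) if u <= v else (v, u)]


def pcc(x, y) -> float:
    """Sample Pearson correlation of two expression vectors.

    The s vs s−1 normalisation of mean and standard deviation cancels in the
    ratio, so the centred-dot-product form is used directly.  Returns 0.0 if
    either vector has zero standard deviation.  Requires equal lengths ≥ 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(
            f"expression vectors must be 1-D of equal length, "
            f"got shapes {x.shape} and {y.shape}"
        )
    if x.size < 2:
        raise ValueError("need at least 2 samples to correlate")
    xc = x - x.mean()
    yc = y - y.mean()
    nx_ = float(np.dot(xc, xc))
    ny_ = float(np.dot(yc, yc))
    if nx_ == 0.0 or ny_ == 0.0:
        return 0.0
    r = float(np.dot(xc, yc)) / np.sqrt(nx_ * ny_)
    # clamp floating-point excursions just past ±1
    return max(-1.0, min(1.0, r))


def edge_pcc(net: PPINetwork, expr: ExpressionMatrix) -> PairCorrelation:
    """PCC for every interaction in the network.

    Proteins absent from the expression matrix contribute the zero vector and
    hence PCC 0 on all their edges.
    """
    values: dict[tuple[str, str], float] = {}
    cache: dict[str, np.ndarray] = {}

    def prof(pid: str) -> np.ndarray:
        if pid not in cache:
            cache[pid] = expr.profile(pid)
        return cache[pid]

    for u, v in net.graph.edges:
        key = (u, v) if u <= v else (v, u)
        values[key] = pcc(prof(u), prof(v))
    return PairCorrelation(values)
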