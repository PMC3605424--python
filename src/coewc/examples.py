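"""Published reference values used in worked examples and validation.

Values originate from the CoEWC analysis of the DIP *Saccharomyces
cerevisiae* interactome (24,743 interactions among 5,093 proteins) combined
with the 36-sample metabolic-cycle expression compendium.  They are inputs to
worked examples — the full yeast network itself is not shipped.
"""

from __future__ import annotations

from .centrality import ScoreTable, combine_coexpression_clustering
from .io_formats import PPINetwork

__all__ = [
    "YOL142W_NEIGHBORS",
    "COEWC_UNIQUE_TOP200",
    "yol142w_star",
    "yol142w_coewc",
]

# Per-neighbour characterisation of the essential protein YOL142W (degree 6):
# neighbour -> (PCC with YOL142W, neighbour's local clustering coefficient,
# neighbour essential?).  Five of the six neighbours are themselves essential,
# and every neighbour CC is far above the network-wide average of 0.097.
YOL142W_NEIGHBORS: dict[str, tuple[float, float, bool]] = {
    "YDR280W": (0.8046, 0.3399, True),
    "YER025W": (0.639, 0.1354, True),
    "YNL265C": (-0.357, 0.1648, False),
    "YGR195W": (0.771, 0.4083, True),
    "YGR095C": (0.7414, 0.3897, True),
    "YOL021C": (0.8391, 0.375, True),
}

# The 26 proteins ranked in the CoEWC top 200 on the yeast network but missed
# by the top 200 of DC, CC, SoECC and PeC alike: (rank, protein, degree,
# CoEWC score, essential?).  21 of the 26 (80.8%) are essential.
COEWC_UNIQUE_TOP200: list[tuple[int, str, int, float, bool]] = [
    (104, "YDR365C", 23, 1.698583, True),
    (124, "YDL232W", 18, 1.503577, True),
    (127, "YJL033W", 19, 1.49437, True),
    (128, "YGL099W", 14, 1.492625, True),
    (130, "YBR234C", 23, 1.473234, True),
    (131, "YIL075C", 32, 1.472131, True),
    (139, "YLR200W", 10, 1.435959, False),
    (145, "YDL087C", 23, 1.401966, True),
    (147, "YKL095W", 38, 1.390057, True),
    (151, "YHR081W", 5, 1.358778, False),
    (152, "YPR088C", 14, 1.351337, True),
    (154, "YOL094C", 37, 1.327599, True),
    (156, "YHL030W", 21, 1.310346, False),
    (158, "YOR259C", 28, 1.282556, True),
    (161, "YBL041W", 9, 1.275247, True),
    (163, "YNL182C", 21, 1.268987, True),
    (170, "YMR314W", 16, 1.246819, True),
    (178, "YBR126C", 29, 1.219773, False),
    (179, "YOL142W", 6, 1.219508, True),
    (181, "YBL023C", 14, 1.211368, True),
    (187, "YNL290W", 34, 1.176549, True),
    (190, "YFL008W", 24, 1.156859, True),
    (191, "YPL012W", 20, 1.153688, True),
    (193, "YER025W", 26, 1.140787, True),
    (194, "YOR210W", 16, 1.138906, True),
    (199, "YKL068W", 35, 1.119936, False),
]


def yol142w_star() -> PPINetwork:
    """The interactions between YOL142W and its six neighbours as a star."""
    return PPINetwork(
        edges=[("YOL142W", nb) for nb in YOL142W_NEIGHBORS]
    )


def yol142w_coewc() -> ScoreTable:
    """CoEWC over the YOL142W star using the published per-neighbour factors.

    The per-edge correlations and per-neighbour clustering coefficients come
    from the full yeast network analysis, so this reproduces YOL142W's
    network-wide CoEWC score from its local neighbourhood alone.
    """
    net = yol142w_star()
    corr = {
        ("YOL142W", nb): vals[0] for nb, vals in YOL142W_NEIGHBORS.items()
    }
    cc = {nb: vals[1] for nb, vals in YOL142W_NEIGHBORS.items()}
    cc["YOL142W"] = 0.0  # star centre: its own CC never enters its score
    return combine_coexpression_clustering(net, corr, cc)
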