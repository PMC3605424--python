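"""Readers/writers for PPI edge lists, expression matrices and protein lists.

The on-disk formats are deliberately minimal and text-only:

* **PPI network** — two whitespace/tab-separated protein-ID columns per line,
  ``#`` comments allowed, extra columns ignored (DIP exports vary).
  Self-interactions and repeated interactions are filtered on load, the way
  curated interactome snapshots are usually cleaned before scoring.
* **Expression matrix** — TSV with a header row of sample names; each data row
  is a protein ID followed by one numeric expression level per sample.
* **Protein lists** — one ID per line (used for reference essential proteins).
* **Score tables** — TSV of (rank, protein, score).

Protein identifiers are case-sensitive opaque strings (yeast ORF names such as
``YOL142W``); no identifier mapping is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("coewc")

__all__ = [
    "PPINetwork",
    "ExpressionMatrix",
    "EssentialSet",
    "ParseError",
    "read_ppi",
    "write_ppi",
    "read_expression",
    "write_expression",
    "read_id_list",
    "write_id_list",
    "write_scores",
    "read_scores",
]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def _canon(u: str, v: str) -> tuple[str, str]:
    """Canonical ordered form of an undirected edge."""
    return (u, v) if u <= v else (v, u)


class PPINetwork:
    """Undirected simple graph of protein IDs.

    Invariants: no self-loops, no duplicate edges (``(u, v)`` and ``(v, u)``
    are the same edge); isolated nodes are permitted.  Backed by a
    :class:`networkx.Graph`; self-loops passed to the constructor are dropped
    silently (the readers count and log them).
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        nodes: Iterable[str] = (),
    ) -> None:
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for u, v in edges:
            if u == v:
                g.add_node(u)  # a self-loop still attests the protein exists
            else:
                g.add_edge(u, v)
        self._g = g

    # -- adjacency queries ------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        """The underlying :class:`networkx.Graph` (treat as read-only)."""
        return self._g

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        """Edge set as canonically ordered (min, max) ID pairs."""
        return {_canon(u, v) for u, v in self._g.edges}

    def number_of_nodes(self) -> int:
        return self._g.number_of_nodes()

    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    def has_node(self, u: str) -> bool:
        return self._g.has_node(u)

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def neighbors(self, u: str) -> set[str]:
        if not self._g.has_node(u):
            raise KeyError(f"unknown protein ID: {u!r}")
        return set(self._g.neighbors(u))

    def degree(self, u: str) -> int:
        if not self._g.has_node(u):
            raise KeyError(f"unknown protein ID: {u!r}")
        return self._g.degree(u)

    def largest_component(self) -> "PPINetwork":
        """Subnetwork induced by the largest connected component."""
        if self._g.number_of_nodes() == 0:
            return PPINetwork()
        comp = max(nx.connected_components(self._g), key=len)
        sub = self._g.subgraph(comp)
        return PPINetwork(edges=sub.edges, nodes=sub.nodes)

    def __contains__(self, u: str) -> bool:
        return self._g.has_node(u)

    def __iter__(self) -> Iterator[str]:
        return iter(self._g.nodes)

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PPINetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"PPINetwork({self.number_of_nodes()} proteins, "
            f"{self.number_of_edges()} interactions)"
        )


@dataclass
class ExpressionMatrix:
    """Per-protein expression vectors over a fixed number of samples.

    Proteins absent from ``profiles`` map to the all-zero vector: the standard
    policy for interactome proteins with no measured transcript, which in turn
    forces their Pearson correlation with any partner to 0.
    """

    n_samples: int
    profiles: dict[str, np.ndarray] = field(default_factory=dict)
    sample_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        for pid, vec in self.profiles.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (self.n_samples,):
                raise ValueError(
                    f"profile for {pid!r} has length {vec.size}, "
                    f"expected {self.n_samples}"
                )
            self.profiles[pid] = vec
        if not self.sample_names:
            self.sample_names = tuple(f"S{i + 1}" for i in range(self.n_samples))

    def profile(self, pid: str) -> np.ndarray:
        """Expression vector for ``pid``; zero vector if unmeasured."""
        try:
            return self.profiles[pid]
        except KeyError:
            return np.zeros(self.n_samples)

    def __contains__(self, pid: str) -> bool:
        return pid in self.profiles

    def missing_from(self, ids: Iterable[str]) -> set[str]:
        """Subset of ``ids`` that have no measured profile."""
        return {i for i in ids if i not in self.profiles}


@dataclass(frozen=True)
class EssentialSet:
    """Reference set of essential protein IDs (exact string membership)."""

    ids: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", frozenset(self.ids))
        if not self.ids:
            raise ValueError("essential-protein set must be non-empty")

    def __contains__(self, pid: str) -> bool:
        return pid in self.ids

    def __len__(self) -> int:
        return len(self.ids)


# ---------------------------------------------------------------------------
# PPI edge lists
# ---------------------------------------------------------------------------

def read_ppi(path: str | Path) -> PPINetwork:
    """Load a two-column edge list, filtering self-loops and duplicates.

    Raises :class:`ParseError` for lines with fewer than two tokens and for
    files containing no interactions at all.  Dropped-record counts are
    reported through the ``coewc`` logger.
    """
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    nodes_seen: set[str] = set()
    n_self = n_dup = 0
    n_records = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ParseError(
                    f"{path}:{lineno}: expected at least 2 columns, "
                    f"got {len(tokens)}"
                )
            u, v = tokens[0], tokens[1]
            n_records += 1
            if u == v:
                n_self += 1
                nodes_seen.add(u)
                continue
            e = _canon(u, v)
            if e in edges:
                n_dup += 1
            else:
                edges.add(e)
    if n_records == 0:
        raise ParseError(f"{path}: no interaction records found")
    net = PPINetwork(edges=edges, nodes=nodes_seen)
    logger.info(
        "read_ppi(%s): %d proteins, %d interactions "
        "(%d self-interactions and %d repeated interactions filtered)",
        path.name,
        net.number_of_nodes(),
        net.number_of_edges(),
        n_self,
        n_dup,
    )
    return net


def write_ppi(net: PPINetwork, path: str | Path) -> None:
    """Write an edge list in canonical (sorted) order; round-trips read_ppi."""
    path = Path(path)
    with path.open("w") as fh:
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> ExpressionMatrix:
    """Load a TSV expression matrix (header of sample names, ID first column).

    Missing values (``NA``, empty cells) are rejected: only whole-protein
    absence is handled, by the zero-vector lookup policy.  Duplicate protein
    IDs keep the last row (with a warning).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: cannot parse expression matrix: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: expression matrix has no sample columns")

    dup = df.index.duplicated(keep="last")
    if dup.any():
        logger.warning(
            "read_expression(%s): %d duplicate protein IDs, keeping last "
            "occurrence of each",
            path.name,
            int(dup.sum()),
        )
        df = df[~dup]

    profiles: dict[str, np.ndarray] = {}
    for pid, row in df.iterrows():
        values = np.empty(len(row), dtype=float)
        for j, cell in enumerate(row):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                raise ParseError(
                    f"{path}: missing value for protein {pid!r}, "
                    f"sample {df.columns[j]!r}"
                )
            try:
                values[j] = float(cell)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: non-numeric value {cell!r} for protein {pid!r}, "
                    f"sample {df.columns[j]!r}"
                ) from exc
        profiles[str(pid)] = values

    return ExpressionMatrix(
        n_samples=df.shape[1],
        profiles=profiles,
        sample_names=tuple(str(c) for c in df.columns),
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("protein\t" + "\t".join(expr.sample_names) + "\n")
        for pid in sorted(expr.profiles):
            vals = "\t".join(format(x, ".6g") for x in expr.profiles[pid])
            fh.write(f"{pid}\t{vals}\n")


# ---------------------------------------------------------------------------
# ID lists and score tables
# ---------------------------------------------------------------------------

def read_id_list(path: str | Path) -> EssentialSet:
    """One protein ID per line; blank lines and ``#`` comments skipped."""
    path = Path(path)
    ids = set()
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.add(line.split()[0])
    if not ids:
        raise ParseError(f"{path}: empty protein list")
    return EssentialSet(frozenset(ids))


def write_id_list(ids: Iterable[str], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for pid in sorted(ids):
            fh.write(pid + "\n")


def write_scores(table, path: str | Path) -> None:
    """Write a ranked score table as TSV (rank, protein, score to 6 dp)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("rank\tprotein\t" + table.measure + "\n")
        for rank, pid in enumerate(table.ranking, start=1):
            fh.write(f"{rank}\t{pid}\t{table.values[pid]:.6f}\n")


def read_scores(path: str | Path):
    """Read a score table written by :func:`write_scores`."""
    from .centrality import ScoreTable

    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != 3:
            raise ParseError(f"{path}: expected 3-column score table header")
        measure = header[2]
        values: dict[str, float] = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            try:
                values[parts[1]] = float(parts[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric score {parts[2]!r}"
                ) from exc
    return ScoreTable(measure=measure, values=values)
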