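"""Simple undirected graphs and neighbourhood degree sequence machinery.

The central object of the library is the nondecreasing list of neighbour
degrees attached to each node of a simple undirected graph, together with
the per-degree-class bookkeeping (unique sequences, multiplicities,
positional means) that every index consumes.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

logger = logging.getLogger(__name__)

Label = str


class UndirectedGraph:
    """Simple, unweighted, undirected graph with opaque string labels.

    Any input label is converted with ``str`` and never reinterpreted.
    Self-loops and duplicate edges in the input are dropped/collapsed with
    a logged count — all index formulas assume a simple graph.
    """

    __slots__ = ("_g", "dropped_self_loops", "collapsed_duplicates")

    def __init__(
        self,
        edges: Iterable[tuple] = (),
        nodes: Iterable = (),
    ) -> None:
        g = nx.Graph()
        for u in nodes:
            g.add_node(str(u))
        loops = dup = 0
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                loops += 1
                g.add_node(u)
                continue
            if g.has_edge(u, v):
                dup += 1
                continue
            g.add_edge(u, v)
        if loops or dup:
            logger.warning(
                "input cleaned: dropped %d self-loop(s), collapsed %d duplicate edge(s)",
                loops,
                dup,
            )
        self.dropped_self_loops = loops
        self.collapsed_duplicates = dup
        self._g = g

    # -- construction ----------------------------------------------------
    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "UndirectedGraph":
        out = cls(nodes=g.nodes(), edges=g.edges())
        return out

    def to_networkx(self) -> nx.Graph:
        """Return a copy as a bare :class:`networkx.Graph`."""
        return self._g.copy()

    # -- basic queries ---------------------------------------------------
    @property
    def n(self) -> int:
        return self._g.number_of_nodes()

    @property
    def m(self) -> int:
        return self._g.number_of_edges()

    @property
    def nodes(self) -> tuple[Label, ...]:
        return tuple(self._g.nodes())

    @property
    def edges(self) -> tuple[tuple[Label, Label], ...]:
        """Canonical edge list: each edge as (min, max), sorted."""
        return tuple(sorted((u, v) if u <= v else (v, u) for u, v in self._g.edges()))

    @property
    def density(self) -> float:
        if self.n < 2:
            return 0.0
        return 2.0 * self.m / (self.n * (self.n - 1))

    def has_node(self, i) -> bool:
        return self._g.has_node(str(i))

    def degree(self, i) -> int:
        i = str(i)
        if not self._g.has_node(i):
            raise KeyError(f"unknown node label: {i!r}")
        return self._g.degree(i)

    def degrees(self) -> dict[Label, int]:
        return dict(self._g.degree())

    def neighbors(self, i) -> tuple[Label, ...]:
        i = str(i)
        if not self._g.has_node(i):
            raise KeyError(f"unknown node label: {i!r}")
        return tuple(self._g.neighbors(i))

    def __contains__(self, i) -> bool:
        return self._g.has_node(str(i))

    def __eq__(self, other) -> bool:
        if not isinstance(other, UndirectedGraph):
            return NotImplemented
        return set(self.nodes) == set(other.nodes) and set(self.edges) == set(other.edges)

    def __hash__(self):  # pragma: no cover - graphs are not meant to be dict keys
        return hash((frozenset(self.nodes), frozenset(self.edges)))

    def __repr__(self) -> str:
        return f"UndirectedGraph(n={self.n}, m={self.m})"


class WeightedDigraph:
    """Weighted directed graph used only as preprocessing input.

    Arcs are (source, target, weight) triples; a repeated arc overwrites
    the stored weight. Index operations never consume this type — it is
    reduced to an :class:`UndirectedGraph` by :func:`symmetrize` or
    :func:`binarize_by_density`.
    """

    __slots__ = ("_nodes", "_arcs")

    def __init__(self, arcs: Iterable[tuple] = (), nodes: Iterable = ()) -> None:
        self._nodes: dict[Label, None] = {str(u): None for u in nodes}
        self._arcs: dict[tuple[Label, Label], float] = {}
        for u, v, w in arcs:
            u, v = str(u), str(v)
            w = float(w)
            if not math.isfinite(w):
                raise ValueError(f"non-finite weight on arc {u!r}->{v!r}: {w}")
            self._nodes.setdefault(u, None)
            self._nodes.setdefault(v, None)
            self._arcs[(u, v)] = w

    @property
    def nodes(self) -> tuple[Label, ...]:
        return tuple(self._nodes)

    @property
    def arcs(self) -> dict[tuple[Label, Label], float]:
        return dict(self._arcs)

    @property
    def n(self) -> int:
        return len(self._nodes)

    def pair_weights(self) -> dict[tuple[Label, Label], float]:
        """Collapse arcs onto unordered pairs, keeping the larger weight.

        Self-loops are discarded.
        """
        out: dict[tuple[Label, Label], float] = {}
        for (u, v), w in self._arcs.items():
            if u == v:
                continue
            key = (u, v) if u <= v else (v, u)
            if key not in out or w > out[key]:
                out[key] = w
        return out


@dataclass(frozen=True)
class NeighbourhoodSequenceTable:
    """Per-node degree and sorted neighbour-degree sequence.

    Isolated (degree-0) nodes are excluded from ``sequences`` — an empty
    sequence can never match or be compared positionally — and listed in
    ``isolates`` instead.
    """

    degrees: Mapping[Label, int]
    sequences: Mapping[Label, tuple[int, ...]]
    isolates: tuple[Label, ...]
    m: int

    @property
    def n(self) -> int:
        """Number of non-isolated nodes (the table's working ``n``)."""
        return len(self.sequences)


@dataclass(frozen=True)
class DegreeClass:
    """All bookkeeping for the nodes sharing one degree ``p``."""

    degree: int
    members: tuple[Label, ...]
    sequences: tuple[tuple[int, ...], ...]  # aligned with members

    @property
    def q(self) -> int:
        """Number of p-length sequences (= class size q_p)."""
        return len(self.members)

    @property
    def counts(self) -> Counter:
        """Multiplicity c_pj of each unique sequence."""
        return Counter(self.sequences)

    @property
    def n_unique(self) -> int:
        """|sigma_p|: number of distinct p-length sequences."""
        return len(set(self.sequences))

    def positional_means(self) -> tuple[float, ...]:
        """mu^p(j): mean of j-th entries over all p-length sequences."""
        p, q = self.degree, self.q
        return tuple(sum(s[j] for s in self.sequences) / q for j in range(p))


@dataclass(frozen=True)
class DegreeClassIndex:
    """Degree classes of a sequence table, keyed by degree."""

    classes: Mapping[int, DegreeClass]

    @property
    def d2(self) -> tuple[int, ...]:
        """Degrees held by at least two nodes, ascending."""
        return tuple(sorted(p for p, c in self.classes.items() if c.q >= 2))


def neighbourhood_degree_sequence(G: UndirectedGraph, i) -> list[int]:
    """Sorted (nondecreasing) degrees of ``i``'s neighbours.

    Empty for an isolated node; raises ``KeyError`` for an unknown label.
    """
    return sorted(G.degree(j) for j in G.neighbors(i))


def sequence_table(G: UndirectedGraph) -> NeighbourhoodSequenceTable:
    """Build the neighbourhood degree sequence of every node of ``G``."""
    deg = G.degrees()
    sequences: dict[Label, tuple[int, ...]] = {}
    isolates: list[Label] = []
    for i in G.nodes:
        if deg[i] == 0:
            isolates.append(i)
        else:
            sequences[i] = tuple(sorted(deg[j] for j in G.neighbors(i)))
    if isolates:
        logger.warning(
            "%d isolated node(s) excluded from the sequence table", len(isolates)
        )
    return NeighbourhoodSequenceTable(
        degrees=dict(deg), sequences=sequences, isolates=tuple(isolates), m=G.m
    )


def degree_class_index(table: NeighbourhoodSequenceTable) -> DegreeClassIndex:
    """Group sequences into degree classes with all per-class bookkeeping.

    Degree-0 nodes never appear (they carry no sequence).
    """
    by_degree: dict[int, list[Label]] = {}
    for i, s in table.sequences.items():
        by_degree.setdefault(len(s), []).append(i)
    classes = {
        p: DegreeClass(
            degree=p,
            members=tuple(members),
            sequences=tuple(table.sequences[i] for i in members),
        )
        for p, members in by_degree.items()
    }
    return DegreeClassIndex(classes=classes)


def symmetrize(D: WeightedDigraph) -> UndirectedGraph:
    """Undirected support of a digraph: edge {i,j} iff any arc between them.

    Weights are discarded; self-loops dropped. Idempotent on already
    symmetric input.
    """
    edges = set()
    for (u, v) in D.arcs:
        if u != v:
            edges.add((u, v) if u <= v else (v, u))
    return UndirectedGraph(nodes=D.nodes, edges=sorted(edges))


def binarize_by_density(W: WeightedDigraph, d: float) -> UndirectedGraph:
    """Keep the ceil(d * n(n-1)/2) largest-weight node pairs as edges.

    Directed input is first collapsed onto unordered pairs (larger of the
    two arc weights). Ties at the cut weight are all kept, deterministically,
    so the resulting density can slightly exceed ``d``.
    """
    if not 0 < d <= 1:
        raise ValueError(f"density must be in (0, 1], got {d}")
    pairs = W.pair_weights()
    n = W.n
    k = math.ceil(d * n * (n - 1) / 2)
    if k >= len(pairs):
        kept = list(pairs)
    else:
        ordered = sorted(pairs.items(), key=lambda kv: (-kv[1], kv[0]))
        cut = ordered[k - 1][1]
        kept = [pair for pair, w in pairs.items() if w >= cut]
    return UndirectedGraph(nodes=W.nodes, edges=sorted(kept))
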