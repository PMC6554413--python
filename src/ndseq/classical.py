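"""Classical global network indices used for comparison.

Transitivity C, degree variance v, characteristic path length L,
degree assortativity r and Newman modularity Q of a detected partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import networkx as nx
import numpy as np

from .graph import UndirectedGraph
from .indices import VarianceConvention, _variance


def transitivity(G: UndirectedGraph) -> float:
    """Global clustering: 3 x triangles / connected triples (0 if no triples)."""
    return float(nx.transitivity(G.to_networkx()))


def degree_variance(
    G: UndirectedGraph,
    variance_convention: VarianceConvention = "population",
    normalised: bool = False,
) -> float:
    """Variance of the degree sequence, ``v``.

    ``normalised=True`` divides by (n - 1); this is a simple scale
    correction of our own choosing (the exact published normalisation is
    not reproduced here) and is excluded from reference comparisons.
    """
    degrees = list(G.degrees().values())
    v = _variance(degrees, variance_convention)
    if normalised and G.n > 1:
        v /= G.n - 1
    return v


def characteristic_path_length(G: UndirectedGraph) -> Optional[float]:
    """Mean shortest-path length over all connected node pairs.

    Disconnected graphs are handled by averaging over existing (finite)
    paths only; ``None`` if no pair is connected at all.
    """
    g = G.to_networkx()
    total = 0.0
    pairs = 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for d in dists.values():
            if d > 0:
                total += d
                pairs += 1
    if pairs == 0:
        return None
    return total / pairs  # both orientations counted: the ratio is unchanged


def assortativity(G: UndirectedGraph) -> Optional[float]:
    """Pearson correlation of endpoint degrees over edges (both orientations).

    ``None`` when either marginal is constant (e.g. regular graphs), where
    the correlation is undefined.
    """
    if G.m < 2:
        return None
    deg = G.degrees()
    x = []
    y = []
    for u, v in G.edges:
        x.extend((deg[u], deg[v]))
        y.extend((deg[v], deg[u]))
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(x, y)[0, 1]
    if not np.isfinite(r):
        return None
    return float(r)


def modularity(
    G: UndirectedGraph, method: Literal["greedy"] = "greedy"
) -> tuple[float, tuple[frozenset, ...]]:
    """Newman modularity Q of a partition found by the configured method.

    The only method currently wired is deterministic greedy modularity
    maximisation (Clauset-Newman-Moore); the partition is returned with Q
    so comparisons are reproducible.
    """
    if method != "greedy":
        raise ValueError(f"unknown community method: {method!r}")
    g = G.to_networkx()
    if G.m == 0:
        raise ValueError("modularity requires at least one edge")
    communities = nx.community.greedy_modularity_communities(g)
    q = nx.community.modularity(g, communities)
    return float(q), tuple(frozenset(c) for c in communities)


def modularity_of_partition(G: UndirectedGraph, partition) -> float:
    """Q of a caller-supplied partition (for fixed-partition comparisons)."""
    return float(nx.community.modularity(G.to_networkx(), partition))


@dataclass(frozen=True)
class ClassicalReport:
    C: float
    v: float
    L: Optional[float]
    r: Optional[float]
    Q: Optional[float]
    partition: Optional[tuple[frozenset, ...]] = None
    flags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"C": self.C, "v": self.v, "L": self.L, "r": self.r, "Q": self.Q,
                "flags": dict(self.flags)}


def compute_classical(
    G: UndirectedGraph,
    variance_convention: VarianceConvention = "population",
) -> ClassicalReport:
    """All five classical indices of ``G`` with undefined-result flags."""
    flags: dict[str, str] = {}
    L = characteristic_path_length(G)
    if L is None:
        flags["L"] = "undefined: no connected pair"
    r = assortativity(G)
    if r is None:
        flags["r"] = "undefined: constant endpoint degrees or m < 2"
    if G.m >= 1:
        Q, partition = modularity(G)
    else:
        Q, partition = None, None
        flags["Q"] = "undefined: no edges"
    return ClassicalReport(
        C=transitivity(G),
        v=degree_variance(G, variance_convention),
        L=L,
        r=r,
        Q=Q,
        partition=partition,
        flags=flags,
    )
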