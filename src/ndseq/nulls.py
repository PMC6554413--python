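"""Configuration-model nulls, graph generators and canonical fixtures."""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import networkx as nx
import numpy as np

from .classical import ClassicalReport, compute_classical
from .graph import UndirectedGraph
from .indices import IndexReport, VarianceConvention, compute_all

logger = logging.getLogger(__name__)

INDEX_COLUMNS = ("S", "V_n", "V_hat_n", "Omega", "R", "R_Omega", "C", "v", "L", "r", "Q")


def configuration_rewire(
    G: UndirectedGraph,
    swaps_per_edge: int = 10,
    seed: Optional[int] = None,
) -> UndirectedGraph:
    """Degree-preserving randomisation by double edge swaps.

    Repeatedly picks two edges (u,v), (x,y) and rewires them to (u,x),
    (v,y) when the result stays simple. The degree multiset is preserved
    exactly. Attempts ``swaps_per_edge * m`` successful swaps; if no valid
    swap exists (e.g. a star graph) the input is returned unchanged with a
    warning. Deterministic given ``seed``.
    """
    if swaps_per_edge < 1:
        raise ValueError("swaps_per_edge must be >= 1")
    edges = [list(e) for e in G.edges]
    m = len(edges)
    if m < 2:
        logger.warning("fewer than 2 edges: rewiring returns the graph unchanged")
        return UndirectedGraph(nodes=G.nodes, edges=G.edges)
    rng = random.Random(seed)
    adj: dict[str, set[str]] = {u: set() for u in G.nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    target = swaps_per_edge * m
    max_tries = 100 * target
    done = tries = 0
    while done < target and tries < max_tries:
        tries += 1
        a, b = rng.randrange(m), rng.randrange(m)
        if a == b:
            continue
        u, v = edges[a]
        x, y = edges[b]
        if rng.random() < 0.5:
            x, y = y, x
        # propose (u,x) and (v,y)
        if u == x or v == y or x in adj[u] or y in adj[v]:
            continue
        adj[u].discard(v)
        adj[v].discard(u)
        adj[x].discard(y)
        adj[y].discard(x)
        adj[u].add(x)
        adj[x].add(u)
        adj[v].add(y)
        adj[y].add(v)
        edges[a] = [u, x]
        edges[b] = [v, y]
        done += 1
    if done == 0:
        logger.warning("no valid double edge swap exists: graph returned unchanged")
        return UndirectedGraph(nodes=G.nodes, edges=G.edges)
    return UndirectedGraph(nodes=G.nodes, edges=[tuple(e) for e in edges])


@dataclass(frozen=True)
class NullEnsemble:
    """Indices over degree-preserving rewired realisations of one graph."""

    source_n: int
    source_m: int
    n_realisations: int
    seed: int
    swaps_per_edge: int
    index_reports: tuple[IndexReport, ...]
    classical_reports: tuple[ClassicalReport, ...]
    summary: dict = field(default_factory=dict)  # index -> (mean, sd, n_defined)

    def mean(self, index: str) -> Optional[float]:
        mu, _, _ = self.summary[index]
        return mu


def _summarise(values: list[Optional[float]]) -> tuple[Optional[float], Optional[float], int]:
    defined = [v for v in values if v is not None]
    if not defined:
        return None, None, 0
    arr = np.asarray(defined, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0, arr.size


def null_ensemble(
    G: UndirectedGraph,
    n_realisations: int = 10,
    seed: int = 0,
    swaps_per_edge: int = 10,
    variance_convention: VarianceConvention = "population",
    per_node_normalised_complexity: bool = False,
    classical: bool = True,
) -> NullEnsemble:
    """Independent rewired realisations of ``G`` with all indices computed.

    Realisation ``r`` draws its RNG seed from a spawned child of a single
    ``numpy`` ``SeedSequence``, so results do not depend on execution order.
    """
    if n_realisations < 1:
        raise ValueError("n_realisations must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_realisations)
    idx_reports: list[IndexReport] = []
    cls_reports: list[ClassicalReport] = []
    for child in children:
        r_seed = int(child.generate_state(1)[0])
        H = configuration_rewire(G, swaps_per_edge=swaps_per_edge, seed=r_seed)
        idx_reports.append(
            compute_all(
                H,
                variance_convention=variance_convention,
                per_node_normalised_complexity=per_node_normalised_complexity,
            )
        )
        if classical:
            cls_reports.append(compute_classical(H, variance_convention))

    summary: dict[str, tuple] = {}
    for name in ("S", "V_n", "V_hat_n", "Omega", "R", "R_Omega"):
        summary[name] = _summarise([getattr(rep, name) for rep in idx_reports])
    if classical:
        for name in ("C", "v", "L", "r", "Q"):
            summary[name] = _summarise([getattr(rep, name) for rep in cls_reports])
    return NullEnsemble(
        source_n=G.n,
        source_m=G.m,
        n_realisations=n_realisations,
        seed=seed,
        swaps_per_edge=swaps_per_edge,
        index_reports=tuple(idx_reports),
        classical_reports=tuple(cls_reports),
        summary=summary,
    )


# ---------------------------------------------------------------------------
# generators


def generate(model: str, seed: Optional[int] = None, **params) -> UndirectedGraph:
    """Standard random-graph constructions, deterministic given ``seed``.

    Models: ``erdos_renyi(n, p)``, ``random_geometric(n, radius)``,
    ``watts_strogatz(n, k, beta)``, ``barabasi_albert(n, m)``.
    """
    try:
        if model == "erdos_renyi":
            if not 0 <= params["p"] <= 1:
                raise ValueError(f"p must be in [0, 1], got {params['p']}")
            g = nx.gnp_random_graph(params["n"], params["p"], seed=seed)
        elif model == "random_geometric":
            if params["radius"] <= 0:
                raise ValueError(f"radius must be positive, got {params['radius']}")
            g = nx.random_geometric_graph(params["n"], params["radius"], seed=seed)
        elif model == "watts_strogatz":
            if not 0 <= params["beta"] <= 1:
                raise ValueError(f"beta must be in [0, 1], got {params['beta']}")
            g = nx.watts_strogatz_graph(params["n"], params["k"], params["beta"], seed=seed)
        elif model == "barabasi_albert":
            g = nx.barabasi_albert_graph(params["n"], params["m"], seed=seed)
        else:
            raise ValueError(f"unknown model: {model!r}")
    except KeyError as exc:
        raise ValueError(f"model {model!r} missing parameter {exc}") from exc
    except (nx.NetworkXError, ValueError) as exc:
        raise ValueError(f"invalid parameters for {model!r}: {exc}") from exc
    return UndirectedGraph.from_networkx(g)


# ---------------------------------------------------------------------------
# fixtures


def _karate() -> UndirectedGraph:
    ref = resources.files("ndseq.data").joinpath("karate.edgelist")
    edges = []
    for line in ref.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        u, v = line.split()
        edges.append((u, v))
    return UndirectedGraph(edges=edges)


def symmetric_double(H: UndirectedGraph) -> UndirectedGraph:
    """Disjoint union H + H (labels prefixed ``a:``/``b:``).

    Such a graph has a planar arrangement with mirror symmetry pivoting on
    no node, so its neighbourhood similarity is exactly 1.
    """
    nodes = [f"a:{u}" for u in H.nodes] + [f"b:{u}" for u in H.nodes]
    edges = [(f"a:{u}", f"a:{v}") for u, v in H.edges] + [
        (f"b:{u}", f"b:{v}") for u, v in H.edges
    ]
    return UndirectedGraph(nodes=nodes, edges=edges)


def planted_multiorder(multiplicities: tuple[int, ...]) -> UndirectedGraph:
    """Graph whose degree-2 class splits into planted sequence groups.

    Group ``j`` (multiplicity ``c_j``) is realised by a spider component:
    a hub with ``c_j`` subdivided legs (hub - mid - leaf) plus enough extra
    pendant leaves to give every hub a distinct degree >= 3. The mid nodes
    are then the *only* degree-2 nodes; group ``j`` contributes ``c_j``
    mids sharing the sequence (1, hub_degree_j), distinct across groups.
    Hence for p=2: q_p = sum(c_j), |sigma_p| = len(multiplicities) and the
    c_pj are exactly ``multiplicities``.
    """
    if not multiplicities or any(c < 1 for c in multiplicities):
        raise ValueError("multiplicities must be a nonempty tuple of positive ints")
    hub_degree_base = max(max(multiplicities) + 1, 3)
    nodes: list[str] = []
    edges: list[tuple[str, str]] = []
    for j, c in enumerate(multiplicities):
        hub = f"g{j}:hub"
        hub_degree = hub_degree_base + j  # distinct per group => distinct sequences
        for leg in range(c):
            mid, leaf = f"g{j}:mid{leg}", f"g{j}:leaf{leg}"
            edges += [(hub, mid), (mid, leaf)]
        for extra in range(hub_degree - c):
            edges.append((hub, f"g{j}:pend{extra}"))
        nodes.append(hub)
    return UndirectedGraph(nodes=nodes, edges=edges)


def fixtures(name: str, **params) -> UndirectedGraph:
    """Canonical graphs addressable by name.

    ``star(n)``, ``path(n)``, ``cycle(n)``, ``complete(n)``, ``karate``,
    ``symmetric_double(graph=H)``, ``planted_multiorder(multiplicities)``.
    """
    if name == "karate":
        return _karate()
    if name == "symmetric_double":
        return symmetric_double(params["graph"])
    if name == "planted_multiorder":
        return planted_multiorder(tuple(params["multiplicities"]))
    n = params.get("n")
    if n is None or n < 1:
        raise ValueError(f"fixture {name!r} needs a positive node count n")
    if name == "star":
        g = nx.star_graph(n - 1)
    elif name == "path":
        g = nx.path_graph(n)
    elif name == "cycle":
        g = nx.cycle_graph(n)
    elif name == "complete":
        g = nx.complete_graph(n)
    else:
        raise ValueError(f"unknown fixture: {name!r}")
    return UndirectedGraph.from_networkx(g)
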