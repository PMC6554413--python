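"""Topology indices over neighbourhood degree sequences.

Five indices are provided: neighbourhood similarity ``S``, node
heterogeneity ``V_n`` and its relative form ``V_hat_n``, the neighbourhood
organisation coefficient ``Omega``, hierarchical complexity ``R`` and its
multi-order-corrected form ``R_Omega`` — plus the height-2 subtree
signature that ties sequences to subtree-based graph isomorphism tests.

Conventions
-----------
* Isolated nodes are excluded everywhere (an empty sequence has no variance
  and can never match), so ``n`` below always means the non-isolated count.
* Variance convention (population vs sample) is selectable and applied
  consistently to sequence variances and to the global degree variance.
* Indices that are undefined for a graph (regular graphs for ``V_hat_n``;
  graphs whose degree classes are all singletons for ``Omega``/``R``) return
  ``None`` rather than raising or silently reporting 0.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .graph import (
    DegreeClass,
    DegreeClassIndex,
    NeighbourhoodSequenceTable,
    UndirectedGraph,
    degree_class_index,
    sequence_table,
)

logger = logging.getLogger(__name__)

VarianceConvention = Literal["population", "sample"]


def _variance(values: Sequence[float], convention: VarianceConvention) -> float:
    ddof = 0 if convention == "population" else 1
    arr = np.asarray(values, dtype=float)
    if arr.size <= ddof:
        return 0.0
    return float(np.var(arr, ddof=ddof))


# ---------------------------------------------------------------------------
# heterogeneity


def node_heterogeneity(
    G: UndirectedGraph,
    variance_convention: VarianceConvention = "population",
    mean_over: Literal["all", "contributing"] = "all",
) -> float:
    """Average variance of neighbourhood degree sequences, ``V_n``.

    Nodes of degree <= 1 contribute zero variance but (with the default
    ``mean_over="all"``) still count in the divisor ``n`` — the divisor is
    the number of non-isolated nodes. ``mean_over="contributing"`` instead
    averages over the degree->1 nodes only.
    """
    table = sequence_table(G)
    contributions = [
        _variance(s, variance_convention)
        for s in table.sequences.values()
        if len(s) > 1
    ]
    if mean_over == "contributing":
        return sum(contributions) / len(contributions) if contributions else 0.0
    if table.n == 0:
        return 0.0
    return sum(contributions) / table.n


def relative_node_heterogeneity(
    G: UndirectedGraph,
    variance_convention: VarianceConvention = "population",
) -> Optional[float]:
    """``V_n`` divided by the global degree variance (same convention).

    ``None`` for regular graphs, whose degree variance is zero.
    """
    table = sequence_table(G)
    degrees = [k for k in table.degrees.values() if k > 0]
    v = _variance(degrees, variance_convention)
    if v == 0.0:
        return None
    return node_heterogeneity(G, variance_convention) / v


# ---------------------------------------------------------------------------
# similarity


def neighbourhood_similarity(
    G: UndirectedGraph, include_self_match: bool = False
) -> float:
    """Fraction of nodes whose sequence equals that of another node, ``S``.

    Isolated nodes are excluded from numerator and denominator. With
    ``include_self_match=True`` the literal double-delta formula is used, in
    which every node matches itself and S is identically 1; the default
    requires a match with at least one *other* node.
    """
    table = sequence_table(G)
    if table.n == 0:
        return 0.0
    if include_self_match:
        return 1.0
    counts = Counter(table.sequences.values())
    matched = sum(1 for s in table.sequences.values() if counts[s] >= 2)
    return matched / table.n


# ---------------------------------------------------------------------------
# organisation


def omega_p(dci: DegreeClassIndex, p: int) -> float:
    """Multi-orderedness coefficient of degree class ``p``.

    omega_p = |sigma_p| * sum_j (q_p - c_pj) / (q_p^2 (q_p - 1)),
    evaluated literally from the stored unique-sequence multiplicities.
    0 when all sequences in the class coincide, 1 when all differ.
    Only defined for classes with q_p >= 2.
    """
    if p not in dci.classes:
        raise KeyError(f"no degree class for p={p}")
    cls = dci.classes[p]
    q = cls.q
    if q < 2:
        raise ValueError(f"omega_p undefined for q_p={q} < 2 (p={p})")
    counts = cls.counts
    total = sum(q - c for c in counts.values())
    return len(counts) * total / (q * q * (q - 1))


def neighbourhood_organisation(G: UndirectedGraph) -> Optional[float]:
    """Neighbourhood organisation coefficient ``Omega``.

    One minus the mean of omega_p over the degrees held by at least two
    nodes (D_2). ``None`` when D_2 is empty (every degree class a
    singleton) — there is nothing to average.
    """
    dci = degree_class_index(sequence_table(G))
    d2 = dci.d2
    if not d2:
        return None
    return 1.0 - sum(omega_p(dci, p) for p in d2) / len(d2)


# ---------------------------------------------------------------------------
# hierarchical complexity


def _class_positional_ss(cls: DegreeClass) -> float:
    """Sum over positions j and members i of (s_i(j) - mu(j))^2."""
    arr = np.asarray(cls.sequences, dtype=float)
    mu = arr.mean(axis=0)
    return float(((arr - mu) ** 2).sum())


def _complexity(
    G: UndirectedGraph, weighted: bool, per_node_normalised: bool
) -> Optional[float]:
    table = sequence_table(G)
    dci = degree_class_index(table)
    d2 = dci.d2
    if not d2:
        return None
    total = 0.0
    for p in d2:
        cls = dci.classes[p]
        term = _class_positional_ss(cls) / (p * (cls.q - 1))
        if weighted:
            term *= omega_p(dci, p)
        total += term
    value = total / len(d2)
    if per_node_normalised:
        value /= table.n
    return value


def hierarchical_complexity(
    G: UndirectedGraph, per_node_normalised: bool = False
) -> Optional[float]:
    """Hierarchical complexity ``R``: mean positional variance over D_2.

    R = (1/|D_2|) sum_{p in D_2} [1/(p(q_p-1))] sum_j sum_{i in V_p}
        (s_i^p(j) - mu^p(j))^2.

    ``per_node_normalised=True`` additionally divides by the number of
    non-isolated nodes; that scale is what published reference values for
    real networks use (see the acceptance tests), while the default matches
    the formula as written. ``None`` when D_2 is empty.
    """
    return _complexity(G, weighted=False, per_node_normalised=per_node_normalised)


def hierarchical_complexity_corrected(
    G: UndirectedGraph, per_node_normalised: bool = False
) -> Optional[float]:
    """Multi-order-corrected hierarchical complexity ``R_Omega``.

    Same as :func:`hierarchical_complexity` with each degree's term
    multiplied by its omega_p, so R_Omega <= R always.
    """
    return _complexity(G, weighted=True, per_node_normalised=per_node_normalised)


# ---------------------------------------------------------------------------
# height-2 subtree signature


def wl2_signature(G: UndirectedGraph, i) -> str:
    """Canonical token of node ``i``'s height-2 rooted subtree.

    In an unlabeled graph that subtree is fully determined by the pair
    (degree, neighbourhood degree sequence); two nodes get equal tokens iff
    those pairs are equal.
    """
    seq = sorted(G.degree(j) for j in G.neighbors(i))
    return f"{len(seq)}|{','.join(map(str, seq))}"


# ---------------------------------------------------------------------------
# batch report


@dataclass(frozen=True)
class PerDegreeRow:
    p: int
    q_p: int
    n_unique: int
    omega_p: Optional[float]
    r_term: Optional[float]


@dataclass(frozen=True)
class IndexReport:
    """All sequence-based indices of one graph, with undefined flags."""

    S: float
    V_n: float
    V_hat_n: Optional[float]
    Omega: Optional[float]
    R: Optional[float]
    R_Omega: Optional[float]
    per_degree: tuple[PerDegreeRow, ...]
    flags: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "S": self.S,
            "V_n": self.V_n,
            "V_hat_n": self.V_hat_n,
            "Omega": self.Omega,
            "R": self.R,
            "R_Omega": self.R_Omega,
            "flags": dict(self.flags),
            "provenance": dict(self.provenance),
        }


def compute_all(
    G: UndirectedGraph,
    variance_convention: VarianceConvention = "population",
    include_self_match: bool = False,
    per_node_normalised_complexity: bool = False,
) -> IndexReport:
    """Compute every sequence index of ``G`` in one pass."""
    table = sequence_table(G)
    dci = degree_class_index(table)
    d2 = set(dci.d2)

    flags: dict[str, str] = {}
    S = neighbourhood_similarity(G, include_self_match=include_self_match)
    V_n = node_heterogeneity(G, variance_convention)
    V_hat = relative_node_heterogeneity(G, variance_convention)
    if V_hat is None:
        flags["V_hat_n"] = "undefined: global degree variance is 0"

    per_degree: list[PerDegreeRow] = []
    for p in sorted(dci.classes):
        cls = dci.classes[p]
        if cls.q >= 2:
            om = omega_p(dci, p)
            term = _class_positional_ss(cls) / (p * (cls.q - 1))
        else:
            om = term = None
        per_degree.append(
            PerDegreeRow(p=p, q_p=cls.q, n_unique=cls.n_unique, omega_p=om, r_term=term)
        )

    if d2:
        omegas = [row.omega_p for row in per_degree if row.p in d2]
        terms = [row.r_term for row in per_degree if row.p in d2]
        Omega = 1.0 - sum(omegas) / len(d2)
        R = sum(terms) / len(d2)
        R_Om = sum(o * t for o, t in zip(omegas, terms)) / len(d2)
        if per_node_normalised_complexity and table.n:
            R /= table.n
            R_Om /= table.n
    else:
        Omega = R = R_Om = None
        flags["Omega"] = flags["R"] = flags["R_Omega"] = (
            "undefined: no degree held by at least two nodes"
        )

    return IndexReport(
        S=S,
        V_n=V_n,
        V_hat_n=V_hat,
        Omega=Omega,
        R=R,
        R_Omega=R_Om,
        per_degree=tuple(per_degree),
        flags=flags,
        provenance={
            "variance_convention": variance_convention,
            "include_self_match": include_self_match,
            "per_node_normalised_complexity": per_node_normalised_complexity,
            "n": G.n,
            "m": G.m,
            "isolates_excluded": len(table.isolates),
        },
    )
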