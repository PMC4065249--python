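"""Conditional interaction network: construction, counts, overlaps.

Networks are undirected bipartite graphs between query and array genes.
Each (query, array) edge accumulates (drug, direction) annotations, so one
gene pair interacting under two drugs is a single edge with two annotations
— counts below are over annotation incidences, matching how significant
conditional interactions are tallied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats as sps

from .errors import CondmapError, ConfigurationError
from .types import DIRECTIONS, DRUGS, InteractionCall

#: size of the screened array-gene library; the default overlap universe
DEFAULT_UNIVERSE = 1536


@dataclass
class CountSummary:
    total: int
    by_direction: dict[str, int]
    by_drug: dict[str, int]
    by_query: dict[str, int]


@dataclass
class OverlapResult:
    """One-sided (greater) overlap test between two gene sets."""

    set_a_size: int
    set_b_size: int
    overlap: int
    universe: int
    odds_ratio: float
    p: float


def build_network(calls: Sequence[InteractionCall]) -> nx.Graph:
    """Build the conditional interaction network from validated calls.

    Idempotent under duplicate calls: annotations are sets.
    """
    g = nx.Graph()
    for call in calls:
        g.add_node(call.query, role="query")
        if call.array not in g:
            g.add_node(call.array, role="array")
        if not g.has_edge(call.query, call.array):
            g.add_edge(call.query, call.array, annotations=set(), q={})
        attrs = g.edges[call.query, call.array]
        attrs["annotations"].add((call.drug, call.direction))
        if call.q is not None:
            attrs["q"][(call.drug, call.direction)] = call.q
    return g


def count_summary(network: nx.Graph) -> CountSummary:
    """Tally annotation incidences by direction, drug, and query gene."""
    by_direction = {d: 0 for d in DIRECTIONS}
    by_drug = {d: 0 for d in DRUGS}
    by_query: dict[str, int] = {}
    total = 0
    for u, v, attrs in network.edges(data=True):
        query = u if network.nodes[u].get("role") == "query" else v
        for drug, direction in attrs["annotations"]:
            total += 1
            by_direction[direction] += 1
            by_drug[drug] += 1
            by_query[query] = by_query.get(query, 0) + 1
    return CountSummary(
        total=total, by_direction=by_direction, by_drug=by_drug, by_query=by_query
    )


def interaction_set(
    network: nx.Graph,
    query: str,
    drugs: Optional[Sequence[str]] = None,
    directions: Optional[Sequence[str]] = None,
) -> set[str]:
    """Array genes interacting with ``query`` under the given filters.

    Defaults take the union over all drugs and both directions.
    """
    if query not in network or network.nodes[query].get("role") != "query":
        raise CondmapError(f"unknown query gene {query!r}")
    drugs = set(drugs) if drugs is not None else set(DRUGS)
    directions = set(directions) if directions is not None else set(DIRECTIONS)
    out = set()
    for neighbor in network.neighbors(query):
        for drug, direction in network.edges[query, neighbor]["annotations"]:
            if drug in drugs and direction in directions:
                out.add(neighbor)
                break
    return out


def shared_exclusive_partition(
    sets: Mapping[str, set[str]]
) -> dict[str, set[str]]:
    """Disjoint 7-region partition of three named gene sets.

    Region keys are sorted '+'-joined name combinations, e.g. for sets named
    A, B, C: 'A', 'B', 'C', 'A+B', 'A+C', 'B+C', 'A+B+C'.
    """
    if len(sets) != 3:
        raise ConfigurationError("partition requires exactly three named sets")
    names = sorted(sets)
    a, b, c = (sets[n] for n in names)
    regions = {
        names[0]: a - b - c,
        names[1]: b - a - c,
        names[2]: c - a - b,
        f"{names[0]}+{names[1]}": (a & b) - c,
        f"{names[0]}+{names[2]}": (a & c) - b,
        f"{names[1]}+{names[2]}": (b & c) - a,
        "+".join(names): a & b & c,
    }
    return regions


def fisher_overlap(
    set_a: set[str], set_b: set[str], universe_n: int = DEFAULT_UNIVERSE
) -> OverlapResult:
    """One-sided (greater) Fisher's exact test for gene-set overlap.

    The p-value is the hypergeometric upper tail P(X >= overlap) for drawing
    |b| genes from a universe of ``universe_n`` containing |a| marked genes.
    The odds ratio comes from the 2x2 table, with a 0.5 continuity
    correction only when a margin cell is zero.
    """
    if len(set_a | set_b) > universe_n:
        raise ConfigurationError(
            f"universe ({universe_n}) smaller than the union of the sets "
            f"({len(set_a | set_b)})"
        )
    k = len(set_a & set_b)
    na, nb = len(set_a), len(set_b)
    p = float(sps.hypergeom.sf(k - 1, universe_n, na, nb))

    t11 = k
    t12 = na - k
    t21 = nb - k
    t22 = universe_n - na - nb + k
    cells = np.array([t11, t12, t21, t22], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    odds = (cells[0] * cells[3]) / (cells[1] * cells[2])
    return OverlapResult(
        set_a_size=na, set_b_size=nb, overlap=k, universe=universe_n,
        odds_ratio=float(odds), p=min(p, 1.0),
    )


def pairwise_overlaps(
    network: nx.Graph,
    universe_n: int = DEFAULT_UNIVERSE,
    exclude_triple: bool = False,
) -> dict[tuple[str, str], OverlapResult]:
    """Overlap tests for every pair of query genes.

    ``exclude_triple`` removes genes interacting with all three queries
    before testing (the 'only two out of three' variant).
    """
    queries = sorted(
        n for n, d in network.nodes(data=True) if d.get("role") == "query"
    )
    sets = {q: interaction_set(network, q) for q in queries}
    if exclude_triple and len(queries) == 3:
        triple = set.intersection(*sets.values())
        sets = {q: s - triple for q, s in sets.items()}
    out = {}
    for i, qa in enumerate(queries):
        for qb in queries[i + 1:]:
            out[(qa, qb)] = fisher_overlap(sets[qa], sets[qb], universe_n)
    return out
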