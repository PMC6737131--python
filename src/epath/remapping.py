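"""Depth-first "remapping" search for missing essential genes (gap genes).

Single-gene knockouts miss genes whose essential function is masked by a
paralog, isozyme, or alternative pathway. On a metabolic map scored 5
(essential) / 1 (non-essential) per reaction edge, such a gap shows up as a
non-essential edge embedded in an essential neighborhood. The search walks
outward from both endpoints of a start edge: it crosses an edge if that edge
is essential or if some essential edge touches the node at its far end, and
stops otherwise (the stopped edge is still recorded as reached). A score-1
edge whose two endpoint sides each reach an essential edge is reclassified as
a missing essential gene. All sections are computed against the original
scores in one pass — reclassification never feeds back into the traversal,
which would otherwise loop.

The rescored matrix S', summing the original scores over each start edge's
section, is reported as a diagnostic alongside the reclassification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import IntegrityError
from .kgml_io import ESSENTIAL_SCORE, PathwayGraph, ReactionMatrix


@dataclass
class EssentialSection:
    """Edges reached by the two-sided search started at one edge.

    ``side_has_eg`` records, per endpoint of the start edge, whether the
    traversal from that endpoint reached an essential (score-5) edge; it is
    always evaluated against the original, pre-remapping scores.
    """

    start_edge: int
    reached_edges: set[int]
    side_has_eg: tuple[bool, bool]


@dataclass
class RemapResult:
    """Outcome of one remapping pass over a pathway graph."""

    missing_edges: set[int] = field(default_factory=set)
    missing_genes: set[str] = field(default_factory=set)
    s_prime: ReactionMatrix | None = None
    propagated_edges: set[int] = field(default_factory=set)


def _adjacency(graph: PathwayGraph) -> list[list[tuple[int, int]]]:
    """node -> [(edge_index, other_node)], deterministically ordered."""
    adj: list[list[tuple[int, int]]] = [[] for _ in range(graph.n)]
    for idx, e in enumerate(graph.edges):
        adj[e.i].append((idx, e.j))
        if e.j != e.i:
            adj[e.j].append((idx, e.i))
    for u in range(graph.n):
        adj[u].sort(key=lambda t: (graph.compounds[t[1]], graph.edges[t[0]].record.reaction_id, t[0]))
    return adj


def _node_has_eg(graph: PathwayGraph) -> list[bool]:
    out = [False] * graph.n
    for e in graph.edges:
        if e.score == ESSENTIAL_SCORE:
            out[e.i] = True
            out[e.j] = True
    return out


def _explore_side(
    graph: PathwayGraph,
    adj: list[list[tuple[int, int]]],
    has_eg: list[bool],
    start_edge: int,
    start_node: int,
) -> set[int]:
    """Edges reached from one endpoint of the start edge, excluding the start.

    A node is expanded when some entered edge allowed the search through it;
    an edge (u, v) entered from an expanded u allows the search through iff it
    scores 5 or v touches a score-5 edge. The reached set is the closure of
    this rule and therefore independent of traversal order.
    """
    reached: set[int] = set()
    expanded: set[int] = set()
    stack = [start_node]
    while stack:
        u = stack.pop()
        if u in expanded:
            continue
        expanded.add(u)
        for eidx, v in adj[u]:
            if eidx == start_edge:
                continue
            reached.add(eidx)
            if graph.edges[eidx].score == ESSENTIAL_SCORE or has_eg[v]:
                if v not in expanded:
                    stack.append(v)
    return reached


def dfs_essential_section(graph: PathwayGraph, start_edge: int) -> EssentialSection:
    """Run the two-sided traversal from one edge and collect its section."""
    if not (0 <= start_edge < len(graph.edges)):
        raise IntegrityError(f"start edge {start_edge} not in graph")
    adj = _adjacency(graph)
    has_eg = _node_has_eg(graph)
    return _section(graph, adj, has_eg, start_edge)


def _section(graph, adj, has_eg, start_edge) -> EssentialSection:
    e = graph.edges[start_edge]
    sides = []
    reached: set[int] = {start_edge}
    for endpoint in (e.i, e.j):
        side = _explore_side(graph, adj, has_eg, start_edge, endpoint)
        sides.append(
            any(graph.edges[x].score == ESSENTIAL_SCORE for x in side)
        )
        reached |= side
    return EssentialSection(
        start_edge=start_edge, reached_edges=reached, side_has_eg=(sides[0], sides[1])
    )


def rescore(graph: PathwayGraph) -> ReactionMatrix:
    """Rescored matrix S': per start edge, the sum of original scores over its section.

    The start edge's own score is included, so every existing edge keeps
    S' >= 1; compound pairs without an edge stay 0. Parallel edges collapse by
    maximum section sum, mirroring the collapse rule for S.
    """
    adj = _adjacency(graph)
    has_eg = _node_has_eg(graph)
    values = np.zeros((graph.n, graph.n), dtype=int)
    for idx, e in enumerate(graph.edges):
        if e.i == e.j:
            continue
        section = _section(graph, adj, has_eg, idx)
        total = sum(graph.edges[x].score for x in section.reached_edges)
        s = max(values[e.i, e.j], total)
        values[e.i, e.j] = s
        values[e.j, e.i] = s
    return ReactionMatrix(n=graph.n, values=values)


def find_missing_egs(graph: PathwayGraph) -> RemapResult:
    """Classify gap edges, collect gap genes, and apply one round of gene propagation.

    A score-1 edge is reclassified as missing-essential iff its section shows
    essential support on both endpoint sides. Gap genes are the locus tags of
    reclassified edges, minus tags already carried by an originally essential
    edge. Edges that are neither essential nor reclassified but share a gap
    gene are reported as propagated; propagation runs once, after the pass,
    and never re-enters the traversal.
    """
    adj = _adjacency(graph)
    has_eg = _node_has_eg(graph)
    values = np.zeros((graph.n, graph.n), dtype=int)

    missing: set[int] = set()
    for idx, e in enumerate(graph.edges):
        section = _section(graph, adj, has_eg, idx)
        total = sum(graph.edges[x].score for x in section.reached_edges)
        if e.i != e.j:
            s = max(values[e.i, e.j], total)
            values[e.i, e.j] = s
            values[e.j, e.i] = s
        if e.score != ESSENTIAL_SCORE and all(section.side_has_eg):
            missing.add(idx)

    essential_tags: set[str] = set()
    for e in graph.edges:
        if e.score == ESSENTIAL_SCORE:
            essential_tags |= e.record.locus_tags
    missing_genes: set[str] = set()
    for idx in missing:
        missing_genes |= graph.edges[idx].record.locus_tags
    missing_genes -= essential_tags

    propagated: set[int] = set()
    for idx, e in enumerate(graph.edges):
        if idx in missing or e.score == ESSENTIAL_SCORE:
            continue
        if e.record.locus_tags & missing_genes:
            propagated.add(idx)

    return RemapResult(
        missing_edges=missing,
        missing_genes=missing_genes,
        s_prime=ReactionMatrix(n=graph.n, values=values),
        propagated_edges=propagated,
    )


def remap_strain(graph: PathwayGraph) -> RemapResult:
    """One full remapping pass: sections for every edge, S', and gap classification.

    The pass is run exactly once; feeding its output labels back in without a
    new search changes nothing, and the result is independent of edge order.
    """
    return find_missing_egs(graph)
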