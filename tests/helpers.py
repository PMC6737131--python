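"""Shared test utilities: graph builders and an independent brute-force oracle.

The oracle decides gap edges by enumerating simple edge paths from each
endpoint of a candidate edge, checking the traversal rule (cross an edge iff
it scores 5 or its far node touches a score-5 edge) along every path. It
shares no code with the closure-based search in the package.
"""

from __future__ import annotations

import itertools

from epath.kgml_io import Edge, PathwayGraph, ReactionRecord


def make_graph(compounds: list[str], edge_specs: list[tuple]) -> PathwayGraph:
    """Build a PathwayGraph from (compound_i, compound_j, score[, tags]) tuples."""
    index = {c: k for k, c in enumerate(compounds)}
    edges = []
    for num, spec in enumerate(edge_specs, start=1):
        u, v, score = spec[0], spec[1], spec[2]
        tags = set(spec[3]) if len(spec) > 3 else {f"g{num:04d}"}
        rec = ReactionRecord(
            reaction_id=f"R{num:05d}",
            substrates=[u],
            products=[v],
            ko_ids={f"K{num:05d}"},
            locus_tags=tags,
        )
        edges.append(Edge(i=index[u], j=index[v], record=rec, score=score))
    return PathwayGraph(compounds=list(compounds), edges=edges)


def _incident(graph: PathwayGraph, node: int) -> list[tuple[int, int]]:
    out = []
    for idx, e in enumerate(graph.edges):
        if e.i == node:
            out.append((idx, e.j))
        elif e.j == node:
            out.append((idx, e.i))
    return out


def _node_touches_essential(graph: PathwayGraph, node: int) -> bool:
    return any(
        e.score == 5 and node in (e.i, e.j) for e in graph.edges
    )


def oracle_side_edges(graph: PathwayGraph, start_edge: int, node: int) -> set[int]:
    """Edges reachable from one endpoint of the start edge, by path enumeration."""
    reached: set[int] = set()

    def walk(u: int, used: frozenset[int]) -> None:
        for eidx, v in _incident(graph, u):
            if eidx == start_edge or eidx in used:
                continue
            reached.add(eidx)
            crossable = graph.edges[eidx].score == 5 or _node_touches_essential(
                graph, v
            )
            if crossable:
                walk(v, used | {eidx})

    walk(node, frozenset())
    return reached


def oracle_side_has_essential(graph: PathwayGraph, start_edge: int, node: int) -> bool:
    return any(
        graph.edges[x].score == 5 for x in oracle_side_edges(graph, start_edge, node)
    )


def oracle_missing_edges(graph: PathwayGraph) -> set[int]:
    """Score-1 edges with essential support on both endpoint sides."""
    missing: set[int] = set()
    for idx, e in enumerate(graph.edges):
        if e.score == 5:
            continue
        if oracle_side_has_essential(graph, idx, e.i) and oracle_side_has_essential(
            graph, idx, e.j
        ):
            missing.add(idx)
    return missing


def oracle_section_sum(graph: PathwayGraph, start_edge: int) -> int:
    e = graph.edges[start_edge]
    reached = (
        {start_edge}
        | oracle_side_edges(graph, start_edge, e.i)
        | oracle_side_edges(graph, start_edge, e.j)
    )
    return sum(graph.edges[x].score for x in reached)


def all_connected_topologies(n_nodes: int):
    """All non-empty edge subsets of the complete graph on ``n_nodes`` that form
    a single connected component over the touched nodes."""
    nodes = list(range(n_nodes))
    possible = list(itertools.combinations(nodes, 2))
    for r in range(1, len(possible) + 1):
        for subset in itertools.combinations(possible, r):
            touched = {u for pair in subset for u in pair}
            # connectivity over touched nodes
            adj = {u: set() for u in touched}
            for u, v in subset:
                adj[u].add(v)
                adj[v].add(u)
            stack = [next(iter(touched))]
            seen = set()
            while stack:
                u = stack.pop()
                if u in seen:
                    continue
                seen.add(u)
                stack.extend(adj[u] - seen)
            if seen == touched:
                yield subset


def graph_from_topology(subset, scores) -> PathwayGraph:
    nodes = sorted({u for pair in subset for u in pair})
    compounds = [f"C{u:05d}" for u in nodes]
    specs = [
        (f"C{u:05d}", f"C{v:05d}", score) for (u, v), score in zip(subset, scores)
    ]
    return make_graph(compounds, specs)


def edge_key(graph: PathwayGraph, idx: int) -> tuple:
    e = graph.edges[idx]
    pair = tuple(sorted((graph.compounds[e.i], graph.compounds[e.j])))
    return (*pair, e.record.reaction_id, e.score)
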