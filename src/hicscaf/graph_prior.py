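"""Orientation evidence from the assembly graph.

The assembler's unitig graph (GFA) records ambiguous adjacencies the
assembler could not resolve. For a pair of contigs we compute unweighted
shortest-path lengths sigma between them in all four relative
orientations; a pair is informative when one orientation is strictly
closer than every other (score = second-shortest / shortest > 1).
Hi-C edges that contradict an informative graph orientation are removed
and replaced by the graph-implied edge.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Tuple

from hicscaf.scaffold_graph import (
    BEGIN,
    END,
    HiCEdge,
    NodeEnd,
    ScaffoldGraph,
    edge_key,
)

Oriented = Tuple[str, str]  # (segment id, "+" | "-")

#: Bijection between a relative orientation class (ou, ov) — measured as a
#: directed traversal u->v — and the contig-end pair of the junction it
#: implies: forward-forward joins u.E to v.B, forward-reverse joins u.E to
#: v.E, and so on.
ORIENT_TO_END_SIDES: Dict[Tuple[str, str], Tuple[str, str]] = {
    ("+", "+"): (END, BEGIN),
    ("+", "-"): (END, END),
    ("-", "+"): (BEGIN, BEGIN),
    ("-", "-"): (BEGIN, END),
}
END_SIDES_TO_ORIENT = {v: k for k, v in ORIENT_TO_END_SIDES.items()}


def _flip(orient: str) -> str:
    return "-" if orient == "+" else "+"


class AssemblyGraph:
    """Bidirected overlap graph over assembly segments.

    A link (a, oa, b, ob) states that segment a traversed in orientation
    oa can be followed by b in orientation ob; its reverse traversal
    (b, -ob) -> (a, -oa) is implied. Both GFA recordings of the same link
    canonicalize to a single edge.
    """

    def __init__(self, segments: Optional[Dict[str, int]] = None):
        self.segments: Dict[str, int] = dict(segments or {})
        self._links: set[Tuple[str, str, str, str]] = set()
        self._adj: Dict[Oriented, list[Oriented]] = {}

    @staticmethod
    def _canonical(a: str, oa: str, b: str, ob: str) -> Tuple[str, str, str, str]:
        fwd = (a, oa, b, ob)
        rev = (b, _flip(ob), a, _flip(oa))
        return min(fwd, rev)

    def add_segment(self, name: str, length: int) -> None:
        self.segments[name] = length

    def add_link(self, a: str, oa: str, b: str, ob: str) -> None:
        if a not in self.segments or b not in self.segments:
            missing = a if a not in self.segments else b
            raise KeyError(f"link references unknown segment {missing!r}")
        canon = self._canonical(a, oa, b, ob)
        if canon in self._links:
            return
        self._links.add(canon)
        a, oa, b, ob = canon
        self._adj.setdefault((a, oa), []).append((b, ob))
        self._adj.setdefault((b, _flip(ob)), []).append((a, _flip(oa)))

    @property
    def links(self) -> list[Tuple[str, str, str, str]]:
        return sorted(self._links)

    def neighbors(self, node: Oriented) -> list[Oriented]:
        return sorted(self._adj.get(node, []))

    def are_linked(self, a: str, b: str) -> bool:
        return any(x == a and y == b or x == b and y == a
                   for x, _, y, _ in self._links)

    def bfs_distances(self, start: Oriented, max_depth: int) -> Dict[Oriented, int]:
        """Hop counts from an oriented segment, capped at ``max_depth``."""
        dist = {start: 0}
        queue = deque([start])
        while queue:
            node = queue.popleft()
            d = dist[node]
            if d >= max_depth:
                continue
            for nxt in self.neighbors(node):
                if nxt not in dist:
                    dist[nxt] = d + 1
                    queue.append(nxt)
        return dist


@dataclass(frozen=True)
class OrientationPathSet:
    """sigma for the four orientation classes of a contig pair."""

    u: str
    v: str
    sigma: Dict[Tuple[str, str], float]  # (ou, ov) -> hop count or inf


@dataclass(frozen=True)
class GraphScore:
    u: str
    v: str
    best_orientation: Tuple[str, str]
    score: float  # second-shortest / shortest; >= 1

    @property
    def retained(self) -> bool:
        return self.score > 1

    @property
    def best_end_pair(self) -> Tuple[NodeEnd, NodeEnd]:
        su, sv = ORIENT_TO_END_SIDES[self.best_orientation]
        return NodeEnd(self.u, su), NodeEnd(self.v, sv)


def orientation_paths(
    graph: AssemblyGraph, u: str, v: str, max_depth: int = 10
) -> OrientationPathSet:
    """Shortest oriented hop counts between two distinct segments.

    sigma[(ou, ov)] is the number of links on the shortest walk entering
    u in orientation ou and reaching v in orientation ov; unreachable
    (or beyond ``max_depth`` hops) is +inf.
    """
    if u == v:
        raise ValueError("orientation paths need two distinct segments")
    for seg in (u, v):
        if seg not in graph.segments:
            raise KeyError(f"unknown segment {seg!r}")
    sigma: Dict[Tuple[str, str], float] = {}
    for ou in "+-":
        dist = graph.bfs_distances((u, ou), max_depth)
        for ov in "+-":
            sigma[(ou, ov)] = float(dist.get((v, ov), math.inf))
    return OrientationPathSet(u=u, v=v, sigma=sigma)


_CLASS_ORDER = [("+", "+"), ("+", "-"), ("-", "+"), ("-", "-")]


def score_pair(pathset: OrientationPathSet) -> GraphScore:
    """Ratio of second-shortest to shortest sigma over all orientations.

    A tie for the shortest path, or no finite path at all, yields score 1
    (no orientation evidence). The second-shortest is taken over the
    three remaining orientation classes.
    """
    sigma = pathset.sigma
    best_class = min(_CLASS_ORDER, key=lambda c: (sigma[c], _CLASS_ORDER.index(c)))
    best = sigma[best_class]
    if math.isinf(best):
        return GraphScore(pathset.u, pathset.v, best_class, 1.0)
    others = [sigma[c] for c in _CLASS_ORDER if c != best_class]
    second = min(others)
    if second == best:
        return GraphScore(pathset.u, pathset.v, best_class, 1.0)
    score = second / best if math.isfinite(second) else math.inf
    return GraphScore(pathset.u, pathset.v, best_class, score)


def score_contig_pair(
    graph: AssemblyGraph, u: str, v: str, max_depth: int = 10
) -> GraphScore:
    return score_pair(orientation_paths(graph, u, v, max_depth))


def reconcile(
    scaffold_graph: ScaffoldGraph,
    scores: Iterable[GraphScore],
    min_graph_weight: Optional[float] = None,
) -> ScaffoldGraph:
    """Resolve Hi-C vs assembly-graph orientation conflicts in place.

    For every retained score: Hi-C edges on the pair implying any other
    orientation are deleted, and an edge implying the graph's best
    orientation is added or kept with the maximum Hi-C weight observed
    on the pair — or ``min_graph_weight`` when the pair has no Hi-C
    support at all (default: the maximum weight anywhere in the graph,
    so graph-implied joins sort first).
    """
    if min_graph_weight is None:
        min_graph_weight = max(
            (e.w for e in scaffold_graph.edges.values()), default=1.0
        )
    for score in scores:
        if not score.retained:
            continue
        pair_keys = [
            edge_key(NodeEnd(score.u, su), NodeEnd(score.v, sv))
            for su in (BEGIN, END)
            for sv in (BEGIN, END)
        ]
        existing = {
            k: scaffold_graph.edges[k] for k in pair_keys if k in scaffold_graph.edges
        }
        if not existing and min_graph_weight <= 0:
            continue
        max_w = max((e.w for e in existing.values()), default=0.0)
        bu, bv = score.best_end_pair
        best_key = edge_key(bu, bv)
        for k in existing:
            if k != best_key:
                scaffold_graph.remove_edge(k)
        weight = max_w if max_w > 0 else min_graph_weight
        if best_key in existing:
            e = scaffold_graph.edges[best_key]
            e.w = weight
            e.source = "hic+graph"
        else:
            scaffold_graph.add_edge(
                HiCEdge(best_key[0], best_key[1], n=0, w=weight, source="graph")
            )
    return scaffold_graph
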