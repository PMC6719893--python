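"""Scaffold layout by iterative greedy weighted maximal matching.

The scaffold graph restricted to mutually-best edges is matched
greedily (a 1/2-approximation of the maximum-weight matching); adding
back each contig's implicit B–E edge turns the matching into a set of
alternating paths — the scaffolds. Cycles that would arise are broken
at their lowest-weight Hi-C edge. Unscaffolded contigs can afterwards
be inserted into existing junctions where their linkage to both flanks
beats the flank-to-flank link itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from hicscaf.io_formats import Contig
from hicscaf.scaffold_graph import (
    BEGIN,
    END,
    EdgeKey,
    HiCEdge,
    NodeEnd,
    ScaffoldGraph,
    compute_best_buddy,
    edge_key,
    filter_best_buddy,
)

Walk = List[Tuple[str, str]]  # ordered (contig_id, "+" | "-")


@dataclass
class Layout:
    """Ordered, oriented contig walks plus the join edges that built them."""

    walks: List[Walk]
    joins: List[List[Optional[HiCEdge]]] = field(default_factory=list)
    names: Optional[List[str]] = None

    def __post_init__(self) -> None:
        if not self.joins:
            self.joins = [[None] * max(len(w) - 1, 0) for w in self.walks]

    def scaffold_name(self, idx: int) -> str:
        if self.names is not None:
            return self.names[idx]
        return f"scaffold_{idx + 1}"

    @property
    def contig_ids(self) -> list[str]:
        return [cid for walk in self.walks for cid, _ in walk]

    def singleton_indices(self) -> list[int]:
        return [i for i, w in enumerate(self.walks) if len(w) == 1]

    def validate(self) -> None:
        ids = self.contig_ids
        if len(ids) != len(set(ids)):
            raise ValueError("a contig appears in more than one walk")
        for walk, joins in zip(self.walks, self.joins):
            if len(joins) != max(len(walk) - 1, 0):
                raise ValueError("join list length mismatch")


def greedy_matching(edges: Iterable[HiCEdge]) -> List[HiCEdge]:
    """Single greedy pass: scan edges best-first, add when both ends free.

    Edges are ordered by BB desc, then W desc, then endpoint ids, making
    the result deterministic; a single pass yields a maximal matching,
    within 1/2 of the maximum-weight matching.
    """
    matched: set[NodeEnd] = set()
    out: List[HiCEdge] = []
    for e in sorted(edges, key=lambda e: (-e.bb, -e.w, e.key)):
        if e.u not in matched and e.v not in matched:
            matched.add(e.u)
            matched.add(e.v)
            out.append(e)
    return out


def iterate_matching(graph: ScaffoldGraph) -> List[HiCEdge]:
    """Accumulate greedy matchings over residual graphs until maximal.

    Each round recomputes best-buddy ratios on the residual graph (edges
    filtered out earlier can become mutually best once their competitors
    are consumed), matches the surviving edges, and removes the matched
    nodes. When a round of filtered matching stalls while addable edges
    remain (only possible under exact weight ties), a final unfiltered
    greedy pass guarantees maximality.
    """
    residual = ScaffoldGraph(contigs=graph.contigs, edges=dict(graph.edges))
    matched: set[NodeEnd] = set()
    out: List[HiCEdge] = []

    def consume(rounds_edges: List[HiCEdge]) -> int:
        added = 0
        for e in rounds_edges:
            if e.u not in matched and e.v not in matched:
                matched.add(e.u)
                matched.add(e.v)
                out.append(e)
                added += 1
        for key in [k for k in residual.edges if k[0] in matched or k[1] in matched]:
            residual.remove_edge(key)
        return added

    while residual.edges:
        compute_best_buddy(residual)
        filtered = filter_best_buddy(residual)
        if consume(greedy_matching(filtered.edges.values())) == 0:
            consume(greedy_matching(residual.edges.values()))
            break
    return out


def _cycle_components(
    adjacency: Dict[NodeEnd, list], nodes: Sequence[NodeEnd]
) -> List[List[NodeEnd]]:
    seen: set[NodeEnd] = set()
    components = []
    for start in sorted(nodes):
        if start in seen:
            continue
        comp = []
        stack = [start]
        seen.add(start)
        while stack:
            node = stack.pop()
            comp.append(node)
            for nxt in adjacency.get(node, []):
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        components.append(comp)
    return components


def build_walks(matching: Sequence[HiCEdge], contigs: Sequence[Contig]) -> Layout:
    """Union the matching with implicit B–E edges and read off the walks.

    Every component of the union is a path or a cycle (each node touches
    one implicit edge and at most one matching edge). Cycles are broken
    at their lowest-weight matching edge. A walk entering a contig at B
    records it forward (+), at E reversed (−).
    """
    partner: Dict[NodeEnd, HiCEdge] = {}
    for e in matching:
        if e.u in partner or e.v in partner:
            raise ValueError("matching touches a node twice")
        partner[e.u] = e
        partner[e.v] = e

    ids = [c.id for c in contigs]
    adjacency: Dict[NodeEnd, list] = {}
    for cid in ids:
        b, e_ = NodeEnd(cid, BEGIN), NodeEnd(cid, END)
        adjacency.setdefault(b, []).append(e_)
        adjacency.setdefault(e_, []).append(b)
    for e in matching:
        adjacency[e.u].append(e.v)
        adjacency[e.v].append(e.u)

    components = _cycle_components(adjacency, list(adjacency))
    walks: List[Walk] = []
    joins: List[List[Optional[HiCEdge]]] = []
    for comp in components:
        comp_set = set(comp)
        terminals = sorted(n for n in comp if n not in partner)
        if not terminals:
            # cycle: drop the lowest-weight non-implicit edge
            cycle_edges = {partner[n].key: partner[n] for n in comp}
            worst = min(cycle_edges.values(), key=lambda e: (e.w, e.key))
            for node in (worst.u, worst.v):
                del partner[node]
            terminals = sorted(n for n in comp if n not in partner)
        start = terminals[0]
        walk: Walk = []
        walk_joins: List[Optional[HiCEdge]] = []
        cur: Optional[NodeEnd] = start
        while cur is not None:
            orient = "+" if cur.side == BEGIN else "-"
            walk.append((cur.contig_id, orient))
            exit_node = cur.other()
            nxt_edge = partner.get(exit_node)
            if nxt_edge is None:
                cur = None
            else:
                walk_joins.append(nxt_edge)
                cur = nxt_edge.v if nxt_edge.u == exit_node else nxt_edge.u
            if cur is not None and cur not in comp_set:
                raise AssertionError("walk escaped its component")
        if 2 * len(walk) != len(comp):
            raise AssertionError("component is neither a path nor a cycle")
        walks.append(walk)
        joins.append(walk_joins)
    return Layout(walks=walks, joins=joins)


def _walk_end_nodes(walk: Walk) -> Tuple[NodeEnd, NodeEnd]:
    """Exposed contig-ends at the left and right extremity of a walk."""
    (c0, o0), (cn, on) = walk[0], walk[-1]
    left = NodeEnd(c0, BEGIN if o0 == "+" else END)
    right = NodeEnd(cn, END if on == "+" else BEGIN)
    return left, right


def _junction_nodes(walk: Walk, i: int) -> Tuple[NodeEnd, NodeEnd]:
    """Contig-ends facing the junction between walk[i] and walk[i+1]."""
    ca, oa = walk[i]
    cb, ob = walk[i + 1]
    a_exit = NodeEnd(ca, END if oa == "+" else BEGIN)
    b_entry = NodeEnd(cb, BEGIN if ob == "+" else END)
    return a_exit, b_entry


def insert_small_contigs(
    layout: Layout,
    graph: ScaffoldGraph,
    candidates: Optional[Sequence[str]] = None,
    insertion_ratio: float = 1.0,
) -> Layout:
    """Place unscaffolded contigs inside existing junctions.

    A candidate c goes between adjacent contigs (a, b) when both
    W(a, c) and W(c, b) exceed W(a, b) × ``insertion_ratio``, choosing
    the orientation of c and the junction maximizing W(a,c) + W(c,b).
    Competing placements are resolved best-score-first (ties by contig
    id); each junction accepts at most one insertion.
    """
    def weight(a: NodeEnd, b: NodeEnd) -> float:
        e = graph.edges.get(edge_key(a, b))
        return e.w if e is not None else 0.0

    if candidates is None:
        candidates = sorted(
            layout.walks[i][0][0] for i in layout.singleton_indices()
        )
    candidate_set = set(candidates)
    walk_of = {w[0][0]: i for i, w in enumerate(layout.walks) if len(w) == 1}

    proposals = []  # (-score, cid, walk_idx, junction_idx, orient)
    for cid in sorted(candidate_set):
        for wi, walk in enumerate(layout.walks):
            if len(walk) < 2:
                continue
            for ji in range(len(walk) - 1):
                a_exit, b_entry = _junction_nodes(walk, ji)
                w_ab = weight(a_exit, b_entry)
                for orient in "+-":
                    c_in = NodeEnd(cid, BEGIN if orient == "+" else END)
                    c_out = NodeEnd(cid, END if orient == "+" else BEGIN)
                    w_ac = weight(a_exit, c_in)
                    w_cb = weight(c_out, b_entry)
                    if w_ac > w_ab * insertion_ratio and w_cb > w_ab * insertion_ratio:
                        proposals.append((-(w_ac + w_cb), cid, wi, ji, orient))
    proposals.sort()

    placed: set[str] = set()
    used_junctions: set[Tuple[int, int]] = set()
    insertions: Dict[Tuple[int, int], Tuple[str, str]] = {}
    for _, cid, wi, ji, orient in proposals:
        if cid in placed or (wi, ji) in used_junctions:
            continue
        placed.add(cid)
        used_junctions.add((wi, ji))
        insertions[(wi, ji)] = (cid, orient)

    new_walks: List[Walk] = []
    new_joins: List[List[Optional[HiCEdge]]] = []
    for wi, walk in enumerate(layout.walks):
        if len(walk) == 1 and walk[0][0] in placed:
            continue
        new_walk: Walk = []
        joins: List[Optional[HiCEdge]] = []
        for i, item in enumerate(walk):
            new_walk.append(item)
            if i < len(walk) - 1:
                if (wi, i) in insertions:
                    cid, orient = insertions[(wi, i)]
                    new_walk.append((cid, orient))
                    joins.extend([None, None])
                else:
                    joins.append(layout.joins[wi][i] if layout.joins else None)
        new_walks.append(new_walk)
        new_joins.append(joins)
    return Layout(walks=new_walks, joins=new_joins)
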