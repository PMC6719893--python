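"""Contig-end scaffold graph from inter-contig Hi-C pairs.

Each contig contributes two nodes, B (begin) and E (end); a read is
assigned to the end whose half of the contig contains its start. Edge
weight W(u,v) = N(u,v) / (C(u) + C(v)) normalizes the raw pair count N
by restriction cut-site content, and the best-buddy ratio BB compares
each edge against the strongest competing edge at either endpoint —
only mutually-best edges (BB > 1) survive filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, NamedTuple, Optional, Sequence, Tuple

from hicscaf.io_formats import Contig, HiCPair

BEGIN = "B"
END = "E"


class NodeEnd(NamedTuple):
    contig_id: str
    side: str  # "B" | "E"

    def other(self) -> "NodeEnd":
        return NodeEnd(self.contig_id, END if self.side == BEGIN else BEGIN)


EdgeKey = Tuple[NodeEnd, NodeEnd]


def edge_key(u: NodeEnd, v: NodeEnd) -> EdgeKey:
    """Canonical unordered key for a contig-end pair."""
    return (u, v) if u <= v else (v, u)


@dataclass
class HiCEdge:
    u: NodeEnd
    v: NodeEnd
    n: int = 0  # raw supporting pair count
    w: float = 0.0  # cut-site-normalized weight
    bb: float = 0.0  # best-buddy ratio, set by compute_best_buddy
    source: str = "hic"  # "hic" | "graph" (assembly-graph-implied)

    @property
    def key(self) -> EdgeKey:
        return edge_key(self.u, self.v)


def assign_end(start: int, contig_length: int) -> str:
    """Map a read's start to the B or E half of its contig.

    Halves are [0, L/2) and [L/2, L): a read starting exactly at the
    midpoint belongs to E.
    """
    return BEGIN if start < contig_length / 2 else END


@dataclass
class ScaffoldGraph:
    """Undirected graph over contig ends with Hi-C edges.

    Implicit B–E edges of each contig are not materialized; they are
    implied by the node set and added during layout.
    """

    contigs: Dict[str, Contig]
    edges: Dict[EdgeKey, HiCEdge] = field(default_factory=dict)

    @property
    def nodes(self) -> list[NodeEnd]:
        out = []
        for cid in self.contigs:
            out.append(NodeEnd(cid, BEGIN))
            out.append(NodeEnd(cid, END))
        return out

    def incident(self, node: NodeEnd) -> list[HiCEdge]:
        return [e for e in self.edges.values() if node in (e.u, e.v)]

    def add_edge(self, edge: HiCEdge) -> None:
        self.edges[edge.key] = edge

    def remove_edge(self, key: EdgeKey) -> None:
        self.edges.pop(key, None)

    def sorted_edges(self) -> list[HiCEdge]:
        """Deterministic total order: BB desc, W desc, then endpoint ids."""
        return sorted(
            self.edges.values(), key=lambda e: (-e.bb, -e.w, e.key)
        )

    def dump_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("u_contig\tu_side\tv_contig\tv_side\tN\tW\tBB\tsource\n")
            for key in sorted(self.edges):
                e = self.edges[key]
                fh.write(
                    f"{e.u.contig_id}\t{e.u.side}\t{e.v.contig_id}\t{e.v.side}\t"
                    f"{e.n}\t{e.w:.6g}\t{e.bb:.6g}\t{e.source}\n"
                )


def effective_cut_sites(contig: Contig) -> int:
    """C(V) with a floor of 1 so weight normalization never divides by 0."""
    return max(contig.cut_sites, 1)


def tally_end_pairs(
    pairs: Iterable[HiCPair], contigs: Dict[str, Contig]
) -> Dict[EdgeKey, int]:
    """Count inter-contig pairs per contig-end pair (one count per pair)."""
    counts: Dict[EdgeKey, int] = {}
    for p in pairs:
        if p.intra:
            raise ValueError(f"intra-contig pair {p.read_id!r} in inter-contig tally")
        c1 = contigs.get(p.end1.contig_id)
        c2 = contigs.get(p.end2.contig_id)
        if c1 is None or c2 is None:
            missing = p.end1.contig_id if c1 is None else p.end2.contig_id
            raise KeyError(f"pair references unknown contig {missing!r}")
        u = NodeEnd(c1.id, assign_end(p.end1.start, c1.length))
        v = NodeEnd(c2.id, assign_end(p.end2.start, c2.length))
        key = edge_key(u, v)
        counts[key] = counts.get(key, 0) + 1
    return counts


def build_graph(
    pairs: Iterable[HiCPair],
    contigs: Sequence[Contig],
    min_support: int = 5,
) -> ScaffoldGraph:
    """Build the scaffold graph from inter-contig Hi-C pairs.

    Edges with fewer than ``min_support`` raw pairs are dropped as
    singleton-pair noise.
    """
    by_id = {c.id: c for c in contigs}
    counts = tally_end_pairs(pairs, by_id)
    graph = ScaffoldGraph(contigs=by_id)
    for key, n in counts.items():
        if n < min_support:
            continue
        u, v = key
        c = effective_cut_sites(by_id[u.contig_id]) + effective_cut_sites(
            by_id[v.contig_id]
        )
        graph.add_edge(HiCEdge(u, v, n=n, w=n / c))
    return graph


def graph_from_weights(
    contigs: Sequence[Contig], weights: Dict[EdgeKey, float]
) -> ScaffoldGraph:
    """Construct a graph directly from end-pair weights (for testing)."""
    graph = ScaffoldGraph(contigs={c.id: c for c in contigs})
    for (u, v), w in weights.items():
        graph.add_edge(HiCEdge(u, v, n=0, w=w))
    return graph


def compute_best_buddy(graph: ScaffoldGraph) -> None:
    """Set BB on every edge in O(|E|).

    BB(u,v) = W(u,v) / max(best_other(u), best_other(v)) where
    best_other(x) is the heaviest edge at x excluding (u,v). Endpoints
    with no other edge contribute 0; when both contribute 0 the edge is
    trivially mutually best and BB = +inf. Implemented by caching the
    top two incident weights per node.
    """
    top2: Dict[NodeEnd, list[tuple[float, EdgeKey]]] = {}
    for key, e in graph.edges.items():
        for node in key:
            ranked = top2.setdefault(node, [])
            ranked.append((e.w, key))
            ranked.sort(reverse=True)
            del ranked[2:]

    def best_other(node: NodeEnd, key: EdgeKey) -> float:
        for w, k in top2.get(node, []):
            if k != key:
                return w
        return 0.0

    for key, e in graph.edges.items():
        denom = max(best_other(e.u, key), best_other(e.v, key))
        e.bb = e.w / denom if denom > 0 else float("inf")


def filter_best_buddy(graph: ScaffoldGraph) -> ScaffoldGraph:
    """Keep only mutually-best edges (BB > 1).

    Strict inequality: two equally-best edges at a node eliminate each
    other. The surviving edge set touches each node at most once, so it
    is itself a matching.
    """
    kept = ScaffoldGraph(contigs=graph.contigs)
    for key, e in graph.edges.items():
        if e.bb > 1:
            kept.add_edge(e)
    return kept
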