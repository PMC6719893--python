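"""Greedy matching, walk construction, cycle breaking, insertion."""

import itertools

import networkx as nx
import pytest

from hicscaf.io_formats import Contig
from hicscaf.layout import (
    Layout,
    build_walks,
    greedy_matching,
    insert_small_contigs,
    iterate_matching,
)
from hicscaf.scaffold_graph import (
    HiCEdge,
    NodeEnd,
    edge_key,
    graph_from_weights,
)


def _edge(a, sa, b, sb, w, bb=None):
    e = HiCEdge(NodeEnd(a, sa), NodeEnd(b, sb), n=1, w=w)
    e.bb = w if bb is None else bb
    return e


def _contigs(*names):
    return [Contig(n, 100) for n in names]


# --- greedy matching -------------------------------------------------------

def test_greedy_path_graph_takes_best_edge():
    edges = [_edge("u", "E", "v", "B", 3.0), _edge("v", "E", "w", "B", 2.0)]
    m = greedy_matching(edges)
    assert [e.w for e in m] == [3.0, 2.0]  # disjoint node-ends: both fit
    edges = [_edge("u", "E", "v", "B", 3.0), _edge("v", "B", "w", "B", 2.0)]
    m = greedy_matching(edges)
    assert [e.w for e in m] == [3.0]


def test_greedy_empty():
    assert greedy_matching([]) == []


def _random_weighted_graph(rng, n_nodes, p=0.4):
    nodes = [NodeEnd(f"c{i}", "B") for i in range(n_nodes)]
    edges = []
    for i, j in itertools.combinations(range(n_nodes), 2):
        if rng.random() < p:
            edges.append(
                _edge(f"c{i}", "B", f"c{j}", "B", float(rng.random()) + 0.01)
            )
    return edges


def _optimal_matching_weight(edges):
    g = nx.Graph()
    for e in edges:
        g.add_edge(e.u, e.v, weight=e.w)
    m = nx.algorithms.matching.max_weight_matching(g)
    return sum(g[u][v]["weight"] for u, v in m)


def _exhaustive_matching_weight(edges):
    best = 0.0
    for r in range(1, len(edges) + 1):
        for combo in itertools.combinations(edges, r):
            nodes = [n for e in combo for n in (e.u, e.v)]
            if len(nodes) == len(set(nodes)):
                best = max(best, sum(e.w for e in combo))
    return best


def test_blossom_oracle_agrees_with_exhaustive_enumeration(rng):
    # cross-validate the two independent optima on tiny graphs
    for _ in range(10):
        edges = _random_weighted_graph(rng, 6, p=0.5)
        if not edges:
            continue
        assert _optimal_matching_weight(edges) == pytest.approx(
            _exhaustive_matching_weight(edges)
        )


def test_greedy_half_approximation(rng):
    for _ in range(50):
        edges = _random_weighted_graph(rng, 12)
        if not edges:
            continue
        greedy = sum(e.w for e in greedy_matching(edges))
        assert greedy >= 0.5 * _optimal_matching_weight(edges)


# --- iterated matching -----------------------------------------------------

def test_iterate_star_graph_single_edge():
    weights = {
        edge_key(NodeEnd("c", "E"), NodeEnd(l, "B")): w
        for l, w in [("a", 3.0), ("b", 2.0), ("d", 1.0)]
    }
    g = graph_from_weights(_contigs("c", "a", "b", "d"), weights)
    m = iterate_matching(g)
    assert len(m) == 1 and m[0].w == 3.0


def test_iterate_perfect_matching_graph():
    weights = {
        edge_key(NodeEnd("a", "E"), NodeEnd("b", "B")): 2.0,
        edge_key(NodeEnd("c", "E"), NodeEnd("d", "B")): 1.0,
    }
    g = graph_from_weights(_contigs("a", "b", "c", "d"), weights)
    assert len(iterate_matching(g)) == 2


def test_iterate_result_is_maximal(rng):
    for _ in range(10):
        edges = _random_weighted_graph(rng, 10)
        g = graph_from_weights(
            _contigs(*[f"c{i}" for i in range(10)]),
            {e.key: e.w for e in edges},
        )
        m = iterate_matching(g)
        matched = {n for e in m for n in (e.u, e.v)}
        for e in edges:
            assert e.u in matched or e.v in matched


# --- walks -----------------------------------------------------------------

def test_build_walks_four_contig_chain():
    matching = [
        _edge("a", "E", "b", "B", 5.0),
        _edge("b", "E", "c", "E", 4.0),  # c reversed
        _edge("c", "B", "d", "B", 3.0),  # d forward after reversed c
    ]
    layout = build_walks(matching, _contigs("a", "b", "c", "d"))
    (walk,) = layout.walks
    assert walk == [("a", "+"), ("b", "+"), ("c", "-"), ("d", "+")]


def test_build_walks_breaks_cycle_at_lowest_weight():
    matching = [
        _edge("a", "E", "b", "B", 5.0),
        _edge("b", "E", "c", "B", 4.0),
        _edge("c", "E", "a", "B", 1.0),  # weakest closes the cycle
    ]
    layout = build_walks(matching, _contigs("a", "b", "c"))
    (walk,) = layout.walks
    assert walk == [("a", "+"), ("b", "+"), ("c", "+")]
    assert [e.w for e in layout.joins[0]] == [5.0, 4.0]


def test_build_walks_every_contig_once(rng):
    contigs = _contigs(*[f"c{i}" for i in range(12)])
    for _ in range(10):
        ends = [NodeEnd(c.id, s) for c in contigs for s in "BE"]
        rng.shuffle(ends)
        matching = []
        used = set()
        for u, v in zip(ends[::2], ends[1::2]):
            if u.contig_id == v.contig_id:
                continue
            matching.append(HiCEdge(u, v, n=1, w=float(rng.random())))
        layout = build_walks(matching, contigs)
        ids = layout.contig_ids
        assert sorted(ids) == sorted(c.id for c in contigs)
        join_keys = {e.key for joins in layout.joins for e in joins if e}
        assert join_keys <= {e.key for e in matching}


def test_singletons_become_single_walks():
    layout = build_walks([], _contigs("a", "b"))
    assert layout.walks == [[("a", "+")], [("b", "+")]]


# --- small-contig insertion ------------------------------------------------

def _weight_graph(weights):
    contigs = {}
    table = {}
    for (a, sa, b, sb), w in weights.items():
        contigs.setdefault(a, Contig(a, 100))
        contigs.setdefault(b, Contig(b, 100))
        table[edge_key(NodeEnd(a, sa), NodeEnd(b, sb))] = w
    return graph_from_weights(list(contigs.values()), table)


def test_insert_between_strong_flanks():
    layout = Layout(walks=[[("a", "+"), ("b", "+")], [("c", "+")]])
    g = _weight_graph({
        ("a", "E", "b", "B"): 1.0,
        ("a", "E", "c", "B"): 3.0,
        ("c", "E", "b", "B"): 3.0,
    })
    out = insert_small_contigs(layout, g)
    assert out.walks == [[("a", "+"), ("c", "+"), ("b", "+")]]


def test_insert_no_links_stays_singleton():
    layout = Layout(walks=[[("a", "+"), ("b", "+")], [("c", "+")]])
    g = _weight_graph({("a", "E", "b", "B"): 1.0})
    out = insert_small_contigs(layout, g)
    assert [("c", "+")] in out.walks


def test_insert_competing_candidates_best_wins():
    layout = Layout(walks=[[("a", "+"), ("b", "+")], [("c", "+")], [("d", "+")]])
    g = _weight_graph({
        ("a", "E", "b", "B"): 1.0,
        ("a", "E", "c", "B"): 3.0,
        ("c", "E", "b", "B"): 3.0,
        ("a", "E", "d", "B"): 2.0,
        ("d", "E", "b", "B"): 2.0,
    })
    out = insert_small_contigs(layout, g)
    assert [("a", "+"), ("c", "+"), ("b", "+")] in out.walks
    assert [("d", "+")] in out.walks


def test_layout_conserves_total_length(small_sim):
    from hicscaf import pipeline

    cfg = pipeline.PipelineConfig(correct=False)
    res = pipeline.scaffold(
        small_sim["contigs"], small_sim["pairs"], small_sim["asm_graph"], cfg
    )
    assert sorted(res.layout.contig_ids) == sorted(
        c.id for c in small_sim["contigs"]
    )
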